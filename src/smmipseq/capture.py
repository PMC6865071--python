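"""Demultiplexing and arm-anchored read-to-probe assignment.

Reads are assigned to their originating smMIP by the identity of the two
targeting arms at fixed layout offsets — the ligation arm directly after the
sample barcode on read 1, the extension arm directly before the UMI at the
amplicon end (read from the reverse-complemented mate).  Because the arms are
anchored by the capture chemistry, fixed-offset Hamming matching (default
tolerance 1 per arm) replaces general alignment and is O(1) per probe for
error-free reads (hash lookup) with a vectorised mismatch scan as fallback.

Mates are merged into the full amplicon by maximising overlap agreement over
the candidate amplicon lengths implied by the assigned probe's splice forms
(plus a small indel window), and overlap positions where the mates disagree
are masked to ``N`` so they contribute no variant evidence downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from ._util import N, decode_rows, encode, hamming, revcomp_codes
from .panel import Panel

UNDETERMINED = "undetermined"


class CaptureError(ValueError):
    """Raised for inputs that violate capture preconditions."""


@dataclass
class AssignmentStats:
    """Per-sample read-accounting; categories always sum to the input count."""

    input_pairs: int = 0
    assigned: int = 0
    unassigned_arms: int = 0
    unmerged: int = 0
    malformed: int = 0

    def to_dict(self) -> dict:
        return {
            "input_pairs": self.input_pairs,
            "assigned": self.assigned,
            "unassigned_arms": self.unassigned_arms,
            "unmerged": self.unmerged,
            "malformed": self.malformed,
        }


@dataclass
class CaptureStats:
    """Run-level accounting: demultiplexing plus per-sample assignment."""

    input_pairs: int = 0
    undetermined_barcode: int = 0
    per_sample: dict[str, AssignmentStats] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_pairs": self.input_pairs,
            "undetermined_barcode": self.undetermined_barcode,
            "per_sample": {k: v.to_dict() for k, v in self.per_sample.items()},
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fastq_pair(r1_path, r2_path):
    """Load a FASTQ pair into code matrices.

    Returns ``(read_ids, r1, r2, lengths_ok)`` where reads shorter than the
    run's read length are padded with ``N`` and flagged as malformed via
    ``lengths_ok``.  The read length is taken as the maximum observed length.
    """
    ids: list[str] = []
    seqs1: list[str] = []
    seqs2: list[str] = []
    with pysam.FastxFile(str(r1_path)) as fh1, pysam.FastxFile(str(r2_path)) as fh2:
        for rec1, rec2 in zip(fh1, fh2):
            if rec1.name != rec2.name:
                raise CaptureError(
                    f"FASTQ pair out of sync at {rec1.name} / {rec2.name}"
                )
            ids.append(rec1.name)
            seqs1.append(rec1.sequence)
            seqs2.append(rec2.sequence)
    if not ids:
        read_len = 0
        empty = np.empty((0, 0), dtype=np.uint8)
        return ids, empty, empty, np.empty(0, dtype=bool)
    read_len = max(max(map(len, seqs1)), max(map(len, seqs2)))
    n = len(ids)
    r1 = np.full((n, read_len), N, dtype=np.uint8)
    r2 = np.full((n, read_len), N, dtype=np.uint8)
    ok = np.empty(n, dtype=bool)
    for i, (s1, s2) in enumerate(zip(seqs1, seqs2)):
        r1[i, : len(s1)] = encode(s1)
        r2[i, : len(s2)] = encode(s2)
        ok[i] = len(s1) == read_len and len(s2) == read_len
    return ids, r1, r2, ok


def load_barcode_table(path, tolerance: int = 1) -> pd.DataFrame:
    """Load a sample/barcode TSV and verify barcode separability."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "barcode"} <= set(table.columns):
        raise CaptureError("barcode table needs columns: sample_id, barcode")
    check_barcodes(list(table["barcode"]), tolerance)
    return table


def check_barcodes(barcodes: list[str], tolerance: int) -> None:
    """Barcodes must be mutually distinguishable at the chosen tolerance
    (pairwise Hamming distance > 2 x tolerance)."""
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise CaptureError("barcodes must share a single length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if hamming(a, b) <= 2 * tolerance:
                raise CaptureError(
                    f"barcodes {a} and {b} are separated by <= {2 * tolerance} "
                    f"mismatches; demultiplexing at tolerance {tolerance} "
                    f"would be ambiguous"
                )


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------


def demultiplex(
    r1: np.ndarray,
    barcodes: list[str],
    tolerance: int = 1,
) -> np.ndarray:
    """Assign each read pair to a barcode index (-1 = undetermined).

    The barcode occupies the first bases of read 1.  Exact matches resolve by
    hash; the remainder by a vectorised nearest-barcode scan, unique within
    tolerance by the separability precondition.
    """
    check_barcodes(barcodes, tolerance)
    bc_len = len(barcodes[0])
    if r1.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    if r1.shape[1] < bc_len:
        raise CaptureError("reads shorter than the barcode length")
    sub = np.ascontiguousarray(r1[:, :bc_len])
    powers = 5 ** np.arange(bc_len, dtype=np.int64)
    codes = sub.astype(np.int64) @ powers
    lut: dict[int, int] = {
        int(encode(b).astype(np.int64) @ powers): i for i, b in enumerate(barcodes)
    }
    out = np.array([lut.get(int(c), -1) for c in codes], dtype=np.int64)
    if tolerance > 0:
        todo = np.flatnonzero(out == -1)
        if len(todo):
            mat = np.stack([encode(b) for b in barcodes])
            dist = (sub[todo, None, :] != mat[None, :, :]).sum(axis=2)
            best = dist.argmin(axis=1)
            hit = dist[np.arange(len(todo)), best] <= tolerance
            out[todo[hit]] = best[hit]
    return out


# ---------------------------------------------------------------------------
# probe assignment & mate merging
# ---------------------------------------------------------------------------


def _row_bytes(matrix: np.ndarray) -> list[bytes]:
    buf = np.ascontiguousarray(matrix).tobytes()
    w = matrix.shape[1]
    return [buf[i : i + w] for i in range(0, len(buf), w)]


def _candidate_lengths(
    panel: Panel, probe, barcode_len: int, umi_len: int, indel_tolerance: int
) -> tuple[list[int], list[int]]:
    """Primary candidate amplicon lengths (per splice form) and an extended
    set covering short indels."""
    overhead = (
        barcode_len + len(probe.ligation_arm) + len(probe.extension_arm) + umi_len
    )
    forms = panel.capturable_gapfills(probe)
    primary: list[int] = []
    for j, (seq, _) in forms.items():
        a = overhead + len(seq)
        if a not in primary:
            primary.append(a)
    extended: list[int] = []
    for a in primary:
        for delta in range(1, indel_tolerance + 1):
            for cand in (a - delta, a + delta):
                if cand not in primary and cand not in extended:
                    extended.append(cand)
    return primary, extended


def _merge_scores(
    r1: np.ndarray, rc2: np.ndarray, a: int, read_len: int
) -> np.ndarray:
    """Fraction of agreeing bases in the mate overlap for amplicon length a."""
    lo, hi = a - read_len, read_len
    if lo >= hi:  # no overlap at this length
        return np.ones(r1.shape[0])
    ov = hi - lo
    agree = (r1[:, lo:hi] == rc2[:, : ov]).sum(axis=1)
    return agree / ov


def assign_reads(
    read_ids: list[str],
    r1: np.ndarray,
    r2: np.ndarray,
    panel: Panel,
    sample_ids: np.ndarray | list[str],
    arm_mismatch: int = 1,
    barcode_len: int = 8,
    umi_len: int = 8,
    min_overlap: int = 10,
    indel_tolerance: int = 6,
    min_merge_agreement: float = 0.8,
    lengths_ok: np.ndarray | None = None,
    _chunk: int = 2048,
) -> tuple[pd.DataFrame, dict[str, AssignmentStats]]:
    """Assign demultiplexed read pairs to probes and extract UMI + gap-fill.

    A pair is assigned to a probe iff both arms match that probe's arms
    within ``arm_mismatch`` at the fixed layout offsets and no other probe
    matches equally well (ties are ambiguous and left unassigned).  Returns
    the captured-read table (sample_id, probe_id, umi, gap-fill in transcript
    orientation, arm mismatch count) and per-sample accounting that conserves
    the input pair count.
    """
    n = r1.shape[0]
    sample_ids = np.asarray(sample_ids, dtype=object)
    stats: dict[str, AssignmentStats] = {
        s: AssignmentStats() for s in pd.unique(sample_ids)
    }
    for s in sample_ids:
        stats[s].input_pairs += 1
    if n == 0:
        cols = ["read_id", "sample_id", "probe_id", "umi", "gapfill", "arm_mismatches"]
        return pd.DataFrame(columns=cols), stats

    read_len = r1.shape[1]
    if lengths_ok is None:
        lengths_ok = np.ones(n, dtype=bool)
    min_len = barcode_len + umi_len + min_overlap
    usable = lengths_ok & (read_len >= min_len)

    rc2 = revcomp_codes(r2)
    probe_idx = np.full(n, -1, dtype=np.int64)
    arm_mm = np.zeros(n, dtype=np.int64)

    # group probes by arm-length pair; within each group arms sit at fixed offsets
    groups: dict[tuple[int, int], list[int]] = {}
    for i, p in enumerate(panel.smmips):
        groups.setdefault((len(p.ligation_arm), len(p.extension_arm)), []).append(i)

    best_mm = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    ambiguous = np.zeros(n, dtype=bool)
    for (l_lig, l_ext), members in groups.items():
        if read_len < barcode_len + l_lig or read_len < umi_len + l_ext:
            continue
        lig = np.ascontiguousarray(r1[:, barcode_len : barcode_len + l_lig])
        ext = np.ascontiguousarray(
            rc2[:, read_len - umi_len - l_ext : read_len - umi_len]
        )
        # exact path
        lut = {
            (
                panel.smmips[i].ligation_arm + panel.smmips[i].extension_arm
            ).encode(): i
            for i in members
        }
        keys = [
            a + b for a, b in zip(_row_bytes(_decode_matrix(lig)), _row_bytes(_decode_matrix(ext)))
        ]
        for ridx in np.flatnonzero(usable):
            hit = lut.get(keys[ridx])
            if hit is not None and 0 < best_mm[ridx]:
                probe_idx[ridx] = hit
                best_mm[ridx] = 0
                ambiguous[ridx] = False
        if arm_mismatch > 0:
            todo = np.flatnonzero(usable & (best_mm > 0))
            if len(todo):
                lig_mat = np.stack([encode(panel.smmips[i].ligation_arm) for i in members])
                ext_mat = np.stack([encode(panel.smmips[i].extension_arm) for i in members])
                for start in range(0, len(todo), _chunk):
                    block = todo[start : start + _chunk]
                    mm_l = (lig[block, None, :] != lig_mat[None, :, :]).sum(axis=2)
                    mm_e = (ext[block, None, :] != ext_mat[None, :, :]).sum(axis=2)
                    feasible = (mm_l <= arm_mismatch) & (mm_e <= arm_mismatch)
                    total = mm_l + mm_e
                    total[~feasible] = np.iinfo(np.int64).max // 2
                    arg = total.argmin(axis=1)
                    rows = np.arange(len(block))
                    mins = total[rows, arg]
                    nmin = (total == mins[:, None]).sum(axis=1)
                    ok = feasible[rows, arg]
                    better = ok & (mins < best_mm[block])
                    equal = ok & (mins == best_mm[block])
                    idx = block[better]
                    probe_idx[idx] = np.array(members, dtype=np.int64)[arg[better]]
                    best_mm[idx] = mins[better]
                    arm_mm[idx] = mins[better]
                    ambiguous[idx] = nmin[better] > 1
                    ambiguous[block[equal]] |= True

    probe_idx[ambiguous] = -1

    # --- mate merging and gap-fill extraction, per assigned probe ----------
    out_frames: list[pd.DataFrame] = []
    merged_ok = np.zeros(n, dtype=bool)
    probes = panel.smmips
    for pi in np.unique(probe_idx[probe_idx >= 0]):
        probe = probes[pi]
        rows = np.flatnonzero(probe_idx == pi)
        primary, extended = _candidate_lengths(
            panel, probe, barcode_len, umi_len, indel_tolerance
        )
        r1g, rc2g = r1[rows], rc2[rows]
        best_a = np.full(len(rows), -1, dtype=np.int64)
        best_score = np.full(len(rows), -1.0)
        for cand_set in (primary, extended):
            pending = best_score < min_merge_agreement
            if not pending.any():
                break
            for a in cand_set:
                if a < read_len or a > 2 * read_len - min_overlap:
                    continue
                score = _merge_scores(r1g, rc2g, a, read_len)
                improve = pending & (score > best_score + 1e-12)
                best_a[improve] = a
                best_score[improve] = score[improve]
        good = best_score >= min_merge_agreement
        merged_ok[rows[good]] = True
        l_lig, l_ext = len(probe.ligation_arm), len(probe.extension_arm)
        for a in np.unique(best_a[good]):
            sel = good & (best_a == a)
            sub_rows = rows[sel]
            s, e = barcode_len + l_lig, int(a) - umi_len - l_ext
            pos = np.arange(s, e)
            only1 = pos < int(a) - read_len
            only2 = pos >= read_len
            both = ~only1 & ~only2
            gap = np.empty((len(sub_rows), e - s), dtype=np.uint8)
            if only1.any():
                gap[:, only1] = r1g[sel][:, pos[only1]]
            if only2.any():
                gap[:, only2] = rc2g[sel][:, pos[only2] - (int(a) - read_len)]
            if both.any():
                x = r1g[sel][:, pos[both]]
                y = rc2g[sel][:, pos[both] - (int(a) - read_len)]
                gap[:, both] = np.where(x == y, x, np.uint8(N))
            umi = rc2g[sel][:, read_len - umi_len :]
            out_frames.append(
                pd.DataFrame(
                    {
                        "read_id": [read_ids[i] for i in sub_rows],
                        "sample_id": sample_ids[sub_rows],
                        "probe_id": probe.probe_id,
                        "umi": decode_rows(umi),
                        "gapfill": decode_rows(gap),
                        "arm_mismatches": arm_mm[sub_rows],
                    }
                )
            )

    # --- accounting --------------------------------------------------------
    for s in stats:
        mask = sample_ids == s
        stats[s].malformed = int((~usable & mask).sum())
        stats[s].assigned = int((merged_ok & mask).sum())
        stats[s].unassigned_arms = int((usable & (probe_idx < 0) & mask).sum())
        stats[s].unmerged = int(
            (usable & (probe_idx >= 0) & ~merged_ok & mask).sum()
        )
    if out_frames:
        captured = pd.concat(out_frames, ignore_index=True)
    else:
        captured = pd.DataFrame(
            columns=["read_id", "sample_id", "probe_id", "umi", "gapfill", "arm_mismatches"]
        )
    return captured, stats


def _decode_matrix(matrix: np.ndarray) -> np.ndarray:
    """Map code rows back to ASCII bytes so they can key against arm strings."""
    from ._util import _DECODE_LUT

    return _DECODE_LUT[matrix]


def capture_run(
    r1_path,
    r2_path,
    barcode_table: pd.DataFrame,
    panel: Panel,
    arm_mismatch: int = 1,
    barcode_mismatch: int = 1,
    **kwargs,
) -> tuple[pd.DataFrame, CaptureStats]:
    """Demultiplex a pooled FASTQ pair and assign every read to its probe.

    Returns the captured-read table and conservation-checked statistics.
    """
    read_ids, r1, r2, ok = read_fastq_pair(r1_path, r2_path)
    barcodes = list(barcode_table["barcode"])
    samples = list(barcode_table["sample_id"])
    bc_idx = demultiplex(r1, barcodes, tolerance=barcode_mismatch)
    stats = CaptureStats(input_pairs=len(read_ids))
    stats.undetermined_barcode = int((bc_idx < 0).sum())
    keep = bc_idx >= 0
    sample_ids = np.array(
        [samples[i] if i >= 0 else UNDETERMINED for i in bc_idx], dtype=object
    )
    captured, per_sample = assign_reads(
        [rid for rid, k in zip(read_ids, keep) if k],
        r1[keep],
        r2[keep],
        panel,
        sample_ids[keep],
        arm_mismatch=arm_mismatch,
        barcode_len=len(barcodes[0]),
        lengths_ok=ok[keep],
        **kwargs,
    )
    for s in samples:
        per_sample.setdefault(s, AssignmentStats())
    stats.per_sample = per_sample
    return captured, stats
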