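"""smMIP panel model: probes, reference transcripts, validation, junction logic.

A single-molecule molecular inversion probe (smMIP) is described by its two
targeting arms (extension and ligation), the transcript region of interest
(ROI) captured between them, and — for splice-sensitive probes — one or more
junction targets.  All coordinates are 0-based half-open on the *transcript*
(not the genome): probes capture cDNA, and every downstream computation
(gap-fill extraction, pileups, junction k-mers) is plain interval arithmetic
in transcript space.

Junction probes and isoforms
----------------------------
A junction target ``(u, d, label)`` declares that the probe discriminates the
isoform ``label`` whose transcript joins exon ``u`` directly to exon ``d``.
For ``d == u + 1`` this is the canonical (full-length) junction; for
``d > u + 1`` the exons in between are spliced out.  The probe's ROI is kept
in canonical coordinates, so a probe spanning a large excised region (an
EGFRvIII-style exon 1/8 probe) has a raw ROI far longer than the gap-fill
capacity: what must fit in the capture reaction is the *effective* gap-fill,
i.e. the ROI after excising the skipped exons, and that is what validation
checks.  A probe whose ROI contains two alternative junctions resolves both
isoforms from a single capture (the CA12 exon-8/9 vs 8/10 case, possible
because exon 9 is only 33 nt).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import is_dna

PANEL_COLUMNS = [
    "probe_id",
    "transcript_id",
    "extension_arm",
    "ligation_arm",
    "roi_start",
    "roi_end",
    "strand",
    "junctions",
]

#: default gap-fill capacity (nt) of the capture reaction; a 266-bp amplicon
#: with an 8-nt barcode, 8-nt UMI and two 25-nt arms leaves 200 nt of gap-fill,
#: plus head-room for short insertions.
DEFAULT_MAX_GAPFILL = 210


class PanelError(ValueError):
    """Raised for malformed or internally inconsistent panel inputs."""


@dataclass(frozen=True)
class SmMIP:
    """One inversion probe targeting a transcript ROI."""

    probe_id: str
    transcript_id: str
    extension_arm: str
    ligation_arm: str
    roi_start: int
    roi_end: int
    strand: str = "+"
    junction_targets: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if not is_dna(self.extension_arm) or not is_dna(self.ligation_arm):
            raise PanelError(
                f"probe {self.probe_id}: arms must be non-empty A/C/G/T strings"
            )
        if not (0 <= self.roi_start < self.roi_end):
            raise PanelError(
                f"probe {self.probe_id}: require 0 <= roi_start < roi_end, "
                f"got [{self.roi_start}, {self.roi_end})"
            )
        if self.strand not in ("+", "-"):
            raise PanelError(f"probe {self.probe_id}: strand must be + or -")

    @property
    def roi_length(self) -> int:
        return self.roi_end - self.roi_start

    @property
    def arm_pair(self) -> tuple[str, str]:
        return (self.ligation_arm, self.extension_arm)


@dataclass(frozen=True)
class Transcript:
    """Reference transcript sequence with exon boundary offsets.

    ``exon_ends`` lists the cumulative end offset of each exon in transcript
    coordinates; the last entry equals the sequence length.  Exons are
    numbered 1-based, as in the field's usage ("exon 9 of CA12").
    """

    transcript_id: str
    seq: str
    exon_ends: tuple[int, ...]
    gene: str

    def __post_init__(self) -> None:
        ends = self.exon_ends
        if not ends or ends[-1] != len(self.seq):
            raise PanelError(
                f"transcript {self.transcript_id}: exon ends must finish at "
                f"sequence length {len(self.seq)}, got {ends}"
            )
        if any(b >= a for b, a in zip(ends, ends[1:])) or ends[0] <= 0:
            raise PanelError(
                f"transcript {self.transcript_id}: exon ends must be strictly "
                f"increasing and positive"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exon_ends)

    def exon_start(self, i: int) -> int:
        """Start offset of 1-based exon ``i``."""
        self._check_exon(i)
        return 0 if i == 1 else self.exon_ends[i - 2]

    def exon_end(self, i: int) -> int:
        """End offset (exclusive) of 1-based exon ``i``."""
        self._check_exon(i)
        return self.exon_ends[i - 1]

    def _check_exon(self, i: int) -> None:
        if not (1 <= i <= self.n_exons):
            raise PanelError(
                f"transcript {self.transcript_id} has {self.n_exons} exons; "
                f"exon {i} does not exist"
            )


@dataclass
class ValidationReport:
    """Outcome of panel validation: hard errors, advisory warnings, summary."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "errors": self.errors,
                "warnings": self.warnings,
                "summary": self.summary,
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = [f"panel validation: {'OK' if self.ok else 'FAILED'}"]
        lines += [f"  ERROR: {e}" for e in self.errors]
        lines += [f"  warning: {w}" for w in self.warnings]
        lines += [f"  {k}: {v}" for k, v in self.summary.items()]
        return "\n".join(lines)


@dataclass
class Panel:
    """A validated-or-validatable collection of smMIPs plus their references."""

    smmips: list[SmMIP]
    transcripts: dict[str, Transcript]
    max_gapfill: int = DEFAULT_MAX_GAPFILL

    def __post_init__(self) -> None:
        self._by_id = {p.probe_id: p for p in self.smmips}
        if len(self._by_id) != len(self.smmips):
            raise PanelError("duplicate probe_id in panel")
        for p in self.smmips:
            if p.transcript_id not in self.transcripts:
                raise PanelError(
                    f"probe {p.probe_id} references unknown transcript "
                    f"{p.transcript_id}"
                )
            t = self.transcripts[p.transcript_id]
            for u, d, label in p.junction_targets:
                t._check_exon(u)
                t._check_exon(d)
                if d <= u:
                    raise PanelError(
                        f"probe {p.probe_id}: junction {u}/{d} is not "
                        f"downstream-oriented"
                    )

    def __len__(self) -> int:
        return len(self.smmips)

    def probe(self, probe_id: str) -> SmMIP:
        return self._by_id[probe_id]

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.smmips]

    @property
    def gene_map(self) -> dict[str, str]:
        return {tid: t.gene for tid, t in self.transcripts.items()}

    @property
    def isoform_defs(self) -> dict[str, tuple[str, int, int]]:
        """isoform label -> (transcript_id, upstream exon, downstream exon)."""
        defs: dict[str, tuple[str, int, int]] = {}
        for p in self.smmips:
            for u, d, label in p.junction_targets:
                key = (p.transcript_id, u, d)
                if label in defs and defs[label] != key:
                    raise PanelError(
                        f"isoform label {label} maps to conflicting junctions"
                    )
                defs[label] = key
        return defs

    def isoforms_of_gene(self, gene: str) -> dict[str, tuple[str, int, int]]:
        gm = self.gene_map
        return {
            lab: (tid, u, d)
            for lab, (tid, u, d) in self.isoform_defs.items()
            if gm[tid] == gene
        }

    # -- gap-fill geometry -------------------------------------------------

    def effective_gapfill(
        self, probe: SmMIP, junction: tuple[int, int] | None = None
    ) -> tuple[str, np.ndarray] | None:
        """Gap-fill sequence a probe captures from a given splice form.

        ``junction=(u, d)`` describes a molecule in which exon ``u`` is joined
        directly to exon ``d`` (``None`` or an adjacent pair means canonical).
        Returns ``(sequence, posmap)`` where ``posmap[i]`` is the canonical
        transcript coordinate of gap-fill base ``i``, or ``None`` when the
        splice form is incompatible with the probe (the excised region cuts
        into an arm or extends past the ROI).  Capacity is *not* checked here.
        """
        t = self.transcripts[probe.transcript_id]
        rs, re = probe.roi_start, probe.roi_end
        if re > len(t.seq):
            raise PanelError(
                f"probe {probe.probe_id}: ROI end {re} outside transcript "
                f"{t.transcript_id} (length {len(t.seq)})"
            )
        x0 = x1 = rs  # empty excision by default
        if junction is not None:
            u, d = junction
            x0, x1 = t.exon_end(u), t.exon_start(d)
        if x0 == x1 or x1 <= rs - len(probe.ligation_arm) or x0 >= re + len(
            probe.extension_arm
        ):
            # canonical, or excision entirely outside the probe footprint
            return t.seq[rs:re], np.arange(rs, re)
        if rs <= x0 and x1 <= re:
            seq = t.seq[rs:x0] + t.seq[x1:re]
            posmap = np.concatenate([np.arange(rs, x0), np.arange(x1, re)])
            return seq, posmap
        return None  # excision clips an arm or a ROI edge: no capture

    def capturable_gapfills(
        self, probe: SmMIP
    ) -> dict[tuple[int, int] | None, tuple[str, np.ndarray]]:
        """All splice forms the probe can physically capture, within capacity.

        Keys are junctions (``None`` = canonical); canonical-equivalent
        junction targets (``d == u + 1``) are folded into their junction key so
        simulation and classification can address them by label.
        """
        out: dict[tuple[int, int] | None, tuple[str, np.ndarray]] = {}
        forms: list[tuple[int, int] | None] = [None]
        forms += [(u, d) for u, d, _ in probe.junction_targets]
        for j in forms:
            g = self.effective_gapfill(probe, j)
            if g is not None and len(g[0]) <= self.max_gapfill:
                out[j] = g
        return out

    def junction_kmer(self, transcript_id: str, u: int, d: int, k: int = 10) -> str:
        """The 2k-mer straddling the exon ``u``/``d`` boundary (clamped at ends)."""
        t = self.transcripts[transcript_id]
        eu, sd = t.exon_end(u), t.exon_start(d)
        left = t.seq[max(0, eu - k) : eu]
        right = t.seq[sd : sd + k]
        return left + right


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_fasta_header(description: str) -> tuple[str | None, tuple[int, ...] | None]:
    """Extract ``gene=`` and ``exons=`` attributes from a FASTA description."""
    gene = None
    exons = None
    for token in description.split()[1:]:
        if token.startswith("gene="):
            gene = token[5:]
        elif token.startswith("exons="):
            exons = tuple(int(x) for x in token[6:].split(",") if x)
    return gene, exons


def load_reference(fasta_path) -> dict[str, Transcript]:
    """Read transcript sequences (plain or gzip FASTA) with exon annotations.

    Exon structure is carried in the header as ``exons=e1,e2,...`` cumulative
    end offsets (the final offset may be omitted; it is always the sequence
    length).  A header without ``exons=`` yields a single-exon transcript.
    ``gene=SYMBOL`` sets the gene symbol (default: the transcript id).
    """
    transcripts: dict[str, Transcript] = {}
    with _open_text(fasta_path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            gene, exons = _parse_fasta_header(rec.description)
            ends = exons or ()
            if not ends or ends[-1] != len(seq):
                ends = tuple(ends) + (len(seq),)
            transcripts[rec.id] = Transcript(
                transcript_id=rec.id,
                seq=seq,
                exon_ends=tuple(ends),
                gene=gene or rec.id,
            )
    if not transcripts:
        raise PanelError(f"no transcripts parsed from {fasta_path}")
    return transcripts


def parse_junction_spec(spec: str) -> tuple[tuple[int, int, str], ...]:
    """Parse ``"1/8:EGFRvIII;8/10:CA12v2"`` into junction-target tuples."""
    spec = (spec or "").strip()
    if spec in ("", ".", "nan"):
        return ()
    targets = []
    for part in spec.split(";"):
        try:
            exons, label = part.split(":")
            u, d = exons.split("/")
            targets.append((int(u), int(d), label.strip()))
        except ValueError as exc:
            raise PanelError(f"malformed junction spec {part!r}") from exc
    return tuple(targets)


def format_junction_spec(targets) -> str:
    if not targets:
        return "."
    return ";".join(f"{u}/{d}:{label}" for u, d, label in targets)


def load_panel(panel_table, reference, max_gapfill: int = DEFAULT_MAX_GAPFILL) -> Panel:
    """Load a panel TSV and its reference FASTA into a :class:`Panel`.

    Any malformed row (non-DNA arm, bad coordinates, unknown transcript) is a
    hard error naming the offending row/probe.
    """
    transcripts = load_reference(reference)
    table = pd.read_csv(panel_table, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in table.columns and c != "junctions"]
    if missing:
        raise PanelError(f"panel table missing required columns: {missing}")
    smmips = []
    for idx, row in enumerate(table.itertuples(index=False), start=1):
        try:
            probe = SmMIP(
                probe_id=row.probe_id,
                transcript_id=row.transcript_id,
                extension_arm=row.extension_arm.upper(),
                ligation_arm=row.ligation_arm.upper(),
                roi_start=int(row.roi_start),
                roi_end=int(row.roi_end),
                strand=getattr(row, "strand", "+") or "+",
                junction_targets=parse_junction_spec(getattr(row, "junctions", ".")),
            )
        except (PanelError, ValueError) as exc:
            raise PanelError(f"panel row {idx}: {exc}") from exc
        if probe.transcript_id not in transcripts:
            raise PanelError(
                f"panel row {idx}: probe {probe.probe_id} references transcript "
                f"{probe.transcript_id} absent from the reference FASTA"
            )
        smmips.append(probe)
    return Panel(smmips=smmips, transcripts=transcripts, max_gapfill=max_gapfill)


def write_panel(panel: Panel, path) -> None:
    """Write the panel back as a normalized TSV (inverse of :func:`load_panel`)."""
    rows = [
        {
            "probe_id": p.probe_id,
            "transcript_id": p.transcript_id,
            "extension_arm": p.extension_arm,
            "ligation_arm": p.ligation_arm,
            "roi_start": p.roi_start,
            "roi_end": p.roi_end,
            "strand": p.strand,
            "junctions": format_junction_spec(p.junction_targets),
        }
        for p in panel.smmips
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def write_reference(transcripts: dict[str, Transcript], path) -> None:
    """Write transcripts as FASTA with gene/exon annotations in the headers."""
    with open(path, "w") as fh:
        for t in transcripts.values():
            exons = ",".join(str(e) for e in t.exon_ends)
            fh.write(f">{t.transcript_id} gene={t.gene} exons={exons}\n")
            for i in range(0, len(t.seq), 80):
                fh.write(t.seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# validation & junction resolution
# ---------------------------------------------------------------------------

MIN_PROBES_PER_TRANSCRIPT = 5


def validate_panel(panel: Panel) -> ValidationReport:
    """Check panel-level design rules; problems are reported, never thrown.

    Errors: duplicate arm pairs (read assignment keys on arms, so duplicates
    make it ill-defined), ROI outside transcript bounds, and probes whose
    every splice form exceeds the gap-fill capacity.  Warnings: transcripts
    covered by fewer than five probes (the design floor for robust
    per-transcript means).
    """
    report = ValidationReport()
    seen_arms: dict[tuple[str, str], str] = {}
    per_transcript: dict[str, int] = {}
    for p in panel.smmips:
        per_transcript[p.transcript_id] = per_transcript.get(p.transcript_id, 0) + 1
        if p.arm_pair in seen_arms:
            report.errors.append(
                f"ambiguous arm pair: probes {seen_arms[p.arm_pair]} and "
                f"{p.probe_id} share identical arms"
            )
        else:
            seen_arms[p.arm_pair] = p.probe_id
        t = panel.transcripts[p.transcript_id]
        if p.roi_end > len(t.seq):
            report.errors.append(
                f"probe {p.probe_id}: ROI [{p.roi_start}, {p.roi_end}) outside "
                f"transcript {t.transcript_id} bounds (length {len(t.seq)})"
            )
            continue
        if not panel.capturable_gapfills(p):
            report.errors.append(
                f"probe {p.probe_id}: no splice form yields a gap-fill within "
                f"capacity {panel.max_gapfill} nt"
            )
    for tid, n in sorted(per_transcript.items()):
        if n < MIN_PROBES_PER_TRANSCRIPT:
            report.warnings.append(
                f"transcript {tid} below minimum probe count "
                f"({n} < {MIN_PROBES_PER_TRANSCRIPT})"
            )
    report.summary = {
        "n_probes": len(panel),
        "n_transcripts": len(panel.transcripts),
        "n_junction_probes": sum(1 for p in panel.smmips if p.junction_targets),
        "n_errors": len(report.errors),
        "n_warnings": len(report.warnings),
    }
    return report


def junction_map(panel: Panel, k: int = 10) -> dict[str, set[str]]:
    """Per probe, the isoform labels its gap-fill sequence can discriminate.

    An isoform is resolvable by a probe when the probe can capture that splice
    form within capacity and the 2k-mer straddling the isoform's junction
    occurs in the captured gap-fill.  One probe may resolve several isoforms
    when alternative junctions both fall inside its ROI.
    """
    out: dict[str, set[str]] = {}
    for p in panel.smmips:
        labels: set[str] = set()
        gapfills = panel.capturable_gapfills(p)
        for u, d, label in p.junction_targets:
            j = (u, d)
            form = gapfills.get(j)
            if form is None:
                continue
            kmer = panel.junction_kmer(p.transcript_id, u, d, k=k)
            if kmer and kmer in form[0]:
                labels.add(label)
        out[p.probe_id] = labels
    return out
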