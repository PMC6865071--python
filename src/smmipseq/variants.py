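"""RNA-level variant calling from unique molecules, hotspot annotation, and
expression-mutation coupling.

Variants are called from a per-position pileup of *molecule* consensus
sequences (not reads), so PCR duplicates contribute no extra evidence.  The
depth at a position is the number of molecules whose consensus covers it
with a determinate (non-``N``) base; every non-reference allele is reported
with its unique-molecule fraction, and a call passes the clinical-reporting
filter iff its fraction strictly exceeds 10% of the unique molecules at that
position.  Short indels are recognised by gap-fill length deviation and
realigned (common prefix/suffix) within the ROI; they are reported
VCF-style, anchored on the base before the event.

Protein-level names (IDH1-R132H, BRAF-V600E, ...) come from a hotspot
catalog lookup only — hotspots are enumerable, so no general codon
translation engine is needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import encode
from .panel import Panel
from .quantify import AMBIGUOUS, classify_molecules

PASS_FRACTION = 0.10

CALL_COLUMNS = [
    "sample_id",
    "transcript_id",
    "position",
    "ref",
    "alt",
    "depth",
    "alt_count",
    "fraction",
    "passed",
]


class VariantError(ValueError):
    pass


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str, max_len: int) -> int:
    n = min(len(a), len(b), max_len)
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


class _Pileup:
    """Per-sample, per-transcript accumulation of molecule consensus bases."""

    def __init__(self, panel: Panel):
        self.panel = panel
        self.depth: dict[tuple[str, str], np.ndarray] = {}
        self.alt: dict[tuple[str, str], np.ndarray] = {}
        self.indels: dict[tuple[str, str, int, str, str], int] = {}

    def _arrays(self, sample: str, tid: str) -> tuple[np.ndarray, np.ndarray]:
        key = (sample, tid)
        if key not in self.depth:
            n = len(self.panel.transcripts[tid].seq)
            self.depth[key] = np.zeros(n, dtype=np.int64)
            self.alt[key] = np.zeros((4, n), dtype=np.int64)
        return self.depth[key], self.alt[key]

    def add_matching(
        self,
        sample: str,
        tid: str,
        gap: str,
        ref: str,
        posmap: np.ndarray,
        count: int,
    ) -> None:
        depth, alt = self._arrays(sample, tid)
        g = encode(gap)
        r = encode(ref)
        valid = g < 4  # N bases carry no evidence and no depth
        depth[posmap[valid]] += count
        mism = valid & (g != r)
        if mism.any():
            alt[g[mism], posmap[mism]] += count

    def add_indel(
        self,
        sample: str,
        tid: str,
        gap: str,
        ref: str,
        posmap: np.ndarray,
        count: int,
    ) -> bool:
        """Realign a length-deviating gap-fill; returns False if unresolvable."""
        p = _common_prefix(gap, ref)
        diff = len(gap) - len(ref)
        if p == 0:
            return False  # no anchor base before the event
        p = min(p, min(len(gap), len(ref)))
        anchor = p - 1
        if diff > 0:  # insertion
            inserted = gap[p : p + diff]
            reduced = gap[:p] + gap[p + diff :]
            if len(reduced) != len(ref):
                return False
            ref_allele = ref[anchor]
            alt_allele = ref[anchor] + inserted
            self.add_matching(sample, tid, reduced, ref, posmap, count)
        else:  # deletion
            d = -diff
            deleted = ref[p : p + d]
            ref_allele = ref[anchor] + deleted
            alt_allele = ref[anchor]
            kept = np.concatenate([posmap[:p], posmap[p + d :]])
            reduced_ref = ref[:p] + ref[p + d :]
            if len(gap) != len(reduced_ref):
                return False
            self.add_matching(sample, tid, gap, reduced_ref, kept, count)
        pos = int(posmap[anchor])
        key = (sample, tid, pos, ref_allele, alt_allele)
        self.indels[key] = self.indels.get(key, 0) + count
        return True


def call_variants(
    molecules: pd.DataFrame,
    panel: Panel,
    min_fraction: float = PASS_FRACTION,
    k: int = 10,
) -> pd.DataFrame:
    """Call substitutions and short indels from molecule consensus pileups.

    Junction-probe molecules are compared against the splice form their
    junction k-mer identifies (ambiguous molecules are excluded from
    evidence).  The pass flag applies the strict ``fraction > min_fraction``
    rule; the default reproduces the >10%-of-unique-reads reporting filter.
    """
    pile = _Pileup(panel)
    if len(molecules) == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)
    classified = classify_molecules(molecules, panel, k=k)
    defs = panel.isoform_defs
    groups = classified.groupby(
        ["sample_id", "probe_id", "isoform_label", "gapfill"], sort=True
    ).size()
    form_cache: dict[tuple[str, str], tuple[str, np.ndarray] | None] = {}
    for (sample, probe_id, label, gap), count in groups.items():
        probe = panel.probe(probe_id)
        if probe.junction_targets:
            if label == AMBIGUOUS:
                continue
            _, u, d = defs[label]
            cache_key = (probe_id, label)
            if cache_key not in form_cache:
                form_cache[cache_key] = panel.effective_gapfill(probe, (u, d))
        else:
            cache_key = (probe_id, "")
            if cache_key not in form_cache:
                form_cache[cache_key] = panel.effective_gapfill(probe, None)
        form = form_cache[cache_key]
        if form is None:
            continue
        ref, posmap = form
        tid = probe.transcript_id
        if len(gap) == len(ref):
            pile.add_matching(sample, tid, gap, ref, posmap, int(count))
        else:
            pile.add_indel(sample, tid, gap, ref, posmap, int(count))

    rows = []
    for (sample, tid), alt_counts in pile.alt.items():
        depth = pile.depth[(sample, tid)]
        seq = panel.transcripts[tid].seq
        bases, positions = np.nonzero(alt_counts)
        for b, pos in zip(bases, positions):
            cnt = int(alt_counts[b, pos])
            dep = int(depth[pos])
            frac = cnt / dep if dep else 0.0
            rows.append(
                (
                    sample,
                    tid,
                    int(pos),
                    seq[pos],
                    "ACGT"[b],
                    dep,
                    cnt,
                    frac,
                    frac > min_fraction,
                )
            )
    for (sample, tid, pos, ref_a, alt_a), cnt in pile.indels.items():
        dep = int(pile.depth[(sample, tid)][pos])
        frac = cnt / dep if dep else 0.0
        rows.append((sample, tid, pos, ref_a, alt_a, dep, cnt, frac, frac > min_fraction))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls.sort_values(
        ["sample_id", "transcript_id", "position", "alt"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# hotspot catalog
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = ["transcript_id", "position", "ref", "alt", "label", "gene", "note"]


def load_catalog(path) -> pd.DataFrame:
    cat = pd.read_csv(path, sep="\t", dtype={"position": int})
    missing = [c for c in CATALOG_COLUMNS[:6] if c not in cat.columns]
    if missing:
        raise VariantError(f"hotspot catalog missing columns: {missing}")
    if cat["label"].duplicated().any():
        raise VariantError("hotspot labels must be unique")
    return cat


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def annotate_hotspots(calls: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Attach protein-level labels to calls matching a catalog entry.

    Non-catalog calls carry a transcript-coordinate c.-style description
    (1-based position) instead.
    """
    key = ["transcript_id", "position", "ref", "alt"]
    merged = calls.merge(
        catalog[key + ["label", "gene"]], on=key, how="left", validate="m:1"
    )
    fallback = (
        merged["transcript_id"]
        + ":c."
        + (merged["position"] + 1).astype(str)
        + merged["ref"]
        + ">"
        + merged["alt"]
    )
    merged["annotation"] = merged["label"].fillna(fallback)
    merged["is_hotspot"] = merged["label"].notna()
    return merged.drop(columns=["label"])


# ---------------------------------------------------------------------------
# expression-mutation coupling
# ---------------------------------------------------------------------------

IDH_GENES = ("IDH1", "IDH2")


def integrate_profile(
    expression: pd.DataFrame,
    annotated_calls: pd.DataFrame,
    catalog: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-sample expression with per-hotspot mutation status.

    One row per sample: the expression vector, one mut/wt column per catalog
    hotspot (mut iff a *passing* call matches the hotspot), and the derived
    IDH status (mut iff any passing IDH1/IDH2 hotspot is present).  Samples
    appearing in the calls but not in the expression matrix (or vice versa
    when the calls carry an explicit sample set) are an error.
    """
    expr_samples = set(expression.index)
    call_samples = set(annotated_calls["sample_id"]) if len(annotated_calls) else set()
    stray = sorted(call_samples - expr_samples)
    if stray:
        raise VariantError(
            f"samples present in variant calls but not in expression: {stray}"
        )
    profiles = expression.copy()
    passing = (
        annotated_calls[
            annotated_calls["passed"] & annotated_calls.get("is_hotspot", False)
        ]
        if len(annotated_calls)
        else annotated_calls
    )
    for _, h in catalog.iterrows():
        label = h["label"]
        mut = (
            set(passing.loc[passing["annotation"] == label, "sample_id"])
            if len(passing)
            else set()
        )
        profiles[label] = [
            "mut" if s in mut else "wt" for s in profiles.index
        ]
    idh_labels = list(catalog.loc[catalog["gene"].isin(IDH_GENES), "label"])
    if idh_labels:
        profiles["IDH_status"] = np.where(
            (profiles[idh_labels] == "mut").any(axis=1), "mut", "wt"
        )
    else:
        profiles["IDH_status"] = "wt"
    return profiles


def calls_to_vcf(calls: pd.DataFrame, panel: Panel, path) -> None:
    """Export calls as a minimal transcript-space VCF (contig = transcript)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for tid, t in panel.transcripts.items():
            fh.write(f"##contig=<ID={tid},length={len(t.seq)}>\n")
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Unique molecule depth">\n'
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt unique fraction">\n'
            '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample id">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in calls.itertuples(index=False):
            filt = "PASS" if row.passed else "lowFraction"
            fh.write(
                f"{row.transcript_id}\t{row.position + 1}\t.\t{row.ref}\t{row.alt}"
                f"\t.\t{filt}\tDP={row.depth};AF={row.fraction:.4f};"
                f"SAMPLE={row.sample_id}\n"
            )
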