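"""Unique-molecule counting, FPM normalisation and isoform quantification.

The UMI makes the assay quantitative: all reads sharing (sample, probe, UMI)
derive from one circularised probe, so collapsing on that key removes PCR
amplification bias.  Per-probe unique counts are normalised to the sample's
total unique count and expressed as fragments per million (FPM); the mean
FPM over all probes of a transcript — including probes that captured zero
molecules — represents the transcript's expression level.

Junction-resolved isoforms are quantified by exact junction k-mer matching
inside each molecule's consensus gap-fill: a probe whose ROI holds two
alternative exon boundaries yields per-isoform molecule counts from a single
capture, on the same per-million denominator as every other probe.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import encode
from .panel import Panel

#: FPM below which an EGFRvIII junction signal is considered negative
EGFRVIII_FPM_THRESHOLD = 5.0

AMBIGUOUS = "ambiguous"


class QuantifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# UMI collapse
# ---------------------------------------------------------------------------


def _consensus(seq_counts: list[tuple[str, int]]) -> str:
    """Per-position weighted majority across supporting reads.

    Reads of the modal gap-fill length (ties: shortest) vote position-wise;
    ``N`` never votes and voting ties are masked to ``N``.
    """
    length_w = Counter()
    for seq, c in seq_counts:
        length_w[len(seq)] += c
    top = max(length_w.values())
    length = min(l for l, w in length_w.items() if w == top)
    votes = [(encode(s), c) for s, c in seq_counts if len(s) == length]
    counts = np.zeros((4, length), dtype=np.int64)
    for codes, c in votes:
        valid = codes < 4
        counts[codes[valid], np.flatnonzero(valid)] += c
    best = counts.max(axis=0)
    arg = counts.argmax(axis=0)
    n_best = (counts == best).sum(axis=0)
    out = np.where((best > 0) & (n_best == 1), arg, 4).astype(np.uint8)
    from ._util import decode

    return decode(out)


def collapse_molecules(captured: pd.DataFrame) -> pd.DataFrame:
    """Collapse captured reads into unique molecules on (sample, probe, UMI).

    Returns one row per molecule with its consensus gap-fill and read
    support.  Idempotent: collapsing the output again changes nothing.
    """
    cols = ["sample_id", "probe_id", "umi", "gapfill", "support"]
    if len(captured) == 0:
        return pd.DataFrame(columns=cols)
    support = captured.get("support", pd.Series(1, index=captured.index))
    work = captured.assign(_n=support).groupby(
        ["sample_id", "probe_id", "umi", "gapfill"], sort=True, as_index=False
    )["_n"].sum()
    key = ["sample_id", "probe_id", "umi"]
    sizes = work.groupby(key, sort=False)["gapfill"].transform("size")
    simple = work[sizes == 1].rename(columns={"_n": "support"})
    rows = [simple[cols]] if len(simple) else []
    multi = work[sizes > 1]
    if len(multi):
        agg = []
        for (s, p, u), grp in multi.groupby(key, sort=False):
            seq = _consensus(list(zip(grp["gapfill"], grp["_n"])))
            agg.append((s, p, u, seq, int(grp["_n"].sum())))
        rows.append(pd.DataFrame(agg, columns=cols))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=cols)
    return out.sort_values(key, ignore_index=True)


# ---------------------------------------------------------------------------
# FPM
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Per-(sample, probe) unique counts and FPM, plus per-sample totals."""

    counts: pd.DataFrame  # sample_id, probe_id, unique_count, fpm
    totals: pd.Series  # sample_id -> total unique count

    def fpm_wide(self, probe_ids=None) -> pd.DataFrame:
        """samples x probes FPM matrix (absent probes = 0)."""
        wide = self.counts.pivot_table(
            index="sample_id", columns="probe_id", values="fpm", fill_value=0.0
        )
        if probe_ids is not None:
            wide = wide.reindex(columns=probe_ids, fill_value=0.0)
        return wide


def fpm_normalize(molecules: pd.DataFrame, samples=None) -> CountTable:
    """Normalise unique counts to fragments per million per sample.

    FPM = unique count / sample total unique count * 1e6, so per-sample FPM
    sums to one million.  A sample named in ``samples`` with no molecules at
    all is a hard error (the normalisation is undefined for it).
    """
    counts = (
        molecules.groupby(["sample_id", "probe_id"], as_index=False)
        .size()
        .rename(columns={"size": "unique_count"})
    )
    totals = counts.groupby("sample_id")["unique_count"].sum()
    if samples is not None:
        empty = [s for s in samples if totals.get(s, 0) == 0]
        if empty:
            raise QuantifyError(
                f"zero unique molecules for sample(s) {empty}: FPM undefined"
            )
    counts["fpm"] = (
        counts["unique_count"] / counts["sample_id"].map(totals) * 1e6
    )
    return CountTable(counts=counts, totals=totals)


def gene_expression(count_table: CountTable, panel: Panel) -> pd.DataFrame:
    """samples x transcripts matrix of mean FPM over each transcript's probes.

    Probes that captured zero molecules contribute zeros to the mean (dropout
    is signal, and excluding it would inflate the mean); junction probes
    count like any other probe of their transcript.
    """
    known = set(panel.probe_ids)
    seen = set(count_table.counts["probe_id"])
    unknown = sorted(seen - known)
    if unknown:
        raise QuantifyError(f"probes absent from the panel: {unknown}")
    wide = count_table.fpm_wide(probe_ids=panel.probe_ids)
    probe_to_tid = {p.probe_id: p.transcript_id for p in panel.smmips}
    return (
        wide.T.groupby(probe_to_tid)
        .mean()
        .T.rename_axis(index="sample_id", columns="transcript_id")
    )


# ---------------------------------------------------------------------------
# junction-resolved isoforms
# ---------------------------------------------------------------------------


def classify_molecules(
    molecules: pd.DataFrame, panel: Panel, k: int = 10
) -> pd.DataFrame:
    """Label each junction-probe molecule with the isoform its gap-fill shows.

    A molecule is assigned the unique junction target whose boundary 2k-mer
    occurs in its consensus gap-fill; no match or more than one match is
    ``ambiguous``.  Molecules of probes without junction targets get an empty
    label.  Returns the input with an ``isoform_label`` column.
    """
    labels = pd.Series("", index=molecules.index, dtype=object)
    for probe in panel.smmips:
        if not probe.junction_targets:
            continue
        mask = molecules["probe_id"] == probe.probe_id
        if not mask.any():
            continue
        kmers = [
            (label, panel.junction_kmer(probe.transcript_id, u, d, k=k))
            for u, d, label in probe.junction_targets
        ]
        distinct = molecules.loc[mask, "gapfill"].unique()
        mapping = {}
        for seq in distinct:
            hits = [label for label, kmer in kmers if kmer in seq]
            mapping[seq] = hits[0] if len(hits) == 1 else AMBIGUOUS
        labels.loc[mask] = molecules.loc[mask, "gapfill"].map(mapping)
    return molecules.assign(isoform_label=labels)


@dataclass
class IsoformResult:
    """Per-sample isoform molecule counts, FPM and classification flags."""

    counts: pd.DataFrame  # samples x isoform labels (unique molecules)
    fpm: pd.DataFrame  # samples x isoform labels
    ambiguous: pd.Series  # per-sample molecules matching no unique junction
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)


def isoform_quantify(
    molecules: pd.DataFrame,
    panel: Panel,
    k: int = 10,
    egfrviii_threshold: float = EGFRVIII_FPM_THRESHOLD,
) -> IsoformResult:
    """Quantify junction-resolved isoforms on the per-sample FPM scale.

    Isoform FPM shares the sample's total-unique-count denominator with the
    probe-level table.  If the panel defines an ``EGFRvIII`` label, each
    sample is flagged positive iff its EGFRvIII FPM is at or above the
    negativity threshold (below 5 FPM is considered negative).
    """
    all_labels = sorted(panel.isoform_defs)
    samples = sorted(molecules["sample_id"].unique())
    classified = classify_molecules(molecules, panel, k=k)
    totals = molecules.groupby("sample_id").size()
    junction = classified[classified["isoform_label"] != ""]
    counts = (
        junction[junction["isoform_label"] != AMBIGUOUS]
        .groupby(["sample_id", "isoform_label"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=samples, columns=all_labels, fill_value=0)
    )
    ambiguous = (
        junction[junction["isoform_label"] == AMBIGUOUS]
        .groupby("sample_id")
        .size()
        .reindex(samples, fill_value=0)
    )
    fpm = counts.div(totals.reindex(samples), axis=0) * 1e6
    flags = pd.DataFrame(index=counts.index)
    if "EGFRvIII" in all_labels:
        flags["EGFRvIII_positive"] = fpm["EGFRvIII"] >= egfrviii_threshold
    return IsoformResult(counts=counts, fpm=fpm, ambiguous=ambiguous, flags=flags)
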