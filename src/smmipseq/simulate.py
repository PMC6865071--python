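"""Truth-annotated synthetic smMIP sequencing runs and cohorts.

This module is the test bed for the whole pipeline: it generates panels,
per-sample molecule truths, read-level libraries and pooled multi-sample
cohorts in which every downstream quantity (molecule counts, isoform
fractions, allele fractions, cluster labels, survival times) has a known
answer.

The capture model follows the assay's chemistry: the number of circularised
probes is linear in the number of target RNA molecules, so per-probe captured
molecule counts are Poisson with mean equal to the sample's transcript
abundance (in expected molecules per probe).  Each captured molecule receives
a random 8-nt UMI (collisions are possible and deliberately not prevented),
is PCR-amplified by an iid geometric duplication factor, and emitted as an
overlapping read pair with uniform substitution errors.

Amplicon layout (recorded in output manifests)::

    barcode(8) | ligation arm | gap-fill | extension arm | UMI(8)

Read 1 is the first ``read_len`` bases of the amplicon; read 2 is the
reverse complement of the last ``read_len`` bases, so the mates overlap in
the middle whenever the amplicon is shorter than twice the read length.

Randomness discipline: every stream descends from the single run seed via
``numpy`` seed sequences.  Molecule-level draws (counts, isoform choices,
variant status, UMIs) and amplification-level draws (duplication factors,
sequencing errors) use separate child streams, so changing the duplication
or error settings never changes which molecules exist — the property the
deduplication contract is tested against.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import decode, decode_rows, encode, random_dna, revcomp_codes
from .panel import Panel, SmMIP, Transcript

CANONICAL = "canonical"


class SimulationError(ValueError):
    """Raised for inconsistent simulation designs or layouts."""


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

# GF(4) multiplication table (addition is XOR)
_GF4_MUL = np.array(
    [[0, 0, 0, 0], [0, 1, 2, 3], [0, 2, 3, 1], [0, 3, 1, 2]], dtype=np.uint8
)

# parity-check columns: pairwise linearly independent points of GF(4)^3
_PCHECK = np.array(
    [
        [0, 0, 1],
        [0, 1, 0],
        [0, 1, 1],
        [0, 1, 2],
        [0, 1, 3],
        [1, 0, 0],
        [1, 0, 1],
        [1, 0, 2],
    ],
    dtype=np.uint8,
).T  # shape (3, 8)


def make_barcodes(n: int, length: int = 8, seed: int | None = None) -> list[str]:
    """Generate ``n`` sample barcodes with pairwise Hamming distance >= 3.

    Barcodes are the codewords of a shortened Hamming-type linear code over
    GF(4) (parity-check columns pairwise linearly independent, hence minimum
    distance 3), which supports demultiplexing at one mismatch of tolerance.
    For the default length 8 the code has 1024 words, comfortably above the
    400 samples a pooled run must accommodate.  With ``seed`` the selection
    among codewords is shuffled; otherwise the first ``n`` are returned.
    """
    if length != _PCHECK.shape[1]:
        raise SimulationError(f"barcode length {length} not supported (use 8)")
    digits = np.indices((4,) * length).reshape(length, -1).T.astype(np.uint8)
    syndrome = np.zeros((digits.shape[0], 3), dtype=np.uint8)
    for r in range(3):
        acc = np.zeros(digits.shape[0], dtype=np.uint8)
        for i in range(length):
            acc ^= _GF4_MUL[_PCHECK[r, i]][digits[:, i]]
        syndrome[:, r] = acc
    words = digits[(syndrome == 0).all(axis=1)]
    if n > len(words):
        raise SimulationError(f"cannot provide {n} barcodes (max {len(words)})")
    if seed is not None:
        words = words[np.random.default_rng(seed).permutation(len(words))]
    return decode_rows(words[:n])


# ---------------------------------------------------------------------------
# synthetic panels
# ---------------------------------------------------------------------------


def synthetic_panel(
    genes: list[str] | None = None,
    probes_per_transcript: int = 5,
    arm_len: int = 25,
    gapfill_len: int = 200,
    include_egfrviii: bool = True,
    include_ca12: bool = True,
    include_vegfa: bool = False,
    max_gapfill: int = 210,
    seed: int = 0,
) -> Panel:
    """Build a randomized but structurally faithful smMIP panel.

    Every transcript gets ``probes_per_transcript`` evenly spaced probes with
    ``arm_len``-nt arms flanking ``gapfill_len``-nt ROIs (a 266-nt amplicon
    with 8-nt barcode and UMI at the defaults).  Optionally adds the panel's
    signature junction probes:

    * an EGFR-like gene with an exon-1/8 junction probe that captures only
      the exon-skipping EGFRvIII form (the canonical gap-fill far exceeds
      capacity),
    * a CA12-like gene whose single junction probe spans both the exon-8/9
      and exon-8/10 boundaries (exon 9 is 33 nt), resolving both isoforms,
    * a VEGFA-like gene with three isoform probes on exons 5/6, 5/7 and 5/8.
    """
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:03d}" for i in range(1, 9)]
    transcripts: dict[str, Transcript] = {}
    smmips: list[SmMIP] = []

    def add_regular_probes(t: Transcript, start: int, n: int, prefix: str) -> None:
        pos = start
        for i in range(1, n + 1):
            rs, re = pos, pos + gapfill_len
            smmips.append(
                SmMIP(
                    probe_id=f"{prefix}_{i:02d}",
                    transcript_id=t.transcript_id,
                    ligation_arm=t.seq[rs - arm_len : rs],
                    extension_arm=t.seq[re : re + arm_len],
                    roi_start=rs,
                    roi_end=re,
                )
            )
            pos = re + 2 * arm_len  # leave both flanks probe-specific

    def regular_transcript(gene: str) -> Transcript:
        tid = f"{gene}_T"
        length = arm_len + probes_per_transcript * (gapfill_len + 2 * arm_len) + 20
        t = Transcript(tid, random_dna(rng, length), (length,), gene)
        transcripts[tid] = t
        add_regular_probes(t, arm_len, probes_per_transcript, gene)
        return t

    for gene in genes:
        regular_transcript(gene)

    if include_egfrviii:
        # exon1=150, exons 2-7 = 120 each, long exon 8 carrying regular probes
        tail = probes_per_transcript * (gapfill_len + 2 * arm_len) + 200
        ends = (150, 270, 390, 510, 630, 750, 870, 870 + tail)
        t = Transcript("EGFR_T", random_dna(rng, ends[-1]), ends, "EGFR")
        transcripts[t.transcript_id] = t
        rs, re = 50, 970  # 100 nt in exon 1 + 100 nt in exon 8
        smmips.append(
            SmMIP(
                probe_id="EGFR_vIII_jx",
                transcript_id=t.transcript_id,
                ligation_arm=t.seq[rs - arm_len : rs],
                extension_arm=t.seq[re : re + arm_len],
                roi_start=rs,
                roi_end=re,
                junction_targets=((1, 8, "EGFRvIII"),),
            )
        )
        add_regular_probes(t, 1000, probes_per_transcript, "EGFR")

    if include_ca12:
        # exons 1-7 = 60 each, exon 8 = 200, tiny exon 9 = 33, long exon 10
        tail = probes_per_transcript * (gapfill_len + 2 * arm_len) + 400
        ends = (60, 120, 180, 240, 300, 360, 420, 620, 653, 653 + tail)
        t = Transcript("CA12_T", random_dna(rng, ends[-1]), ends, "CA12")
        transcripts[t.transcript_id] = t
        rs, re = 620 - 84, 653 + 83  # 84 nt exon 8 + exon 9 (33) + 83 nt exon 10
        smmips.append(
            SmMIP(
                probe_id="CA12_jx",
                transcript_id=t.transcript_id,
                ligation_arm=t.seq[rs - arm_len : rs],
                extension_arm=t.seq[re : re + arm_len],
                roi_start=rs,
                roi_end=re,
                junction_targets=((8, 9, "CA12v1"), (8, 10, "CA12v2")),
            )
        )
        add_regular_probes(t, 800, probes_per_transcript, "CA12")

    if include_vegfa:
        # exons 1-5 = 80 each, exon 6 = 72, exon 7 = 132, long exon 8
        tail = probes_per_transcript * (gapfill_len + 2 * arm_len) + 400
        ends = (80, 160, 240, 320, 400, 472, 604, 604 + tail)
        t = Transcript("VEGFA_T", random_dna(rng, ends[-1]), ends, "VEGFA")
        transcripts[t.transcript_id] = t
        for label, d, re_off in (("VEGFA_189", 6, None), ("VEGFA_165", 7, None), ("VEGFA_121", 8, None)):
            start_d = t.exon_start(d)
            rs = 400 - 100
            re = start_d + (gapfill_len - 100) if d > 6 else 400 + (gapfill_len - 100)
            smmips.append(
                SmMIP(
                    probe_id=f"VEGFA_{d}_jx",
                    transcript_id=t.transcript_id,
                    ligation_arm=t.seq[rs - arm_len : rs],
                    extension_arm=t.seq[re : re + arm_len],
                    roi_start=rs,
                    roi_end=re,
                    junction_targets=((5, d, label),),
                )
            )
        add_regular_probes(t, 700, probes_per_transcript, "VEGFA")

    return Panel(smmips=smmips, transcripts=transcripts, max_gapfill=max_gapfill)


def hotspot_catalog(panel: Panel) -> pd.DataFrame:
    """Synthetic hotspot catalog aligned with a synthetic panel.

    For each of the classic marker genes present in the panel, places one
    hotspot substitution in the middle of the gene's first regular probe ROI,
    labelled with the field's protein-level shorthand.  Returned as the
    catalog table the variants module loads (transcript_id, position, ref,
    alt, label, gene, note).
    """
    labels = {"IDH1": "IDH1-R132H", "IDH2": "IDH2-R172K", "BRAF": "BRAF-V600E"}
    rows = []
    gm = panel.gene_map
    for probe in panel.smmips:
        gene = gm[probe.transcript_id]
        if gene not in labels or probe.junction_targets:
            continue
        t = panel.transcripts[probe.transcript_id]
        pos = (probe.roi_start + probe.roi_end) // 2
        ref = t.seq[pos]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        rows.append(
            {
                "transcript_id": probe.transcript_id,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "label": labels.pop(gene),
                "gene": gene,
                "note": "synthetic hotspot",
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "position", "ref", "alt", "label", "gene", "note"]
    )


# ---------------------------------------------------------------------------
# design / truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """A planted transcript variant (substitution or short indel, VCF-style
    ref/alt with a shared leading base for indels)."""

    transcript_id: str
    position: int
    ref: str
    alt: str
    allele_fraction: float
    exact: bool = False  # floor(af * n) alt molecules instead of Binomial(n, af)
    label: str | None = None
    carrier_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.allele_fraction <= 1.0):
            raise SimulationError(
                f"allele fraction {self.allele_fraction} outside [0, 1]"
            )

    @property
    def key(self) -> str:
        return f"{self.transcript_id}:{self.position}:{self.ref}>{self.alt}"


@dataclass
class GroupSpec:
    """One cohort group: size, expression effects, variants, survival hazard."""

    name: str
    n_samples: int
    abundance_mult: dict[str, float] = field(default_factory=dict)
    variants: list[VariantSpec] = field(default_factory=list)
    isoform_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    survival_scale_days: float = 1000.0


@dataclass
class CohortDesign:
    """Cohort-level simulation design.

    ``base_abundance`` is the expected number of captured molecules per smMIP
    per transcript in a reference sample; group multipliers and a per-sample
    log-normal jitter (``sample_sigma`` on the log scale) modulate it.
    """

    base_abundance: dict[str, float]
    groups: list[GroupSpec]
    isoform_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    sample_sigma: float = 0.15
    censor_scale_days: float | None = 5000.0

    def validate(self) -> None:
        for tid, a in self.base_abundance.items():
            if a < 0:
                raise SimulationError(f"abundance for {tid} negative")
        for fractions in list(self.isoform_fractions.values()) + [
            f for g in self.groups for f in g.isoform_fractions.values()
        ]:
            total = sum(fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(
                    f"isoform fractions {fractions} sum to {total}, not 1"
                )


@dataclass
class SampleTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    group: str
    abundance: dict[str, float]  # transcript -> expected molecules per probe
    isoform_fractions: dict[str, dict[str, float]]
    variants: list[VariantSpec]
    survival_days: float
    event: bool


def _as_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_sample_truth(design: CohortDesign, seed) -> list[SampleTruth]:
    """Draw the per-sample truth tables for a cohort design (reproducible)."""
    design.validate()
    rng = _as_rng(seed)
    truths: list[SampleTruth] = []
    i = 0
    for group in design.groups:
        for _ in range(group.n_samples):
            i += 1
            sample_id = f"S{i:03d}"
            abundance = {
                tid: base
                * group.abundance_mult.get(tid, 1.0)
                * (rng.lognormal(0.0, design.sample_sigma) if design.sample_sigma else 1.0)
                for tid, base in sorted(design.base_abundance.items())
            }
            fractions = {**design.isoform_fractions, **group.isoform_fractions}
            variants = [
                v
                for v in group.variants
                if v.carrier_fraction >= 1.0 or rng.random() < v.carrier_fraction
            ]
            t = rng.exponential(group.survival_scale_days)
            event = True
            if design.censor_scale_days is not None:
                c = rng.exponential(design.censor_scale_days)
                event = t <= c
                t = min(t, c)
            truths.append(
                SampleTruth(
                    sample_id=sample_id,
                    group=group.name,
                    abundance=abundance,
                    isoform_fractions=fractions,
                    variants=variants,
                    survival_days=float(t),
                    event=bool(event),
                )
            )
    return truths


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Sequencing-run layout and noise model.

    The defaults mirror the assay this package models: 266-nt amplicons with
    an 8-nt sample barcode and 8-nt UMI, sequenced as overlapping 2x151
    pairs.  ``mean_duplication`` is the mean of the per-molecule geometric
    PCR duplication factor (1 = no duplication); ``error_rate`` is the
    uniform per-base substitution probability applied to each emitted read.
    """

    read_len: int = 151
    umi_len: int = 8
    barcode_len: int = 8
    amplicon_len: int = 266
    mean_duplication: float = 3.0
    error_rate: float = 0.001
    min_overlap: int = 10
    #: draw per-probe UMIs without replacement.  Collisions are a real
    #: feature of 8-mer UMIs and are simulated by default; this switch gives
    #: the deterministic-depth regime used to verify exact count boundaries.
    collision_free_umis: bool = False

    def __post_init__(self) -> None:
        if self.umi_len != 8:
            raise SimulationError("the assay's UMI is a fixed random 8-mer")
        if self.mean_duplication < 1.0:
            raise SimulationError("mean duplication factor must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise SimulationError("error rate must be in [0, 1)")

    @property
    def max_amplicon(self) -> int:
        return 2 * self.read_len - self.min_overlap

    def to_dict(self) -> dict:
        return {
            "read_len": self.read_len,
            "umi_len": self.umi_len,
            "barcode_len": self.barcode_len,
            "amplicon_len": self.amplicon_len,
            "mean_duplication": self.mean_duplication,
            "error_rate": self.error_rate,
            "min_overlap": self.min_overlap,
            "layout": "barcode|ligation_arm|gapfill|extension_arm|umi",
        }


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------


@dataclass
class Library:
    """An in-memory simulated library: read matrices plus truth tables."""

    sample_id: str
    r1: np.ndarray  # (n_reads, read_len) uint8 codes
    r2: np.ndarray
    read_ids: list[str]
    truth_reads: pd.DataFrame  # read_id, sample_id, probe_id, molecule_id, umi, isoform, variants
    truth_molecules: pd.DataFrame  # sample_id, probe_id, molecule_id, umi, isoform, variants, duplication

    @property
    def n_reads(self) -> int:
        return self.r1.shape[0]


def _isoform_junction(
    panel: Panel, gene: str, label: str
) -> tuple[int, int] | None:
    if label == CANONICAL:
        return None
    defs = panel.isoform_defs
    if label not in defs:
        raise SimulationError(f"isoform label {label} not defined by the panel")
    _, u, d = defs[label]
    return (u, d)


def _apply_variant(
    seq: str, posmap: np.ndarray, v: VariantSpec
) -> tuple[str, np.ndarray] | None:
    """Apply a variant to a gap-fill, or None if the ref span is not retained."""
    n = len(v.ref)
    idx = int(np.searchsorted(posmap, v.position))
    if idx >= len(posmap) or posmap[idx] != v.position:
        return None
    if idx + n > len(posmap) or posmap[idx + n - 1] != v.position + n - 1:
        return None
    if seq[idx : idx + n] != v.ref:
        raise SimulationError(
            f"variant {v.key}: reference allele mismatch in gap-fill"
        )
    new_seq = seq[:idx] + v.alt + seq[idx + n :]
    new_map = np.concatenate(
        [posmap[:idx], np.full(len(v.alt), -1, dtype=posmap.dtype), posmap[idx + n :]]
    )
    return new_seq, new_map


def simulate_library(
    truth: SampleTruth,
    panel: Panel,
    run: RunConfig,
    seed,
    barcode: str = "ACGTACGT",
) -> Library:
    """Emit the read pairs of one sample, with a complete per-read truth table.

    Molecule-level randomness and amplification-level randomness come from
    separate child streams of ``seed`` (see module docstring), so molecule
    identities are invariant to duplication and error settings.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    rng_mol, rng_amp = (np.random.default_rng(c) for c in ss.spawn(2))
    if len(barcode) != run.barcode_len:
        raise SimulationError("barcode length inconsistent with run layout")
    bc_codes = encode(barcode)
    gene_map = panel.gene_map

    r1_blocks: list[np.ndarray] = []
    r2_blocks: list[np.ndarray] = []
    mol_rows: list[pd.DataFrame] = []
    dup_per_mol: list[np.ndarray] = []
    mol_counter = 0

    for probe in panel.smmips:
        lam = truth.abundance.get(probe.transcript_id, 0.0)
        if lam <= 0:
            continue
        gene = gene_map[probe.transcript_id]
        fractions = truth.isoform_fractions.get(gene)
        n_total = int(rng_mol.poisson(lam))
        if fractions:
            labels = sorted(fractions)
            counts = rng_mol.multinomial(n_total, [fractions[l] for l in labels])
            allocation = list(zip(labels, counts))
        else:
            allocation = [(CANONICAL, n_total)]

        if run.collision_free_umis:
            space = 4**run.umi_len
            if n_total > space:
                raise SimulationError(
                    f"probe {probe.probe_id}: {n_total} molecules exceed the "
                    f"UMI space for collision-free mode"
                )
            ints = rng_mol.choice(space, size=n_total, replace=False)
            shifts = 2 * np.arange(run.umi_len - 1, -1, -1)
            probe_umis = ((ints[:, None] >> shifts) & 3).astype(np.uint8)
        else:
            probe_umis = rng_mol.integers(
                0, 4, size=(n_total, run.umi_len), dtype=np.uint8
            )
        umi_offset = 0

        for label, n_label in allocation:
            junction = _isoform_junction(panel, gene, label)
            form = panel.effective_gapfill(probe, junction)
            # isoform choice must be drawn even for non-capturable forms to
            # keep molecule-level streams aligned; such molecules are lost
            if form is None or len(form[0]) > panel.max_gapfill:
                continue
            base_seq, posmap = form
            n_label = int(n_label)
            if n_label == 0:
                continue
            # assign variant status per molecule
            applicable = [
                v for v in truth.variants if v.transcript_id == probe.transcript_id
            ]
            combo_of = np.zeros(n_label, dtype=np.int64)
            combo_variants: dict[int, tuple[VariantSpec, ...]] = {0: ()}
            for k, v in enumerate(applicable):
                if _apply_variant(base_seq, posmap, v) is None:
                    continue
                if v.exact:
                    n_alt = int(np.floor(v.allele_fraction * n_label))
                    flags = np.zeros(n_label, dtype=bool)
                    flags[rng_mol.permutation(n_label)[:n_alt]] = True
                else:
                    flags = rng_mol.random(n_label) < v.allele_fraction
                combo_of = combo_of * 2 + flags
            # enumerate realised combos
            umis = probe_umis[umi_offset : umi_offset + n_label]
            umi_offset += n_label
            visible = [v for v in applicable if _apply_variant(base_seq, posmap, v)]
            for combo in np.unique(combo_of):
                members = np.flatnonzero(combo_of == combo)
                seq, pm = base_seq, posmap
                applied: list[VariantSpec] = []
                for k, v in enumerate(visible):
                    if (combo >> (len(visible) - 1 - k)) & 1:
                        res = _apply_variant(seq, pm, v)
                        if res is None:  # clobbered by an earlier overlapping edit
                            continue
                        seq, pm = res
                        applied.append(v)
                amp_len = (
                    run.barcode_len
                    + len(probe.ligation_arm)
                    + len(seq)
                    + len(probe.extension_arm)
                    + run.umi_len
                )
                if amp_len > run.max_amplicon:
                    raise SimulationError(
                        f"probe {probe.probe_id}: amplicon {amp_len} nt exceeds "
                        f"2 x read length minus the required overlap "
                        f"({run.max_amplicon} nt)"
                    )
                if amp_len < run.read_len:
                    raise SimulationError(
                        f"probe {probe.probe_id}: amplicon {amp_len} nt shorter "
                        f"than the read length {run.read_len}"
                    )
                m = len(members)
                template = np.concatenate(
                    [
                        bc_codes,
                        encode(probe.ligation_arm),
                        encode(seq),
                        encode(probe.extension_arm),
                    ]
                )
                amp = np.empty((m, amp_len), dtype=np.uint8)
                amp[:, : amp_len - run.umi_len] = template
                amp[:, amp_len - run.umi_len :] = umis[members]

                if run.mean_duplication > 1.0:
                    dup = rng_amp.geometric(1.0 / run.mean_duplication, size=m)
                else:
                    dup = np.ones(m, dtype=np.int64)
                reads = np.repeat(amp, dup, axis=0)
                r1 = reads[:, : run.read_len].copy()
                r2 = revcomp_codes(reads[:, amp_len - run.read_len :]).copy()
                for mat in (r1, r2):
                    if run.error_rate > 0:
                        mask = rng_amp.random(mat.shape) < run.error_rate
                        shift = rng_amp.integers(1, 4, size=mat.shape, dtype=np.uint8)
                        mat[mask] = (mat[mask] + shift[mask]) % 4
                r1_blocks.append(r1)
                r2_blocks.append(r2)
                dup_per_mol.append(dup)
                mol_rows.append(
                    pd.DataFrame(
                        {
                            "sample_id": truth.sample_id,
                            "probe_id": probe.probe_id,
                            "molecule_id": np.arange(mol_counter, mol_counter + m),
                            "umi": decode_rows(umis[members]),
                            "isoform": label,
                            "variants": ";".join(v.key for v in applied),
                            "duplication": dup,
                        }
                    )
                )
                mol_counter += m

    read_len = run.read_len
    if r1_blocks:
        r1 = np.vstack(r1_blocks)
        r2 = np.vstack(r2_blocks)
        molecules = pd.concat(mol_rows, ignore_index=True)
        dup_all = np.concatenate(dup_per_mol)
        reads = molecules.loc[
            molecules.index.repeat(dup_all),
            ["sample_id", "probe_id", "molecule_id", "umi", "isoform", "variants"],
        ].reset_index(drop=True)
    else:
        r1 = np.empty((0, read_len), dtype=np.uint8)
        r2 = np.empty((0, read_len), dtype=np.uint8)
        molecules = pd.DataFrame(
            columns=[
                "sample_id",
                "probe_id",
                "molecule_id",
                "umi",
                "isoform",
                "variants",
                "duplication",
            ]
        )
        reads = pd.DataFrame(
            columns=["sample_id", "probe_id", "molecule_id", "umi", "isoform", "variants"]
        )
    read_ids = [f"{truth.sample_id}.{i:07d}" for i in range(len(reads))]
    reads.insert(0, "read_id", read_ids)
    return Library(
        sample_id=truth.sample_id,
        r1=r1,
        r2=r2,
        read_ids=read_ids,
        truth_reads=reads,
        truth_molecules=molecules,
    )


# ---------------------------------------------------------------------------
# pooled cohorts
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    """A pooled multi-sample run plus its complete truth bundle."""

    r1: np.ndarray
    r2: np.ndarray
    read_ids: list[str]
    truths: list[SampleTruth]
    barcode_table: pd.DataFrame  # sample_id, barcode
    truth_reads: pd.DataFrame
    truth_molecules: pd.DataFrame
    clinical: pd.DataFrame  # sample_id, survival_days, event, group
    run: RunConfig
    seed: int

    @property
    def sample_ids(self) -> list[str]:
        return [t.sample_id for t in self.truths]

    def write(self, outdir) -> dict[str, str]:
        """Write FASTQ pair, truth tables and manifest; returns file map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {
            "r1": str(outdir / "pooled_R1.fastq.gz"),
            "r2": str(outdir / "pooled_R2.fastq.gz"),
            "barcodes": str(outdir / "barcodes.tsv"),
            "truth_reads": str(outdir / "truth_reads.tsv"),
            "truth_molecules": str(outdir / "truth_molecules.tsv"),
            "clinical": str(outdir / "clinical.tsv"),
            "manifest": str(outdir / "manifest.json"),
        }
        write_fastq(files["r1"], self.read_ids, self.r1)
        write_fastq(files["r2"], self.read_ids, self.r2)
        self.barcode_table.to_csv(files["barcodes"], sep="\t", index=False)
        self.truth_reads.to_csv(files["truth_reads"], sep="\t", index=False)
        self.truth_molecules.to_csv(files["truth_molecules"], sep="\t", index=False)
        self.clinical.to_csv(files["clinical"], sep="\t", index=False)
        manifest = {
            "seed": self.seed,
            "n_samples": len(self.truths),
            "n_read_pairs": len(self.read_ids),
            "run": self.run.to_dict(),
            "files": {k: Path(v).name for k, v in files.items()},
        }
        with open(files["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2)
        return files


def write_fastq(path, read_ids, codes: np.ndarray) -> None:
    """Write a code matrix as a gzip FASTQ (fixed quality, mtime 0 so repeated
    runs are byte-identical)."""
    qual = "I" * codes.shape[1] if codes.size else ""
    seqs = decode_rows(codes)
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0, compresslevel=2) as gz:
            out = []
            for rid, seq in zip(read_ids, seqs):
                out.append(f"@{rid}\n{seq}\n+\n{qual}\n")
            gz.write("".join(out).encode())


def simulate_cohort(
    design: CohortDesign,
    panel: Panel,
    run: RunConfig,
    seed: int,
    outdir=None,
) -> SimulatedCohort:
    """Simulate a barcoded multi-sample pool (one read-pair file set).

    Samples are assigned distinct barcodes (error if the design exceeds the
    barcode supply), simulated independently from per-sample child seeds, and
    pooled in a seeded random order.
    """
    ss = np.random.SeedSequence(seed)
    n_samples = sum(g.n_samples for g in design.groups)
    barcodes = make_barcodes(min(1024, max(n_samples, 400)))
    if n_samples > len(barcodes):
        raise SimulationError(
            f"{n_samples} samples exceed the {len(barcodes)} available barcodes"
        )
    truth_ss, shuffle_ss, *sample_ss = ss.spawn(2 + n_samples)
    truths = simulate_sample_truth(design, truth_ss)
    libraries = [
        simulate_library(t, panel, run, s, barcode=barcodes[i])
        for i, (t, s) in enumerate(zip(truths, sample_ss))
    ]
    r1 = np.vstack([lib.r1 for lib in libraries])
    r2 = np.vstack([lib.r2 for lib in libraries])
    truth_reads = pd.concat([lib.truth_reads for lib in libraries], ignore_index=True)
    truth_molecules = pd.concat(
        [lib.truth_molecules for lib in libraries], ignore_index=True
    )
    read_ids = [rid for lib in libraries for rid in lib.read_ids]
    perm = np.random.default_rng(shuffle_ss).permutation(len(read_ids))
    r1, r2 = r1[perm], r2[perm]
    read_ids = [read_ids[i] for i in perm]
    barcode_table = pd.DataFrame(
        {"sample_id": [t.sample_id for t in truths], "barcode": barcodes[:n_samples]}
    )
    clinical = pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truths],
            "survival_days": [t.survival_days for t in truths],
            "event": [int(t.event) for t in truths],
            "group": [t.group for t in truths],
        }
    )
    cohort = SimulatedCohort(
        r1=r1,
        r2=r2,
        read_ids=read_ids,
        truths=truths,
        barcode_table=barcode_table,
        truth_reads=truth_reads,
        truth_molecules=truth_molecules,
        clinical=clinical,
        run=run,
        seed=seed,
    )
    if outdir is not None:
        cohort.write(outdir)
    return cohort


# ---------------------------------------------------------------------------
# reusable study designs
# ---------------------------------------------------------------------------


def three_group_design(
    panel: Panel,
    n_per_group: tuple[int, int, int] = (10, 10, 10),
    base_abundance: float = 60.0,
    effect: float = 5.0,
    hazard_ratio: float = 4.0,
    hotspot: pd.DataFrame | None = None,
) -> CohortDesign:
    """A three-cluster glioma-style cohort design.

    Group B carries a hotspot variant (heterozygous, confined to the group),
    a distinct expression programme and long survival; groups A and C share a
    ``hazard_ratio``-fold higher hazard and have their own marker programmes.
    Marker transcripts are drawn deterministically from the panel's regular
    genes; junction genes keep group-specific isoform mixes (CA12v1 absent
    from group B, EGFRvIII present only in group A).
    """
    tids = sorted(panel.transcripts)
    abundance = {tid: base_abundance for tid in tids}
    regular = [
        tid
        for tid in tids
        if panel.gene_map[tid] not in ("EGFR", "CA12", "VEGFA")
    ]
    third = max(1, len(regular) // 3)
    markers_b = regular[:third]
    markers_c = regular[third : 2 * third]
    markers_a = regular[2 * third : 3 * third]

    iso_default: dict[str, dict[str, float]] = {}
    iso_a: dict[str, dict[str, float]] = {}
    iso_b: dict[str, dict[str, float]] = {}
    genes = set(panel.gene_map.values())
    if "EGFR" in genes:
        iso_default["EGFR"] = {CANONICAL: 1.0}
        iso_a["EGFR"] = {CANONICAL: 0.7, "EGFRvIII": 0.3}
    if "CA12" in genes:
        iso_default["CA12"] = {"CA12v1": 0.7, "CA12v2": 0.3}
        iso_b["CA12"] = {"CA12v1": 0.0, "CA12v2": 1.0}

    variants_b: list[VariantSpec] = []
    if hotspot is not None and len(hotspot):
        h = hotspot.iloc[0]
        variants_b.append(
            VariantSpec(
                transcript_id=h["transcript_id"],
                position=int(h["position"]),
                ref=h["ref"],
                alt=h["alt"],
                allele_fraction=0.5,
                label=h["label"],
            )
        )

    scale_long = 1600.0
    scale_short = scale_long / hazard_ratio
    groups = [
        GroupSpec(
            name="A",
            n_samples=n_per_group[0],
            abundance_mult={tid: effect for tid in markers_a},
            isoform_fractions=iso_a,
            survival_scale_days=scale_short,
        ),
        GroupSpec(
            name="B",
            n_samples=n_per_group[1],
            abundance_mult={tid: effect for tid in markers_b},
            variants=variants_b,
            isoform_fractions=iso_b,
            survival_scale_days=scale_long,
        ),
        GroupSpec(
            name="C",
            n_samples=n_per_group[2],
            abundance_mult={tid: effect for tid in markers_c},
            survival_scale_days=scale_short,
        ),
    ]
    return CohortDesign(
        base_abundance=abundance,
        groups=groups,
        isoform_fractions=iso_default,
    )
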