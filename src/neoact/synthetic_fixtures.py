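"""Deterministic synthetic inputs for every pipeline stage.

Real inputs to a neoantigen T-cell therapy study — tumor exomes,
expression tables, clonotype repertoires, lesion measurements — are
patient data under restricted access.  This module generates stand-ins
with the statistical structure the pipeline's rules consume:

* random but internally consistent proteome/CDS FASTA pairs;
* somatic variant tables with right-skewed (Beta-law) allele
  frequencies, including a configurable fraction below the VAF cutoff;
* motif-structured binder peptides for training and challenging the
  built-in PSSM predictor;
* Dirichlet-multinomial clonotype count series with clones spiked to
  expand by programmed folds after infusion (and contract afterwards);
* a trial fixture encoding the published per-patient outcomes and
  adverse-event counts as literal data, with synthetic lesion
  trajectories consistent with each response category.

Every generator is a pure function of :class:`SimConfig`: each draws
from its own seed stream (derived from the master seed by a fixed
label), so repeated calls are byte-identical and adding a generator
never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .clinical_outcomes import AdverseEvent, LesionRecord
from .mhc_binding import AMINO_ACIDS
from .tcr_dynamics import Clonotype, ClonotypeTable
from .variant_peptides import Variant, VariantKind


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic-data generators, seed included."""

    seed: int = 0
    n_genes: int = 50
    n_variants: int = 200
    vaf_beta: tuple[float, float] = (0.3, 3.0)  # right-skewed, mass near 0.01
    sub_threshold_fraction: float = 0.1  # variants forced below the VAF cutoff
    frameshift_fraction: float = 0.1
    inframe_fraction: float = 0.1
    motif_anchors: Mapping[int, str] = field(
        default_factory=lambda: {2: "LM", 9: "KV"})  # 1-based positions
    peptide_length: int = 9
    binder_fraction: float = 0.1
    n_clones: int = 200
    read_depth: int = 100_000
    spiked_folds: tuple[float, ...] = (2.0, 10.0, 100.0)
    timepoints_months: tuple[float, ...] = (-1.0, 1.0, 2.0, 4.0, 6.0)


def _rng(cfg: SimConfig, label: str) -> np.random.Generator:
    """One independent stream per generator, derived from the master seed."""
    return np.random.default_rng([cfg.seed, zlib.crc32(label.encode())])


# --------------------------------------------------------------------------
# Proteome and variants
# --------------------------------------------------------------------------

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
_STOP_CODONS = tuple(sorted(_STANDARD.stop_codons))


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    transcript_id: str
    protein: str
    cds: str


def gen_proteome(cfg: SimConfig) -> list[GeneRecord]:
    """Random genes with consistent protein/CDS pairs (no internal stops)."""
    rng = _rng(cfg, "proteome")
    genes = []
    for i in range(cfg.n_genes):
        length = int(rng.integers(80, 201))
        body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
        protein = "M" + body
        cds = "".join(
            _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))]
            for aa in protein) + _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
        genes.append(GeneRecord(f"GENE{i:04d}", f"TX{i:04d}", protein, cds))
    return genes


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _draw_vaf(rng: np.random.Generator, cfg: SimConfig) -> float:
    if rng.random() < cfg.sub_threshold_fraction:
        return float(rng.uniform(1e-4, 0.01))
    a, b = cfg.vaf_beta
    while True:
        v = float(rng.beta(a, b))
        if v > 0.01:
            return v


def gen_variants(cfg: SimConfig, proteome: Sequence[GeneRecord]) -> list[Variant]:
    """Somatic coding variants over the synthetic proteome.

    Mix of missense, in-frame 3-bp deletions and 1-bp frameshift
    deletions; VAFs are Beta-distributed with a configurable fraction
    forced below the 0.01 cutoff to exercise the strict-inequality edge.
    """
    if not proteome:
        raise ValueError("proteome must be nonempty")
    rng = _rng(cfg, "variants")
    variants = []
    for i in range(cfg.n_variants):
        gene = proteome[rng.integers(len(proteome))]
        vaf = _draw_vaf(rng, cfg)
        vid = f"VAR{i:05d}"
        u = rng.random()
        # keep edits away from the start codon and the stop
        n_codons = len(gene.protein)
        codon_idx = int(rng.integers(2, n_codons))  # 0-based codon, skip Met
        if u < cfg.frameshift_fraction:
            pos = codon_idx * 3 + 1
            variants.append(Variant(vid, gene.gene_id, gene.transcript_id,
                                    VariantKind.FRAMESHIFT, pos,
                                    gene.cds[pos - 1], "", vaf))
        elif u < cfg.frameshift_fraction + cfg.inframe_fraction:
            pos = codon_idx * 3 + 1
            variants.append(Variant(vid, gene.gene_id, gene.transcript_id,
                                    VariantKind.INFRAME_INDEL, pos,
                                    gene.cds[pos - 1:pos + 2], "", vaf))
        else:
            # missense: swap the whole codon for one encoding a different aa
            pos = codon_idx * 3 + 1
            ref_codon = gene.cds[pos - 1:pos + 2]
            ref_aa = gene.protein[codon_idx]
            alt_aa = ref_aa
            while alt_aa == ref_aa:
                alt_aa = AMINO_ACIDS[rng.integers(20)]
            alts = _CODONS_BY_AA[alt_aa]
            alt_codon = alts[rng.integers(len(alts))]
            variants.append(Variant(vid, gene.gene_id, gene.transcript_id,
                                    VariantKind.MISSENSE, pos,
                                    ref_codon, alt_codon, vaf))
    return variants


def variants_to_tsv(variants: Sequence[Variant], path: str | Path) -> None:
    rows = [{"id": v.id, "gene_id": v.gene_id, "transcript_id": v.transcript_id,
             "kind": v.kind.value, "cds_pos": v.cds_pos, "ref_bases": v.ref_bases,
             "alt_bases": v.alt_bases, "vaf": v.vaf} for v in variants]
    # %.17g keeps VAFs bit-exact across a write/read round trip
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.17g")


def read_variants_tsv(path: str | Path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     float_precision="round_trip")
    return [Variant(str(r.id), str(r.gene_id), str(r.transcript_id),
                    VariantKind(r.kind), int(r.cds_pos), str(r.ref_bases),
                    str(r.alt_bases), float(r.vaf)) for r in df.itertuples()]


def gen_expression(cfg: SimConfig, proteome: Sequence[GeneRecord],
                   silent_fraction: float = 0.2) -> dict[str, float]:
    """Gene -> TPM; a fraction of genes fall below the TPM >= 1 cutoff."""
    rng = _rng(cfg, "expression")
    tpm = {}
    for gene in proteome:
        if rng.random() < silent_fraction:
            tpm[gene.gene_id] = float(rng.uniform(0.0, 1.0))
        else:
            tpm[gene.gene_id] = float(rng.lognormal(2.0, 1.0) + 1.0)
    return tpm


# --------------------------------------------------------------------------
# Binder peptides for the PSSM predictor
# --------------------------------------------------------------------------

def gen_binder_set(cfg: SimConfig, allele: str, n: int) -> list[str]:
    """Peptides with fixed anchor residues, uniform elsewhere."""
    if not cfg.motif_anchors:
        raise ValueError("motif_anchors must be nonempty")
    rng = _rng(cfg, f"binders:{allele}")
    peptides = []
    for _ in range(n):
        residues = [AMINO_ACIDS[rng.integers(20)]
                    for _ in range(cfg.peptide_length)]
        for pos, allowed in sorted(cfg.motif_anchors.items()):
            residues[pos - 1] = allowed[rng.integers(len(allowed))]
        peptides.append("".join(residues))
    return peptides


def gen_random_peptides(cfg: SimConfig, n: int, label: str = "decoys") -> list[str]:
    rng = _rng(cfg, label)
    return ["".join(AMINO_ACIDS[rng.integers(20)]
                    for _ in range(cfg.peptide_length)) for _ in range(n)]


# --------------------------------------------------------------------------
# Clonotype repertoire series
# --------------------------------------------------------------------------

def _synthetic_cdr3(rng: np.random.Generator) -> str:
    middle = "".join(AMINO_ACIDS[rng.integers(20)]
                     for _ in range(int(rng.integers(6, 12))))
    return "CASS" + middle + "F"


def gen_clonotype_series(cfg: SimConfig) -> tuple[list[ClonotypeTable],
                                                  list[Clonotype]]:
    """Repertoire count tables across timepoints with programmed expansions.

    Baseline clone frequencies come from a Dirichlet law.  One designated
    clone per entry of ``spiked_folds`` is multiplied by its fold at the
    first two post-infusion timepoints, then contracts (emulating the
    typical expansion-contraction kinetics of transferred clones); counts
    at each timepoint are multinomial at ``read_depth``.  Returns the
    tables and the spiked clones (in ``spiked_folds`` order).
    """
    if cfg.read_depth < 1000:
        raise ValueError("read_depth must be >= 1000")
    rng = _rng(cfg, "clonotypes")
    n = cfg.n_clones
    clones = []
    seen: set[str] = set()
    while len(clones) < n:
        cdr3 = _synthetic_cdr3(rng)
        if cdr3 in seen:
            continue
        seen.add(cdr3)
        clones.append(Clonotype(cdr3, f"TRBV{rng.integers(1, 31)}",
                                f"TRBJ{rng.integers(1, 8)}"))
    base_freq = rng.dirichlet(np.ones(n))
    spiked = list(range(len(cfg.spiked_folds)))
    # spiked clones start rare so large folds stay representable
    for idx in spiked:
        base_freq[idx] = 2e-4
    base_freq /= base_freq.sum()

    tables = []
    timepoints = sorted(cfg.timepoints_months)
    for j, tp in enumerate(timepoints):
        freq = base_freq.copy()
        if j > 0:  # post-baseline
            for idx, fold in zip(spiked, cfg.spiked_folds):
                factor = fold if j <= 2 else fold * 0.2  # later contraction
                freq[idx] = base_freq[idx] * factor
            freq /= freq.sum()
        counts = rng.multinomial(cfg.read_depth, freq)
        table = {clones[i]: int(c) for i, c in enumerate(counts) if c > 0}
        tables.append(ClonotypeTable(tp, table))
    return tables, [clones[i] for i in spiked]


# --------------------------------------------------------------------------
# Trial fixture (published per-patient outcomes)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialFixture:
    patients: pd.DataFrame                  # one row per enrolled patient
    responses: dict[str, str]               # evaluable patients only
    infusions: dict[str, int]
    sd_durations_months: tuple[float, ...]
    ae_events: tuple[AdverseEvent, ...]
    group_sizes: dict[str, int]
    lesions: dict[str, tuple[LesionRecord, ...]]


def _load_data_csv(name: str) -> pd.DataFrame:
    with resources.files("neoact.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def _lesion_series(pid: str, category: str,
                   duration: float | None) -> tuple[LesionRecord, ...]:
    """Deterministic target-lesion trajectory matching a response category."""
    def rec(tp: float, mm: float, new: bool = False) -> LesionRecord:
        return LesionRecord(pid, f"{pid}-L1", tp, mm, new)

    if category == "PD":
        return (rec(0.0, 100.0), rec(2.0, 130.0))
    if category == "SD":
        # mild shrinkage, then progression after the recorded SD duration
        d = duration if duration is not None else 4.0
        return (rec(0.0, 100.0), rec(2.0, 95.0), rec(d, 90.0),
                rec(d + 2.0, 130.0))
    if category == "PR":
        d = duration if duration is not None else 8.0
        series = [rec(0.0, 100.0), rec(2.0, 80.0), rec(4.0, 65.0)]
        if d > 6.0:
            series.append(rec(6.0, 60.0))
        # progression via a new lesion once the response duration elapses
        series.append(rec(4.0 + d, 60.0))
        series.append(LesionRecord(pid, f"{pid}-NEW", 4.0 + d, 12.0,
                                   new_lesion=True))
        return tuple(series)
    raise ValueError(f"unknown response category {category!r}")


def gen_trial_fixture() -> TrialFixture:
    """The published cohort as a reusable fixture.

    Per-patient outcomes (response category, duration, infusion count,
    lymphodepletion arm) and group-level adverse-event counts are literal
    published values; per-patient AE rows are reconstructed
    deterministically from the group counts (grade >= 3 patients first,
    the remainder at grade 2), and lesion trajectories are synthetic
    curves consistent with each patient's recorded category.
    """
    patients = _load_data_csv("trial_patients.csv")
    ae_counts = _load_data_csv("adverse_events.csv")

    group_members = {
        g: list(patients.loc[patients["group"] == g, "patient_id"])
        for g in ("none", "low", "high")
    }
    group_sizes = {g: len(m) for g, m in group_members.items()}

    events = []
    for row in ae_counts.itertuples():
        members = group_members[row.group]
        if row.any_grade_count > len(members):
            raise ValueError(f"{row.term}/{row.group}: count exceeds arm size")
        for i in range(int(row.any_grade_count)):
            grade = 3 if i < int(row.ge3_count) else 2
            events.append(AdverseEvent(members[i], row.group, row.term, grade))

    evaluable = patients[patients["evaluable"]]
    responses = dict(zip(evaluable["patient_id"], evaluable["response"]))
    infusions = dict(zip(patients["patient_id"], patients["infusions"]))
    sd_durations = tuple(
        float(d) for d in evaluable.loc[evaluable["response"] == "SD",
                                        "duration_months"])
    lesions = {}
    for row in evaluable.itertuples():
        duration = None if pd.isna(row.duration_months) else float(
            row.duration_months)
        lesions[row.patient_id] = _lesion_series(row.patient_id, row.response,
                                                 duration)
    return TrialFixture(patients, responses, infusions, sd_durations,
                        tuple(events), group_sizes, lesions)


def write_trial_fixture(fixture: TrialFixture, outdir: str | Path) -> None:
    """Emit the trial fixture as the CSV files clinical_outcomes reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lesion_rows = [
        {"patient_id": l.patient_id, "lesion_id": l.lesion_id,
         "timepoint_months": l.timepoint_months, "diameter_mm": l.diameter_mm,
         "new_lesion": l.new_lesion}
        for series in fixture.lesions.values() for l in series
    ]
    pd.DataFrame(lesion_rows).to_csv(outdir / "lesions.csv", index=False)
    ae_rows = [{"patient_id": e.patient_id, "group": e.group, "term": e.term,
                "grade": e.grade} for e in fixture.ae_events]
    pd.DataFrame(ae_rows).to_csv(outdir / "adverse_events.csv", index=False)
    fixture.patients.to_csv(outdir / "patients.csv", index=False)
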