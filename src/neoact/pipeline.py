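"""End-to-end candidate selection: variants in, ranked neoantigens out."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import mhc_binding as mb
from . import variant_peptides as vp


@dataclass(frozen=True)
class PipelineConfig:
    """Selection-run settings, loadable from YAML or JSON."""

    alleles: tuple[str, ...] = ("HLA-A*11:01",)
    lengths: tuple[int, ...] = tuple(vp.DEFAULT_LENGTHS)
    affinity_nm: float = 500.0
    tpm_min: float = 1.0
    vaf_threshold: float = 0.01
    top_n: int | None = 20
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = PipelineConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    for key in ("alleles", "lengths"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def select_candidates(
    proteome: Mapping[str, str],            # transcript_id -> CDS
    variants: Sequence[vp.Variant],
    expression: Mapping[str, float],        # gene_id -> TPM
    predictors: Sequence[mb.Predictor],
    allele: str,
    *,
    lengths: Sequence[int] = vp.DEFAULT_LENGTHS,
    vaf_threshold: float = 0.01,
    reference_proteins: Sequence[str] | None = None,
    top_n: int | None = None,
) -> list[mb.NeoantigenCandidate]:
    """Run the full selection cascade for one patient/allele.

    Steps: VAF filter -> peptide window enumeration -> reference-identity
    filter (when a reference proteome is supplied) -> five-predictor
    consensus IC50 for mutant and wild-type windows -> affinity /
    wild-type / expression filters -> ranking by ascending mutant IC50.
    """
    kept = vp.filter_vaf(variants, vaf_threshold)
    pairs: list[vp.PeptidePair] = []
    by_variant: dict[str, vp.Variant] = {}
    for variant in kept:
        cds = proteome[variant.transcript_id]
        for pair in vp.peptides_for_variant(cds, variant, lengths):
            pairs.append(pair)
            by_variant[variant.id] = variant
    if reference_proteins is not None:
        index = vp.ProteomeIndex(reference_proteins, lengths)
        pairs = vp.filter_reference_identity(pairs, index)
    mut_pred, wt_pred = mb.predict_ensemble(pairs, predictors, allele)
    candidates = []
    for pair in pairs:
        variant = by_variant[pair.variant_id]
        wt = (wt_pred[pair.wt_peptide].consensus_ic50
              if pair.wt_peptide is not None else None)
        candidates.append(mb.NeoantigenCandidate(
            pair=pair,
            mut_ic50=mut_pred[pair.mut_peptide].consensus_ic50,
            wt_ic50=wt,
            tpm=expression.get(variant.gene_id, 0.0),
            vaf=variant.vaf,
        ))
    return mb.rank_candidates(mb.apply_filters(candidates), top_n=top_n)
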