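"""Peptide–MHC affinity scoring, ensemble consensus, filtering and ranking.

The selection pipeline scores each candidate peptide against the patient's
HLA class I allele with an ensemble of five affinity predictors, each
returning an IC50 in nM (lower = stronger binding; 500 nM is the
conventional binder threshold).  The ensemble consensus rule is:

    if at least three of the five IC50s are < 500 nM, the consensus IC50
    is the minimum of the five; otherwise it is the sentinel 50,000 nM.

Candidates then pass a three-part filter cascade — consensus IC50 of the
mutant peptide must not exceed 500 nM, the mutant must bind at least as
strongly as its wild-type partner (when one exists), and the source gene
must be expressed (TPM >= 1) — and survivors are ranked by ascending
mutant IC50.

External predictors are pluggable: any callable mapping
``(peptide, allele) -> nM``, or a pre-computed exchange TSV, can fill the
five ensemble slots.  A built-in position-specific scoring matrix (PSSM)
predictor makes the pipeline runnable with no external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_peptides import InvalidSequenceError, PeptidePair

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Sentinel IC50 (nM) assigned when the ensemble does not reach consensus
#: or a predictor fails.  Matches the non-binder scale of the 500 nM rule.
SENTINEL_IC50 = 50_000.0

#: Conventional binder threshold in nM.
AFFINITY_THRESHOLD = 500.0

N_PREDICTORS = 5

Predictor = Callable[[str, str], float]


# --------------------------------------------------------------------------
# Built-in PSSM predictor
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PSSMModel:
    """Log-odds position-specific scoring matrix for one allele and length."""

    allele: str
    length: int
    weights: np.ndarray        # shape (20, length)
    background: np.ndarray     # shape (20,), sums to 1
    score_min: float
    score_max: float

    def __post_init__(self) -> None:
        if self.weights.shape != (20, self.length):
            raise ValueError("weights must be 20 x length")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be positive")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if not self.score_max > self.score_min:
            raise ValueError("score_max must exceed score_min")


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20)


def train_pssm(binders: Sequence[str], length: int, pseudocount: float = 1.0,
               background: np.ndarray | None = None,
               allele: str = "HLA-A*11:01") -> PSSMModel:
    """Fit a log2-odds PSSM from known binder peptides of one length.

    weights[a][i] = log2( (count(a,i) + pc*bg[a]) / (n + pc) / bg[a] ),
    the pseudocount-smoothed observed frequency over background.
    """
    if not binders:
        raise ValueError("at least one binder peptide required")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = uniform_background() if background is None else np.asarray(background, float)
    counts = np.zeros((20, length))
    for pep in binders:
        if len(pep) != length:
            raise ValueError(f"binder {pep!r} is not length {length}")
        for i, aa in enumerate(pep):
            if aa not in _AA_INDEX:
                raise InvalidSequenceError(f"non-standard residue {aa!r}")
            counts[_AA_INDEX[aa], i] += 1
    n = len(binders)
    freq = (counts + pseudocount * bg[:, None]) / (n + pseudocount)
    weights = np.log2(freq / bg[:, None])
    score_min = float(weights.min(axis=0).sum())
    score_max = float(weights.max(axis=0).sum())
    return PSSMModel(allele, length, weights, bg, score_min, score_max)


def pssm_score(model: PSSMModel, peptide: str) -> float:
    """Normalized PSSM score in [0, 1]; 1 = the matrix's consensus motif."""
    if len(peptide) != model.length:
        raise ValueError(
            f"peptide length {len(peptide)} != model length {model.length}")
    try:
        raw = sum(model.weights[_AA_INDEX[aa], i] for i, aa in enumerate(peptide))
    except KeyError as exc:
        raise InvalidSequenceError(f"non-standard residue {exc.args[0]!r}") from exc
    norm = (raw - model.score_min) / (model.score_max - model.score_min)
    return min(1.0, max(0.0, norm))


def score_to_ic50(score: float) -> float:
    """Map a normalized score in [0, 1] to an IC50 in nM as 50000^(1-score)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return SENTINEL_IC50 ** (1.0 - score)


def pssm_predictor(model: PSSMModel) -> Predictor:
    """Wrap a PSSM as an ensemble-slot predictor callable."""
    def predict(peptide: str, allele: str) -> float:
        return score_to_ic50(pssm_score(model, peptide))
    return predict


# --------------------------------------------------------------------------
# Ensemble consensus
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinityPrediction:
    peptide: str
    allele: str
    predictor_ic50s: tuple[float, ...]
    consensus_ic50: float


def consensus_ic50(ic50s: Sequence[float]) -> float:
    """Five-predictor consensus: min of the five if >=3 are <500 nM, else 50000."""
    if len(ic50s) != N_PREDICTORS:
        raise ValueError(f"exactly {N_PREDICTORS} IC50 values required, "
                         f"got {len(ic50s)}")
    if any(v <= 0 for v in ic50s):
        raise ValueError("IC50 values must be positive")
    n_strong = sum(1 for v in ic50s if v < AFFINITY_THRESHOLD)
    return min(ic50s) if n_strong >= 3 else SENTINEL_IC50


def predict_ensemble(
    pairs: Sequence[PeptidePair],
    predictors: Sequence[Predictor],
    allele: str,
) -> tuple[dict[str, AffinityPrediction], dict[str, AffinityPrediction]]:
    """Run all five predictors over mutant and wild-type peptides.

    Returns ``(mutant, wildtype)`` maps keyed by peptide sequence.  A
    predictor raising on a peptide contributes the sentinel 50,000 nM
    (it cannot vote "binder" nor become the minimum unless all fail).
    """
    if len(predictors) != N_PREDICTORS:
        raise ValueError(f"exactly {N_PREDICTORS} predictors required")
    peptides = {p.mut_peptide for p in pairs}
    wt_peptides = {p.wt_peptide for p in pairs if p.wt_peptide is not None}

    def run(peps: Iterable[str]) -> dict[str, AffinityPrediction]:
        out: dict[str, AffinityPrediction] = {}
        for pep in sorted(peps):
            values = []
            for predict in predictors:
                try:
                    values.append(float(predict(pep, allele)))
                except Exception:
                    values.append(SENTINEL_IC50)
            out[pep] = AffinityPrediction(pep, allele, tuple(values),
                                          consensus_ic50(values))
        return out

    return run(peptides), run(wt_peptides)


# --------------------------------------------------------------------------
# Exchange TSV for externally computed predictions
# --------------------------------------------------------------------------

def read_exchange_tsv(path: str | Path) -> dict[tuple[str, str], tuple[float, ...]]:
    """Read pre-computed predictor IC50s.

    Columns: peptide, allele, predictor, ic50_nm — one row per predictor
    call; exactly five distinct predictor labels are required per
    (peptide, allele).  Values are ordered by predictor label so the tuple
    is deterministic.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str,
                                            "predictor": str})
    required = {"peptide", "allele", "predictor", "ic50_nm"}
    if not required <= set(df.columns):
        raise ValueError(f"exchange TSV must have columns {sorted(required)}")
    out: dict[tuple[str, str], tuple[float, ...]] = {}
    for (pep, allele), grp in df.groupby(["peptide", "allele"], sort=True):
        labels = grp["predictor"].tolist()
        if len(set(labels)) != N_PREDICTORS or len(labels) != N_PREDICTORS:
            raise ValueError(
                f"{pep}/{allele}: expected {N_PREDICTORS} distinct predictor "
                f"rows, got {labels}")
        ordered = grp.sort_values("predictor")["ic50_nm"].astype(float)
        out[(pep, allele)] = tuple(ordered)
    return out


def exchange_predictions(
    table: Mapping[tuple[str, str], tuple[float, ...]],
) -> dict[str, AffinityPrediction]:
    """Consensus over an exchange table (all rows, keyed by peptide)."""
    return {
        pep: AffinityPrediction(pep, allele, values, consensus_ic50(values))
        for (pep, allele), values in table.items()
    }


# --------------------------------------------------------------------------
# Filter cascade and ranking
# --------------------------------------------------------------------------

FAIL_AFFINITY = "fail_affinity"
FAIL_WT_COMPARISON = "fail_wt_comparison"
FAIL_EXPRESSION = "fail_expression"


@dataclass(frozen=True)
class NeoantigenCandidate:
    """A peptide pair with its affinities, expression and filter status."""

    pair: PeptidePair
    mut_ic50: float
    wt_ic50: float | None
    tpm: float
    vaf: float
    filter_flags: frozenset[str] = frozenset()
    rank: int | None = None


def apply_filters(candidates: Sequence[NeoantigenCandidate],
                  affinity_nm: float = AFFINITY_THRESHOLD,
                  tpm_min: float = 1.0) -> list[NeoantigenCandidate]:
    """Evaluate all three filters on every candidate (no short-circuit).

    * ``fail_affinity``       — mutant IC50 strictly greater than 500 nM
    * ``fail_wt_comparison``  — mutant binds more weakly than wild type
      (skipped when no wild-type partner exists)
    * ``fail_expression``     — source-gene TPM strictly below 1
    """
    out = []
    for c in candidates:
        flags = set()
        if c.mut_ic50 > affinity_nm:
            flags.add(FAIL_AFFINITY)
        if c.wt_ic50 is not None and c.mut_ic50 > c.wt_ic50:
            flags.add(FAIL_WT_COMPARISON)
        if c.tpm < tpm_min:
            flags.add(FAIL_EXPRESSION)
        out.append(replace(c, filter_flags=frozenset(flags), rank=None))
    return out


def rank_candidates(candidates: Sequence[NeoantigenCandidate],
                    top_n: int | None = None) -> list[NeoantigenCandidate]:
    """Rank flag-free candidates by ascending mutant IC50.

    Ties break by descending VAF (higher clonality first), then
    lexicographic peptide.  Duplicate mutant peptides keep only the
    lowest-IC50 record.  ``top_n`` truncates the list (the selection
    protocol takes 5–20 peptides per patient).
    """
    retained = [c for c in candidates if not c.filter_flags]
    retained.sort(key=lambda c: (c.mut_ic50, -c.vaf, c.pair.mut_peptide))
    deduped: list[NeoantigenCandidate] = []
    seen: set[str] = set()
    for c in retained:
        if c.pair.mut_peptide in seen:
            continue
        seen.add(c.pair.mut_peptide)
        deduped.append(c)
    if top_n is not None:
        deduped = deduped[:top_n]
    return [replace(c, rank=i + 1) for i, c in enumerate(deduped)]


def ranked_table(candidates: Sequence[NeoantigenCandidate]) -> pd.DataFrame:
    """Ranked candidates as a DataFrame in the canonical output column order."""
    rows = [{
        "variant_id": c.pair.variant_id,
        "mut_peptide": c.pair.mut_peptide,
        "wt_peptide": c.pair.wt_peptide if c.pair.wt_peptide is not None else "",
        "mut_ic50": c.mut_ic50,
        "wt_ic50": c.wt_ic50 if c.wt_ic50 is not None else "",
        "tpm": c.tpm,
        "rank": c.rank,
    } for c in candidates]
    return pd.DataFrame(rows, columns=["variant_id", "mut_peptide", "wt_peptide",
                                       "mut_ic50", "wt_ic50", "tpm", "rank"])


def write_ranked_tsv(candidates: Sequence[NeoantigenCandidate],
                     path: str | Path) -> None:
    """Write the ranked candidate TSV (floats at 4 decimals, deterministic)."""
    ranked_table(candidates).to_csv(path, sep="\t", index=False,
                                    float_format="%.4f")
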