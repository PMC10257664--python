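"""Scoring of immunological assay readouts.

Covers the three wet-lab readouts used to validate candidate neoantigens
and the T-cell products raised against them:

* IFN-γ ELISPOT positivity — a peptide is called positive when the well
  shows more than 10 spots and at least two-fold the negative control;
* LDH-release cytotoxicity — percent specific lysis from 490 nm
  absorbances, using the standard corrected-lysis formula of the CytoTox
  96 non-radioactive assay;
* tetramer staining — percentage of CD8+ events that are peptide–MHC
  tetramer positive, with a 95% Wilson score confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence


@dataclass(frozen=True)
class ElispotWell:
    sample_id: str
    peptide_id: str
    spots: int
    negative_control_spots: int
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.spots < 0 or self.negative_control_spots < 0:
            raise ValueError("spot counts must be nonnegative")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


@dataclass(frozen=True)
class LdhReadings:
    """490 nm absorbances for one effector:target condition."""

    experimental: float
    effector_spontaneous: float
    target_spontaneous: float
    target_maximum: float

    def __post_init__(self) -> None:
        if min(self.experimental, self.effector_spontaneous,
               self.target_spontaneous, self.target_maximum) < 0:
            raise ValueError("absorbances must be nonnegative")
        if self.target_maximum <= self.target_spontaneous:
            raise ValueError("target maximum release must exceed "
                             "target spontaneous release")


@dataclass(frozen=True)
class TetramerCount:
    cd8_events: int
    tetramer_positive_events: int

    def __post_init__(self) -> None:
        if self.cd8_events < 1:
            raise ValueError("need at least one CD8+ event")
        if not 0 <= self.tetramer_positive_events <= self.cd8_events:
            raise ValueError("tetramer-positive events exceed CD8+ events")


def elispot_positive(well: ElispotWell) -> bool:
    """Positive iff spots > 10 and spots >= 2 x negative control."""
    return well.spots > 10 and well.spots >= 2 * well.negative_control_spots


def _round_half_up_int(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def elispot_positive_replicates(wells: Sequence[ElispotWell]) -> bool:
    """One positivity call per peptide from replicate wells.

    Replicates are combined by the mean spot count (and mean control),
    rounded half-up to whole spots, then passed through the single-well
    rule — one deterministic decision per peptide.
    """
    if not wells:
        raise ValueError("no replicate wells supplied")
    mean_spots = _round_half_up_int(sum(w.spots for w in wells) / len(wells))
    mean_ctrl = _round_half_up_int(
        sum(w.negative_control_spots for w in wells) / len(wells))
    combined = ElispotWell(wells[0].sample_id, wells[0].peptide_id,
                           mean_spots, mean_ctrl)
    return elispot_positive(combined)


@dataclass(frozen=True)
class LysisResult:
    percent_lysis: float
    out_of_range: bool  # negative or >100%: noisy readings, reported as-is


def percent_lysis(r: LdhReadings) -> LysisResult:
    """Corrected percent specific lysis from LDH-release absorbances.

    100 x (experimental - effector spontaneous - target spontaneous)
        / (target maximum - target spontaneous).

    Values outside [0, 100] are possible on noisy plates; they are
    reported unclipped with ``out_of_range`` set.
    """
    pct = 100.0 * (r.experimental - r.effector_spontaneous
                   - r.target_spontaneous) / (r.target_maximum
                                              - r.target_spontaneous)
    return LysisResult(pct, out_of_range=not 0.0 <= pct <= 100.0)


@dataclass(frozen=True)
class TetramerFraction:
    percent: float
    ci95_low: float   # percent
    ci95_high: float  # percent


def tetramer_fraction(t: TetramerCount) -> TetramerFraction:
    """Tetramer-positive percentage of CD8+ events with 95% Wilson interval."""
    n, k = t.cd8_events, t.tetramer_positive_events
    p = k / n
    z = 1.959963984540054  # two-sided 95% normal quantile
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    low = min(p, max(0.0, center - half))   # interval always contains p
    high = max(p, min(1.0, center + half))
    return TetramerFraction(100.0 * p, 100.0 * low, 100.0 * high)


# --------------------------------------------------------------------------
# Plate CSV I/O
# --------------------------------------------------------------------------

def score_elispot_csv(path) -> "pd.DataFrame":
    """Positivity calls from a plate CSV (one row per well).

    Columns: sample_id, peptide_id, spots, negative_control_spots,
    replicate.  Replicate wells of the same (sample, peptide) are combined
    by the mean rule; output has one row per peptide with the call.
    """
    import pandas as pd

    df = pd.read_csv(path)
    rows = []
    for (sid, pid), grp in df.groupby(["sample_id", "peptide_id"], sort=True):
        wells = [ElispotWell(str(sid), str(pid), int(r.spots),
                             int(r.negative_control_spots), int(r.replicate))
                 for r in grp.itertuples()]
        rows.append({"sample_id": sid, "peptide_id": pid,
                     "n_replicates": len(wells),
                     "positive": elispot_positive_replicates(wells)})
    return pd.DataFrame(rows, columns=["sample_id", "peptide_id",
                                       "n_replicates", "positive"])


def score_ldh_csv(path) -> "pd.DataFrame":
    """Percent lysis per row of an LDH plate CSV, with quality flags.

    Columns: sample_id, experimental, effector_spontaneous,
    target_spontaneous, target_maximum (490 nm absorbances).
    """
    import pandas as pd

    df = pd.read_csv(path)
    rows = []
    for r in df.itertuples():
        res = percent_lysis(LdhReadings(float(r.experimental),
                                        float(r.effector_spontaneous),
                                        float(r.target_spontaneous),
                                        float(r.target_maximum)))
        rows.append({"sample_id": r.sample_id,
                     "percent_lysis": res.percent_lysis,
                     "out_of_range": res.out_of_range})
    return pd.DataFrame(rows, columns=["sample_id", "percent_lysis",
                                       "out_of_range"])
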