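"""TCR clonotype tracking across infusion timepoints.

A clonotype is a unique TCR identity: the CDR3 amino-acid sequence of the
beta chain plus its V and J gene calls.  Given clonotype count tables
sampled from peripheral blood before and after T-cell infusions, this
module normalizes counts to frequencies, removes pathogen-associated
CDR3s via an exact-match blocklist, and summarizes per-clone dynamics:
expansion fold-change against the pre-infusion baseline (with a
pseudocount for clones unseen at baseline), top-clone dominance, and
persistence at the final sampled timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default pseudocount added to read counts (not frequencies) when
#: estimating fold-changes; bounds the estimate for zero-baseline clones.
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class Clonotype:
    cdr3_aa: str
    v_call: str = ""
    j_call: str = ""

    def __post_init__(self) -> None:
        if not self.cdr3_aa or not set(self.cdr3_aa) <= _RESIDUES:
            raise ValueError(f"invalid CDR3 sequence {self.cdr3_aa!r}")


@dataclass
class ClonotypeTable:
    """Clonotype read counts at one timepoint (months from first infusion)."""

    timepoint: float
    counts: dict[Clonotype, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("counts must be >= 1 (absent clones are omitted)")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def normalize(table: ClonotypeTable) -> dict[Clonotype, float]:
    """Counts -> frequencies summing to 1."""
    total = table.total_reads
    if total < 1:
        raise ValueError("cannot normalize an empty clonotype table")
    return {clone: count / total for clone, count in table.counts.items()}


def remove_blocklisted(table: ClonotypeTable,
                       blocklist: Iterable[str]) -> ClonotypeTable:
    """Drop clones whose CDR3 matches the pathogen-associated blocklist exactly."""
    blocked = set(blocklist)
    kept = {c: n for c, n in table.counts.items() if c.cdr3_aa not in blocked}
    return ClonotypeTable(table.timepoint, kept)


def fold_change(baseline: ClonotypeTable, later: ClonotypeTable,
                clone: Clonotype,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Frequency ratio later/baseline with pseudocounted read counts.

    The pseudocount is added to both the clone count and the total, so a
    clone unseen at baseline still gets a finite (bounded) fold estimate;
    with pseudocount 0 and nonzero counts this is the exact frequency
    ratio.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    for t in (baseline, later):
        if t.total_reads < 1:
            raise ValueError("tables must contain reads")
    f_base = ((baseline.counts.get(clone, 0) + pseudocount)
              / (baseline.total_reads + pseudocount))
    f_later = ((later.counts.get(clone, 0) + pseudocount)
               / (later.total_reads + pseudocount))
    return f_later / f_base


def top_clones(table: ClonotypeTable, n: int) -> list[tuple[Clonotype, float]]:
    """The n most frequent clones, descending; ties break by CDR3 lexicographic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = normalize(table)
    ordered = sorted(freqs.items(),
                     key=lambda kv: (-kv[1], kv[0].cdr3_aa, kv[0].v_call,
                                     kv[0].j_call))
    return ordered[:n]


@dataclass(frozen=True)
class CloneTrajectory:
    clone: Clonotype
    series: tuple[tuple[float, float], ...]  # (timepoint, frequency)
    max_fold_change: float
    persists_at_last: bool


def trajectory(series: Sequence[ClonotypeTable], clone: Clonotype,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> CloneTrajectory:
    """Per-timepoint frequencies plus expansion/persistence summary.

    The earliest timepoint is the baseline (pre-infusion samples carry
    negative month values).  ``max_fold_change`` is the largest
    pseudocounted fold versus baseline over the post-baseline timepoints;
    ``persists_at_last`` reports detection at the final timepoint.
    """
    if len(series) < 2:
        raise ValueError("need at least two timepoints (baseline + follow-up)")
    ordered = sorted(series, key=lambda t: t.timepoint)
    timepoints = [t.timepoint for t in ordered]
    if len(set(timepoints)) != len(timepoints):
        raise ValueError("timepoints must be unique within a series")
    baseline = ordered[0]
    freqs = tuple(
        (t.timepoint, t.counts.get(clone, 0) / t.total_reads) for t in ordered)
    max_fc = max(fold_change(baseline, t, clone, pseudocount)
                 for t in ordered[1:])
    persists = ordered[-1].counts.get(clone, 0) >= 1
    return CloneTrajectory(clone, freqs, max_fc, persists)


# --------------------------------------------------------------------------
# AIRR-flavored I/O
# --------------------------------------------------------------------------

_TSV_COLUMNS = ["sample_id", "timepoint_months", "cdr3_aa", "v_call",
                "j_call", "count"]


def read_clonotype_tsv(path: str | Path,
                       sample_id: str | None = None) -> list[ClonotypeTable]:
    """Read an AIRR-flavored clonotype TSV into per-timepoint tables.

    Columns: sample_id, timepoint_months, cdr3_aa, v_call, j_call, count.
    Tables are returned sorted by timepoint.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cdr3_aa": str, "v_call": str,
                                            "j_call": str, "sample_id": str})
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clonotype TSV missing columns {sorted(missing)}")
    if sample_id is not None:
        df = df[df["sample_id"] == sample_id]
    tables = []
    for tp, grp in df.groupby("timepoint_months", sort=True):
        counts = {
            Clonotype(r.cdr3_aa, r.v_call, r.j_call): int(r.count)
            for r in grp.itertuples()
        }
        tables.append(ClonotypeTable(float(tp), counts))
    return tables


def write_clonotype_tsv(tables: Sequence[ClonotypeTable], path: str | Path,
                        sample_id: str = "S1") -> None:
    rows = [
        {"sample_id": sample_id, "timepoint_months": t.timepoint,
         "cdr3_aa": c.cdr3_aa, "v_call": c.v_call, "j_call": c.j_call,
         "count": n}
        for t in sorted(tables, key=lambda t: t.timepoint)
        for c, n in sorted(t.counts.items(),
                           key=lambda kv: (kv[0].cdr3_aa, kv[0].v_call,
                                           kv[0].j_call))
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_blocklist(path: str | Path) -> set[str]:
    """One CDR3 amino-acid sequence per line; blank lines ignored."""
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def trajectory_table(series: Sequence[ClonotypeTable],
                     clones: Sequence[Clonotype],
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """One summary row per tracked clone: max fold-change and persistence."""
    rows = []
    for clone in clones:
        tr = trajectory(series, clone, pseudocount)
        rows.append({"cdr3_aa": clone.cdr3_aa, "v_call": clone.v_call,
                     "j_call": clone.j_call,
                     "max_fold_change": tr.max_fold_change,
                     "persists_at_last": tr.persists_at_last})
    return pd.DataFrame(rows, columns=["cdr3_aa", "v_call", "j_call",
                                       "max_fold_change", "persists_at_last"])


def frequency_long_table(series: Sequence[ClonotypeTable],
                         clones: Sequence[Clonotype],
                         sample_id: str = "S1") -> pd.DataFrame:
    """Long-format (sample, clone, timepoint, frequency) table for plotting."""
    rows = []
    for t in sorted(series, key=lambda t: t.timepoint):
        total = t.total_reads
        for c in clones:
            rows.append({"sample_id": sample_id, "cdr3_aa": c.cdr3_aa,
                         "timepoint_months": t.timepoint,
                         "frequency": t.counts.get(c, 0) / total})
    return pd.DataFrame(rows)
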