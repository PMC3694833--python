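"""Joint-fraction summaries and colony-assay arithmetic.

Count tables are plain pandas DataFrames: one row per joint identifier plus
the special rows ``ambiguous`` / ``unmatched`` / ``contaminant``, one column
per sample.  Joint fractions are computed over joint rows only — special
categories are reported as fractions of all reads in the table, never mixed
into the joint denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .classify import SPECIAL_ROWS
from .joints import PRECISE_ID

PRECISE = "precise"
MAJOR_IMPRECISE = "major_imprecise"
OTHER = "other"

#: joints reaching this fraction in any sample are "major imprecise"
MAJOR_THRESHOLD = 0.001


class QuantifyError(ValueError):
    pass


def joint_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the special category rows, leaving repair joints only."""
    return table.drop(index=[r for r in SPECIAL_ROWS if r in table.index])


def sample_totals(table: pd.DataFrame) -> pd.Series:
    """Per-sample totals over joint rows only."""
    return joint_rows(table).sum(axis=0)


def joint_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Express counts as fractions of each sample's total joint reads.

    Joint rows are normalised by the per-sample joint total (so they sum to 1
    per sample); special rows, if present, are normalised by the all-category
    total of the table so they remain interpretable as fractions of all reads.
    """
    joints = joint_rows(table)
    totals = joints.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise QuantifyError(f"zero joint reads for sample(s) {list(zero.index)}")
    frac = joints / totals
    specials = table.loc[[r for r in SPECIAL_ROWS if r in table.index]]
    if len(specials):
        frac = pd.concat([frac, specials / table.sum(axis=0)])
    return frac


def categorize_joints(fractions: pd.DataFrame, threshold: float = MAJOR_THRESHOLD) -> dict[str, str]:
    """Assign each joint to precise / major_imprecise / other.

    The precise joint is always its own category; an imprecise joint is major
    iff its fraction reaches ``threshold`` (>=, not >) in at least one sample.
    """
    joints = joint_rows(fractions)
    out: dict[str, str] = {}
    for joint_id, row in joints.iterrows():
        if joint_id == PRECISE_ID:
            out[joint_id] = PRECISE
        elif (row >= threshold).any():
            out[joint_id] = MAJOR_IMPRECISE
        else:
            out[joint_id] = OTHER
    return out


def category_fractions(fractions: pd.DataFrame, categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Sum joint fractions per category; columns are samples, rows categories."""
    joints = joint_rows(fractions)
    if categories is None:
        categories = categorize_joints(fractions)
    cats = pd.Series({j: categories[j] for j in joints.index}, name="category")
    out = joints.groupby(cats).sum()
    return out.reindex([PRECISE, MAJOR_IMPRECISE, OTHER], fill_value=0.0)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ColonyAssayRecord:
    """Colony counts from the two-cut deletion assay for one strain.

    ``recleavable``/``tested_recleavage`` score survivors whose repair joint
    could be re-cut by the nuclease (hence precise religation).  For the
    marker-loss arm, ``met_minus`` of ``total_colonies`` lost the internal
    cassette marker, and ``pcr_positive`` of ``pcr_tested`` of those yielded a
    junction-flanking PCR product (imprecise joining rather than a large
    deletion).
    """

    strain: str
    recleavable: int = 0
    tested_recleavage: int = 0
    met_minus: int = 0
    total_colonies: int = 0
    pcr_positive: int = 0
    pcr_tested: int = 0

    def __post_init__(self) -> None:
        fields = (
            self.recleavable,
            self.tested_recleavage,
            self.met_minus,
            self.total_colonies,
            self.pcr_positive,
            self.pcr_tested,
        )
        if min(fields) < 0:
            raise QuantifyError("colony counts must be non-negative")
        if self.recleavable > self.tested_recleavage:
            raise QuantifyError("recleavable exceeds tested_recleavage")
        if not (self.pcr_positive <= self.pcr_tested <= self.met_minus <= self.total_colonies):
            raise QuantifyError(
                "expected pcr_positive <= pcr_tested <= met_minus <= total_colonies"
            )


def precise_percent(rec: ColonyAssayRecord) -> int:
    """Percent of tested survivors whose joint was re-cleavable (precise)."""
    if rec.tested_recleavage == 0:
        raise QuantifyError(f"{rec.strain}: no colonies tested for re-cleavage")
    return round_half_up(100 * rec.recleavable / rec.tested_recleavage)


def ade_minus_summary(rec: ColonyAssayRecord) -> dict[str, int]:
    """Classify marker-loss colonies into large-deletion / imprecise / other.

    The junction PCR is only run on a subsample of marker-loss colonies, so
    the PCR rate is extrapolated to all of them: imprecise joining is
    ``(pcr_positive / pcr_tested) x (met_minus / total_colonies)``, large
    deletions the PCR-negative complement, and "other" the colonies that never
    lost the marker.  All three are rounded half-up to integer percent and sum
    to 100 within rounding.
    """
    if rec.pcr_tested == 0 or rec.total_colonies == 0:
        raise QuantifyError(f"{rec.strain}: zero denominator in marker-loss summary")
    met_rate = rec.met_minus / rec.total_colonies
    pcr_rate = rec.pcr_positive / rec.pcr_tested
    return {
        "large_deletion_pct": round_half_up(100 * (1 - pcr_rate) * met_rate),
        "imprecise_pct": round_half_up(100 * pcr_rate * met_rate),
        "other_pct": round_half_up(100 * (1 - met_rate)),
    }


def read_count_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if (table < 0).any().any():
        raise QuantifyError(f"negative counts in {path}")
    return table


def write_table(table: pd.DataFrame, path: str | Path, index_label: str = "joint_id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label)


def read_colony_records(path: str | Path) -> list[ColonyAssayRecord]:
    """Read colony-assay records from a TSV with one strain per row."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            ColonyAssayRecord(
                strain=str(row["strain"]),
                recleavable=int(row.get("recleavable", 0)),
                tested_recleavage=int(row.get("tested_recleavage", 0)),
                met_minus=int(row.get("met_minus", 0)),
                total_colonies=int(row.get("total_colonies", 0)),
                pcr_positive=int(row.get("pcr_positive", 0)),
                pcr_tested=int(row.get("pcr_tested", 0)),
            )
        )
    return records
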