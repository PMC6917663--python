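"""Low-temperature injury phenotyping.

Seedlings exposed to chilling stress are scored on an ordinal injury scale
{0, 1, 3, 5, 7, 9} (0 = no symptoms on cotyledons or first true leaf,
9 = cotyledons and first true leaf dried). The per-replicate tallies of
plants in each grade are summarised by the low-temperature injury index

    LTII = 100 * (0*S0 + 1*S1 + 3*S3 + 5*S5 + 7*S7 + 9*S9) / (9 * N)

where N is the number of plants scored. LTII lives on a 0-100 scale: 0 means
every plant symptom-free, 100 means every plant dead. Family means over
replicates are the quantitative phenotype used for QTL mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GRADES",
    "GradeCounts",
    "LTIIRecord",
    "compute_ltii",
    "ltii_table",
    "aggregate_families",
    "experiment_correlation",
    "read_phenotype_csv",
]

#: The ordinal injury grades used for scoring.
GRADES = (0, 1, 3, 5, 7, 9)

_GRADE_COLUMNS = ["S0", "S1", "S3", "S5", "S7", "S9"]


@dataclass(frozen=True)
class GradeCounts:
    """Plant tallies per injury grade for one replicate of one family."""

    s0: int = 0
    s1: int = 0
    s3: int = 0
    s5: int = 0
    s7: int = 0
    s9: int = 0

    def __post_init__(self):
        counts = self.as_tuple()
        if any(int(c) != c or c < 0 for c in counts):
            raise ValueError(f"grade counts must be non-negative integers, got {counts}")
        if self.n == 0:
            raise ValueError("grade counts must tally at least one plant (N > 0)")

    def as_tuple(self) -> tuple[int, ...]:
        return (self.s0, self.s1, self.s3, self.s5, self.s7, self.s9)

    @property
    def n(self) -> int:
        """Total number of plants scored."""
        return sum(self.as_tuple())


@dataclass(frozen=True)
class LTIIRecord:
    """Injury index for one replicate of one family."""

    family_id: str
    replicate: int
    ltii: float

    def __post_init__(self):
        if not 0.0 <= self.ltii <= 100.0:
            raise ValueError(f"LTII must be in [0, 100], got {self.ltii}")


def compute_ltii(counts: GradeCounts) -> float:
    """Low-temperature injury index of one replicate, on the 0-100 scale.

    The weighted grade sum is divided by the maximum possible score 9*N, so
    the index is 0 when every plant is grade 0 and 100 when every plant is
    grade 9. Moving any plant to a higher grade can only increase the index.
    """
    weighted = sum(g * c for g, c in zip(GRADES, counts.as_tuple()))
    return 100.0 * weighted / (9.0 * counts.n)


def ltii_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Compute LTII for every (family, replicate) row of a phenotype table.

    Parameters
    ----------
    phenotypes
        Table with columns ``family_id``, ``replicate``, ``S0``, ``S1``,
        ``S3``, ``S5``, ``S7``, ``S9`` (the CSV schema written by the
        synthetic-data generator).

    Returns
    -------
    DataFrame with columns ``family_id``, ``replicate``, ``ltii``.
    """
    missing = [c for c in ["family_id", "replicate", *_GRADE_COLUMNS] if c not in phenotypes]
    if missing:
        raise ValueError(f"phenotype table is missing columns: {missing}")
    extra = [c for c in phenotypes.columns if c.startswith("S") and c not in _GRADE_COLUMNS]
    if extra:
        raise ValueError(
            f"unsupported grade columns {extra}: grades are restricted to {GRADES}"
        )
    out = []
    for _, row in phenotypes.iterrows():
        gc = GradeCounts(*(int(row[c]) for c in _GRADE_COLUMNS))
        out.append((row["family_id"], row["replicate"], compute_ltii(gc)))
    return pd.DataFrame(out, columns=["family_id", "replicate", "ltii"])


def aggregate_families(records) -> pd.Series:
    """Per-family mean LTII over replicates.

    Accepts either a list of :class:`LTIIRecord` or the DataFrame produced by
    :func:`ltii_table`. Families may have unequal replicate counts; the mean
    is over whatever replicates are present.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("no LTII records to aggregate")
        df = pd.DataFrame(
            [(r.family_id, r.replicate, r.ltii) for r in records],
            columns=["family_id", "replicate", "ltii"],
        )
    if df.empty:
        raise ValueError("no LTII records to aggregate")
    means = df.groupby("family_id", sort=False)["ltii"].mean()
    means.name = "ltii"
    return means


def experiment_correlation(exp_a: pd.Series, exp_b: pd.Series) -> float:
    """Pearson correlation of family-mean LTII between two experiments.

    The two series are aligned on family id; families absent from either
    experiment are dropped. At least three shared families are required, and
    both vectors must vary.
    """
    joined = pd.concat([exp_a.rename("a"), exp_b.rename("b")], axis=1, join="inner")
    if len(joined) < 3:
        raise ValueError(f"need >= 3 shared families, got {len(joined)}")
    a = joined["a"].to_numpy(float)
    b = joined["b"].to_numpy(float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined: zero variance in an experiment")
    return float(np.corrcoef(a, b)[0, 1])


def read_phenotype_csv(path) -> pd.DataFrame:
    """Read a phenotype CSV (family_id, replicate, S0, S1, S3, S5, S7, S9)."""
    df = pd.read_csv(path, dtype={"family_id": str})
    for col in _GRADE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"phenotype CSV {path} lacks required column {col}")
    return df
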