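"""Candidate-gene validation: relative expression and marker association.

Two independent lines of evidence for a candidate gene:

* qRT-PCR relative expression over a cold time course, analysed with the
  2^-ddCt method (reference-gene normalisation, self-calibration at 0 h per
  line), with per-timepoint Welch t tests between the tolerant and sensitive
  line on the normalised dCt values;
* association between the candidate SNP genotype class of each F2 individual
  (a = resistant-parent homozygote, b = sensitive-parent homozygote,
  ab = heterozygote) and its family-mean injury index, via one-way ANOVA,
  plus a chi-square test of 1:2:1 segregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "TIMEPOINTS_H",
    "delta_delta_ct",
    "compare_lines",
    "star_code",
    "assign_genotype_class",
    "marker_phenotype_association",
    "AssociationResult",
]

#: Column schema of a Ct table.
CT_COLUMNS = ["line", "timepoint", "gene", "ct_target", "ct_reference", "bio_rep", "tech_rep"]

#: Hours after the start of cold exposure at which leaves are sampled.
TIMEPOINTS_H = (0, 10, 24, 48, 96, 144, 216, 288, 384, 480)


def _check_ct(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    bad = ~(
        np.isfinite(measurements["ct_target"])
        & np.isfinite(measurements["ct_reference"])
        & (measurements["ct_target"] > 0)
        & (measurements["ct_reference"] > 0)
    )
    if bad.any():
        raise ValueError("Ct values must be positive and finite")
    return measurements


def _dct_per_biorep(measurements: pd.DataFrame) -> pd.DataFrame:
    """dCt = Ct_target - Ct_reference per biological replicate.

    Technical replicates are averaged first (separately for target and
    reference), then differenced.
    """
    grouped = (
        measurements.groupby(["line", "gene", "timepoint", "bio_rep"], sort=False)[
            ["ct_target", "ct_reference"]
        ]
        .mean()
        .reset_index()
    )
    grouped["dct"] = grouped["ct_target"] - grouped["ct_reference"]
    return grouped


def delta_delta_ct(
    measurements: pd.DataFrame, calibrator_timepoint: float = 0
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    Per line x gene, ddCt(t) = mean dCt(t) - mean dCt(calibrator) and
    fold = 2^-ddCt, so the calibrator timepoint has fold 1 by construction.
    ``dispersion`` is the standard deviation over biological replicates of
    the per-replicate fold 2^-(dCt_rep - mean dCt(calibrator)).

    Returns a table with line, gene, timepoint, n_bio_reps, ddct, fold,
    dispersion.
    """
    dct = _dct_per_biorep(_check_ct(measurements))
    out = []
    for (line, gene), sub in dct.groupby(["line", "gene"], sort=False):
        cal = sub[sub["timepoint"] == calibrator_timepoint]
        if cal.empty:
            raise ValueError(
                f"no calibrator timepoint {calibrator_timepoint} for {line}/{gene}"
            )
        cal_mean = cal["dct"].mean()
        for t, tp in sub.groupby("timepoint", sort=True):
            ddct = tp["dct"].mean() - cal_mean
            rep_folds = 2.0 ** -(tp["dct"] - cal_mean)
            out.append(
                {
                    "line": line,
                    "gene": gene,
                    "timepoint": t,
                    "n_bio_reps": len(tp),
                    "ddct": ddct,
                    "fold": 2.0 ** -ddct,
                    "dispersion": float(rep_folds.std(ddof=1)) if len(tp) > 1 else np.nan,
                }
            )
    return pd.DataFrame(out)


def star_code(p: float) -> str:
    """Significance stars: * for p<0.05, ** for p<0.01, *** for p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_lines(
    measurements: pd.DataFrame,
    line_a: str,
    line_b: str,
    gene: str | None = None,
) -> pd.DataFrame:
    """Per-timepoint Welch t test between two lines on dCt values.

    The test operates on reference-normalised dCt (approximately normal),
    not on fold changes. Timepoints with fewer than two biological
    replicates in either line are flagged and left untested.
    """
    dct = _dct_per_biorep(_check_ct(measurements))
    if gene is not None:
        dct = dct[dct["gene"] == gene]
    rows = []
    for (g, t), sub in dct.groupby(["gene", "timepoint"], sort=True):
        a = sub.loc[sub["line"] == line_a, "dct"].to_numpy(float)
        b = sub.loc[sub["line"] == line_b, "dct"].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {"gene": g, "timepoint": t, "t": np.nan, "p": np.nan,
                 "stars": "", "tested": False}
            )
            continue
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {"gene": g, "timepoint": t, "t": float(t_stat), "p": float(p),
             "stars": star_code(float(p)), "tested": True}
        )
    return pd.DataFrame(rows)


def assign_genotype_class(
    calls,
    resistant_parent_call: int,
    sensitive_parent_call: int,
) -> pd.Series:
    """Genotype class of each F2 individual at the candidate SNP.

    ``calls`` maps individual id -> genotype code (0 hom-ref, 1 het,
    2 hom-alt, -1 missing), as in the variant table. Individuals matching the
    resistant parent are class 'a', the sensitive parent 'b', heterozygotes
    'ab'; missing stays missing (NaN).
    """
    for c in (resistant_parent_call, sensitive_parent_call):
        if c not in (0, 2):
            raise ValueError("parental calls must be homozygous (0 or 2)")
    if resistant_parent_call == sensitive_parent_call:
        raise ValueError("parental calls are identical; the marker is undiagnostic")
    s = pd.Series(calls)
    out = pd.Series(index=s.index, dtype=object)
    out[s == resistant_parent_call] = "a"
    out[s == sensitive_parent_call] = "b"
    out[s == 1] = "ab"
    out[s == -1] = np.nan
    return out


@dataclass
class AssociationResult:
    group_means: dict
    group_sizes: dict
    f_statistic: float
    p_value: float
    segregation_chi2: float
    segregation_p: float


def marker_phenotype_association(classes: pd.Series, ltii: pd.Series) -> AssociationResult:
    """One-way ANOVA of family LTII across genotype classes {a, ab, b}.

    Also tests the class counts against the Mendelian 1:2:1 expectation with
    a 2-df chi-square. At least two populated classes are required.
    """
    df = pd.concat([classes.rename("cls"), ltii.rename("y")], axis=1, join="inner").dropna()
    groups = {c: df.loc[df["cls"] == c, "y"].to_numpy(float) for c in ("a", "ab", "b")}
    populated = [g for g in groups.values() if len(g) > 0]
    if len(populated) < 2:
        raise ValueError("need at least two populated genotype classes for ANOVA")
    means = {c: float(np.mean(g)) for c, g in groups.items() if len(g)}
    sizes = {c: int(len(g)) for c, g in groups.items()}
    if all(np.allclose(g, np.concatenate(populated).mean()) for g in populated):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*populated)

    counts = np.array([sizes.get("a", 0), sizes.get("ab", 0), sizes.get("b", 0)], float)
    expected = counts.sum() * np.array([0.25, 0.5, 0.25])
    chi2, chi_p = stats.chisquare(counts, expected)
    return AssociationResult(
        group_means=means,
        group_sizes=sizes,
        f_statistic=float(f_stat),
        p_value=float(p),
        segregation_chi2=float(chi2),
        segregation_p=float(chi_p),
    )
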