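"""Repeated-measures ANOVA for fully within-subject two-factor designs.

Closed-form sums-of-squares implementation (each main effect tested against
its factor × subject interaction, the A×B interaction against the A×B×subject
residual), equivalent to the standard univariate repeated-measures ANOVA
without sphericity correction.  Written in numpy so calibration studies can
run thousands of replicates cheaply.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateDataError, StructuralError


def rm_anova_two_way(
    data: np.ndarray, factor_names: tuple[str, str] = ("A", "B")
) -> pd.DataFrame:
    """Two-way fully repeated-measures ANOVA.

    Parameters
    ----------
    data:
        (subjects × levels_A × levels_B) array of one observation per cell.

    Returns
    -------
    DataFrame with rows for both main effects and the interaction:
    columns (source, ss, df1, df2, ms, F, p).  If an error term is zero the
    corresponding F and p are NaN and the row is marked degenerate.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise StructuralError("data must be (subjects, levels_A, levels_B)")
    n, a, b = data.shape
    if n < 2:
        raise StructuralError("need at least 2 subjects")
    if a < 2 or b < 2:
        raise StructuralError("each factor needs at least 2 levels")
    if not np.all(np.isfinite(data)):
        raise StructuralError("non-finite observations (no imputation is performed)")

    grand = data.mean()
    m_s = data.mean(axis=(1, 2))  # subject means
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_sa = data.mean(axis=2)  # (n, a)
    m_sb = data.mean(axis=1)  # (n, b)
    m_ab = data.mean(axis=0)  # (a, b)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    rows = []
    for source, ss_eff, df1, ss_err, df2 in [
        (factor_names[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (factor_names[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (
            f"{factor_names[0]} x {factor_names[1]}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_abs,
            (a - 1) * (b - 1) * (n - 1),
        ),
    ]:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        degenerate = ms_err <= 1e-300
        F = np.nan if degenerate else ms_eff / ms_err
        p = np.nan if degenerate else float(sstats.f.sf(F, df1, df2))
        rows.append(
            {
                "source": source,
                "ss": ss_eff,
                "df1": df1,
                "df2": df2,
                "ms": ms_eff,
                "F": F,
                "p": p,
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)


def rm_anova_from_long(
    df: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    subject: str = "subject",
) -> pd.DataFrame:
    """Pivot a balanced long table to a cube and run :func:`rm_anova_two_way`."""
    a_levels = list(dict.fromkeys(df[within[0]]))
    b_levels = list(dict.fromkeys(df[within[1]]))
    subjects = list(dict.fromkeys(df[subject]))
    cube = np.full((len(subjects), len(a_levels), len(b_levels)), np.nan)
    for _, row in df.iterrows():
        i = subjects.index(row[subject])
        j = a_levels.index(row[within[0]])
        k = b_levels.index(row[within[1]])
        if not np.isnan(cube[i, j, k]):
            raise StructuralError(
                f"duplicate cell ({row[subject]}, {row[within[0]]}, {row[within[1]]})"
            )
        cube[i, j, k] = row[dv]
    if np.isnan(cube).any():
        missing = int(np.isnan(cube).sum())
        raise StructuralError(f"unbalanced design: {missing} empty cells")
    return rm_anova_two_way(cube, factor_names=within)


def one_sample_t(values: np.ndarray, popmean: float) -> tuple[float, float, int]:
    """Two-sided one-sample t-test; returns (t, p, df).

    Zero-variance input yields (0.0, 1.0) when every value equals the null
    mean, and raises otherwise (the statistic is undefined).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise StructuralError("one-sample t-test needs n >= 2")
    if np.allclose(values.std(ddof=1), 0):
        if np.allclose(values.mean(), popmean):
            return 0.0, 1.0, values.size - 1
        raise DegenerateDataError(
            "zero variance with mean differing from the null value"
        )
    res = sstats.ttest_1samp(values, popmean)
    return float(res.statistic), float(res.pvalue), values.size - 1
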