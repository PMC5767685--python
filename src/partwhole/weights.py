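"""Convex weight estimation: how much face vs body explains the whole person.

For each subject, ROI and emotion, patterns are first averaged across the
three analysis runs.  The face weight α is swept over the closed grid
0.00–1.00 in 0.01 steps; at each α the Pearson correlation between
α·face + (1−α)·body and the run-averaged whole-person pattern is computed
and Fisher-z transformed.  The optimal α is the (smallest, on ties) grid
point maximising the curve; group statistics are run on the body weights
β̂ = 1 − α̂.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .config import EMOTIONS
from .datasets import PatternDataset
from .errors import DomainError, StructuralError
from .similarity import fisher_z
from .stats import one_sample_t, rm_anova_from_long

#: the 101-point face-weight grid
ALPHA_GRID = np.round(np.arange(0, 101) * 0.01, 2)


def weighted_mean(face: np.ndarray, body: np.ndarray, alpha: float) -> np.ndarray:
    """α·face + (1−α)·body, the synthetic weighted mean pattern."""
    if not (0 <= alpha <= 1) or not math.isfinite(alpha):
        raise DomainError(f"alpha must lie in [0, 1]; got {alpha!r}")
    face = np.asarray(face, dtype=float)
    body = np.asarray(body, dtype=float)
    if face.shape != body.shape:
        raise StructuralError(f"length mismatch: {face.shape} vs {body.shape}")
    return alpha * face + (1 - alpha) * body


def average_across_runs(
    ds: PatternDataset,
    subject: int,
    roi: str,
    body_type: str,
    emotion: str,
    runs: tuple[int, ...] = (0, 1, 2),
) -> np.ndarray:
    """Elementwise mean pattern over the analysis runs."""
    return np.mean([ds.get(subject, r, roi, body_type, emotion) for r in runs], axis=0)


@dataclass
class WeightCurve:
    """α grid → Fisher-z correlation profile for one subject/ROI/emotion."""

    alphas: np.ndarray
    z: np.ndarray
    valid: np.ndarray  # False where the weighted pattern had zero variance
    subject: int | None = None
    roi: str | None = None
    emotion: str | None = None

    def __post_init__(self) -> None:
        if len(self.alphas) != 101 or len(self.z) != 101:
            raise StructuralError("weight curve must have exactly 101 grid points")
        if np.any(np.diff(self.alphas) <= 0):
            raise StructuralError("alpha grid must be strictly increasing")


@dataclass
class OptimalWeight:
    alpha_hat: float
    beta_hat: float
    z_max: float
    tie_count: int


def weight_curve(
    face_avg: np.ndarray,
    body_avg: np.ndarray,
    person_avg: np.ndarray,
    subject: int | None = None,
    roi: str | None = None,
    emotion: str | None = None,
) -> WeightCurve:
    """Fisher-z correlation of the weighted face/body mean with the person
    pattern at each of the 101 grid weights."""
    face_avg = np.asarray(face_avg, dtype=float)
    body_avg = np.asarray(body_avg, dtype=float)
    person_avg = np.asarray(person_avg, dtype=float)
    if not (face_avg.shape == body_avg.shape == person_avg.shape):
        raise StructuralError("face, body and person patterns must share length")
    p = person_avg - person_avg.mean()
    p_norm = np.linalg.norm(p)
    if p_norm == 0:
        raise StructuralError("person pattern has zero variance")
    # all 101 weighted patterns at once: (101, V)
    W = ALPHA_GRID[:, None] * face_avg[None, :] + (1 - ALPHA_GRID)[:, None] * body_avg
    Wc = W - W.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Wc, axis=1)
    valid = norms > 0
    r = np.full(101, np.nan)
    r[valid] = (Wc[valid] @ p) / (norms[valid] * p_norm)
    z = np.full(101, np.nan)
    z[valid] = fisher_z(r[valid])
    return WeightCurve(
        alphas=ALPHA_GRID.copy(), z=z, valid=valid, subject=subject, roi=roi, emotion=emotion
    )


def optimal_alpha(curve: WeightCurve) -> OptimalWeight:
    """Smallest grid α attaining the curve maximum, with tie count."""
    if not curve.valid.any():
        raise StructuralError("all grid points are flagged invalid")
    z = np.where(curve.valid, curve.z, -np.inf)
    z_max = z.max()
    # ties up to floating-point noise (an analytically constant curve is
    # reported as a 101-way tie rather than split by last-bit rounding)
    ties = np.nonzero(np.isclose(z, z_max, rtol=1e-9, atol=1e-12))[0]
    a_hat = float(curve.alphas[ties[0]])
    return OptimalWeight(
        alpha_hat=a_hat,
        beta_hat=round(1.0 - a_hat, 10),
        z_max=float(z_max),
        tie_count=int(ties.size),
    )


def fit_optimal_weights(
    ds: PatternDataset,
    rois: tuple[str, ...] | None = None,
    runs: tuple[int, ...] = (0, 1, 2),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full optimisation per subject × ROI × emotion.

    Returns ``(curves, optima)``: the long table of all 101-point curves
    (subject, roi, emotion, alpha, z) and the per-cell optima
    (subject, roi, emotion, alpha_hat, beta_hat, z_max, tie_count).
    """
    rois = rois or ds.roi_names
    curve_rows = []
    opt_rows = []
    for s in ds.subjects:
        for roi in rois:
            for emo in EMOTIONS:
                f = average_across_runs(ds, s, roi, "face", emo, runs)
                b = average_across_runs(ds, s, roi, "body", emo, runs)
                p = average_across_runs(ds, s, roi, "person", emo, runs)
                curve = weight_curve(f, b, p, subject=s, roi=roi, emotion=emo)
                opt = optimal_alpha(curve)
                for a, zz in zip(curve.alphas, curve.z):
                    curve_rows.append(
                        {"subject": s, "roi": roi, "emotion": emo, "alpha": a, "z": zz}
                    )
                opt_rows.append(
                    {
                        "subject": s,
                        "roi": roi,
                        "emotion": emo,
                        "alpha_hat": opt.alpha_hat,
                        "beta_hat": opt.beta_hat,
                        "z_max": opt.z_max,
                        "tie_count": opt.tie_count,
                    }
                )
    return pd.DataFrame(curve_rows), pd.DataFrame(opt_rows)


def test_alpha_vs_half(weights: np.ndarray) -> dict:
    """Two-sided one-sample t-test of per-subject optimal weights against 0.5."""
    t, p, df = one_sample_t(np.asarray(weights, dtype=float), 0.5)
    return {"t": t, "p": p, "df": df, "mean": float(np.mean(weights))}


def emotion_roi_anova(optima: pd.DataFrame, rois: tuple[str, ...]) -> dict:
    """3 (Emotion) × len(rois) (ROI) repeated-measures ANOVA on body weights,
    with paired follow-up comparisons.

    Paired t-tests between emotions pool over ROIs and those between ROIs
    pool over emotions (both per-level tables are also returned unpooled).
    """
    if len(rois) < 2:
        raise StructuralError("emotion × ROI ANOVA needs at least 2 ROIs")
    sub = optima[optima["roi"].isin(rois)].copy()
    long = sub.rename(columns={"beta_hat": "beta"})[
        ["subject", "roi", "emotion", "beta"]
    ]
    anova = rm_anova_from_long(long, dv="beta", within=("emotion", "roi"))

    def _paired(level_col: str, pool_col: str) -> pd.DataFrame:
        levels = list(dict.fromkeys(long[level_col]))
        rows = []
        for i, la in enumerate(levels):
            for lb in levels[i + 1 :]:
                # pooled: one observation per subject × pooled level
                xa = (
                    long[long[level_col] == la]
                    .sort_values(["subject", pool_col])["beta"]
                    .to_numpy()
                )
                xb = (
                    long[long[level_col] == lb]
                    .sort_values(["subject", pool_col])["beta"]
                    .to_numpy()
                )
                res = sstats.ttest_rel(xa, xb)
                rows.append(
                    {
                        "level_a": la,
                        "level_b": lb,
                        "pooling": f"pooled_over_{pool_col}",
                        "t": float(res.statistic),
                        "df": len(xa) - 1,
                        "p": float(res.pvalue),
                    }
                )
        return pd.DataFrame(rows)

    return {
        "anova": anova,
        "emotion_pairs": _paired("emotion", "roi"),
        "roi_pairs": _paired("roi", "emotion"),
    }
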