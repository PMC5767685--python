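"""Pattern-similarity analysis: synthetic means, cross-run Fisher-z RSMs,
group averages, and the Category × Emotion comparisons.

The synthetic mean pattern — the elementwise average of a run's face and
body patterns — is the equal-weight model of a part-based whole-person
representation.  Similarity between categories is always measured across
runs (pattern from run i against pattern from run j ≠ i), which removes
shared within-run noise; each Pearson correlation is Fisher-z transformed
before averaging.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CATEGORIES, EMOTIONS
from .datasets import PatternDataset
from .errors import DomainError, StructuralError
from .stats import rm_anova_from_long

#: clip bound keeping atanh finite at |r| = 1
R_CLIP = 1.0 - 1e-7


def synthetic_mean(face: np.ndarray, body: np.ndarray) -> np.ndarray:
    """Elementwise average of a face and a body pattern."""
    face = np.asarray(face, dtype=float)
    body = np.asarray(body, dtype=float)
    if face.shape != body.shape:
        raise StructuralError(f"length mismatch: {face.shape} vs {body.shape}")
    return (face + body) / 2.0


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilising atanh transform, with |r| clipped to 1 - 1e-7."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise DomainError(f"correlation outside [-1, 1]: {r!r}")
    z = np.arctanh(np.clip(r_arr, -R_CLIP, R_CLIP))
    return float(z) if np.isscalar(r) or r_arr.ndim == 0 else z


def category_pattern(
    ds: PatternDataset, subject: int, run: int, roi: str, category: str, emotion: str
) -> np.ndarray:
    """Fetch a category pattern; 'synthetic' is built within-run from face+body."""
    if category == "synthetic":
        return synthetic_mean(
            ds.get(subject, run, roi, "face", emotion),
            ds.get(subject, run, roi, "body", emotion),
        )
    return ds.get(subject, run, roi, category, emotion)


@dataclass
class CorrelationResult:
    r: float
    z: float
    pair: tuple[str, str]
    emotion: str
    roi: str
    subject: int
    n_comparisons: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    xs = x.std()
    ys = y.std()
    if xs == 0 or ys == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def cross_run_correlation(
    ds: PatternDataset,
    subject: int,
    roi: str,
    emotion: str,
    cat_a: str,
    cat_b: str,
    runs: tuple[int, ...] = (0, 1, 2),
) -> CorrelationResult:
    """Mean cross-run Fisher-z correlation between two categories.

    For every unordered run pair (i, j) both directed comparisons are made
    (cat_a from run i vs cat_b from run j, and vice versa), giving six
    z-values for distinct categories and three when cat_a == cat_b.
    Zero-variance vectors skip their pair with a warning.
    """
    zs = []
    rs = []
    for i, j in itertools.combinations(runs, 2):
        pairs = [(i, j)] if cat_a == cat_b else [(i, j), (j, i)]
        for ri, rj in pairs:
            x = category_pattern(ds, subject, ri, roi, cat_a, emotion)
            y = category_pattern(ds, subject, rj, roi, cat_b, emotion)
            r = _pearson(x, y)
            if r is None:
                warnings.warn(
                    f"zero-variance pattern in ({cat_a}, {cat_b}) runs ({ri},{rj}); "
                    "pair skipped"
                )
                continue
            rs.append(r)
            zs.append(fisher_z(r))
    if not zs:
        raise StructuralError(
            f"no valid run pairs for ({cat_a}, {cat_b}), subject {subject}, roi {roi}"
        )
    return CorrelationResult(
        r=float(np.mean(rs)),
        z=float(np.mean(zs)),
        pair=(cat_a, cat_b),
        emotion=emotion,
        roi=roi,
        subject=subject,
        n_comparisons=len(zs),
    )


def build_rsm(
    ds: PatternDataset,
    subject: int,
    roi: str,
    emotion: str,
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Symmetric category × category matrix of mean cross-run z-values.

    The diagonal holds cross-run same-category reliabilities (not forced to
    the clip maximum).
    """
    k = len(categories)
    mat = np.zeros((k, k))
    for i, ca in enumerate(categories):
        for j in range(i, k):
            z = cross_run_correlation(ds, subject, roi, emotion, ca, categories[j]).z
            mat[i, j] = mat[j, i] = z
    return pd.DataFrame(mat, index=list(categories), columns=list(categories))


def group_average_rsm(rsms: list[pd.DataFrame]) -> pd.DataFrame:
    """Elementwise mean RSM across subjects."""
    if not rsms:
        raise StructuralError("no RSMs to average")
    ref = rsms[0]
    for m in rsms[1:]:
        if not (m.index.equals(ref.index) and m.columns.equals(ref.columns)):
            raise StructuralError("RSMs have inconsistent category sets")
    return sum(rsms) / len(rsms)


def correlation_table(
    ds: PatternDataset,
    rois: tuple[str, ...] | None = None,
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Long-format table of all pairwise cross-run correlations.

    Columns: subject, roi, emotion, cat_a, cat_b, r, z.
    """
    rois = rois or ds.roi_names
    rows = []
    for s in ds.subjects:
        for roi in rois:
            for emo in EMOTIONS:
                for i, ca in enumerate(categories):
                    for cb in categories[i:]:
                        res = cross_run_correlation(ds, s, roi, emo, ca, cb)
                        rows.append(
                            {
                                "subject": s,
                                "roi": roi,
                                "emotion": emo,
                                "cat_a": ca,
                                "cat_b": cb,
                                "r": res.r,
                                "z": res.z,
                            }
                        )
    return pd.DataFrame(rows)


CONTRASTS = {
    "person_face_vs_synthetic": ("face", "synthetic"),
    "person_body_vs_synthetic": ("body", "synthetic"),
}


def category_emotion_anova(
    corr_table: pd.DataFrame, roi: str, contrast: str
) -> pd.DataFrame:
    """2 (Category) × 3 (Emotion) repeated-measures ANOVA on z-values.

    Category compares the person–X correlation (X = face or body, per the
    contrast) with the person–synthetic correlation, within subjects.
    """
    if contrast not in CONTRASTS:
        raise StructuralError(
            f"contrast must be one of {sorted(CONTRASTS)}; got {contrast!r}"
        )
    other, synth = CONTRASTS[contrast]
    sub = corr_table[corr_table["roi"] == roi]
    rows = []
    for cat in (other, synth):
        mask = (
            ((sub["cat_a"] == "person") & (sub["cat_b"] == cat))
            | ((sub["cat_a"] == cat) & (sub["cat_b"] == "person"))
        )
        for _, row in sub[mask].iterrows():
            rows.append(
                {
                    "subject": row["subject"],
                    "category": f"person_{cat}",
                    "emotion": row["emotion"],
                    "z": row["z"],
                }
            )
    long = pd.DataFrame(rows)
    if long.empty:
        raise StructuralError(f"no person–{other}/–{synth} rows for roi {roi!r}")
    return rm_anova_from_long(long, dv="z", within=("category", "emotion"))
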