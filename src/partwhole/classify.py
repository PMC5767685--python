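"""Three-emotion decoding of whole-person patterns from synthesized training sets.

Training exemplars come from the z-scored stimulus volumes of runs 1–3 in
one of four flavours — face, body, their equal-weight mean, or the
weighted mean at each subject's optimal face weight — and the test set is
the final run's whole-person volumes.  Voxels are pre-selected by a one-way
ANOVA over all nine conditions of the training runs only (p < 0.05), and a
linear support-vector machine (C = 1, one-vs-one) does the decoding.
Group results are tested against the analytic 1/3 chance level and
corrected with Benjamini–Hochberg FDR across all ROI × training-type tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .config import CONDITIONS, EMOTIONS
from .datasets import VolumePatternSet
from .errors import DegenerateDataError, StructuralError
from .stats import one_sample_t

CHANCE = 1.0 / 3.0
TRAINING_TYPES = ("face", "body", "mean", "weighted_mean")


def zscore_patterns(vols: VolumePatternSet) -> VolumePatternSet:
    """Per voxel, per run (conditions pooled): mean 0, SD 1.

    Zero-variance voxels are set to 0 with a warning.
    """
    out = dict(vols.volumes)
    cells = sorted({(s, r, roi) for (s, r, roi, _, _) in vols.volumes})
    for s, r, roi in cells:
        keys = [
            k for k in vols.volumes if (k[0], k[1], k[2]) == (s, r, roi)
        ]
        stacked = np.vstack([vols.volumes[k] for k in keys])
        if stacked.shape[0] < 2:
            raise StructuralError(f"run ({s},{r}) roi {roi} has fewer than 2 volumes")
        mu = stacked.mean(axis=0)
        sd = stacked.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance voxels set to 0 in run ({s},{r}) "
                f"roi {roi}"
            )
        sd_safe = np.where(zero, 1.0, sd)
        for k in keys:
            z = (vols.volumes[k] - mu) / sd_safe
            z[:, zero] = 0.0
            out[k] = z
    return VolumePatternSet(
        volumes=out,
        roi_names=vols.roi_names,
        n_subjects=vols.n_subjects,
        n_runs=vols.n_runs,
        provenance={**vols.provenance, "zscored": True},
    )


@dataclass
class FeatureMask:
    mask: np.ndarray
    p_threshold: float
    p_values: np.ndarray = field(repr=False, default=None)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def anova_feature_select(
    training: np.ndarray, labels: np.ndarray, p_threshold: float = 0.05
) -> FeatureMask:
    """One-way ANOVA per voxel across condition labels; keep p < threshold.

    Voxels with undefined F (zero variance) are never selected unless the
    threshold is 1.0, in which case every finite-variance voxel is kept.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise StructuralError("feature selection needs >= 2 condition labels")
    if training.shape[0] != labels.shape[0]:
        raise StructuralError("training rows and labels disagree")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant voxels produce harmless warnings
        _, p = f_classif(training, labels)
    finite = np.isfinite(p)
    if p_threshold >= 1.0:
        mask = finite
    else:
        mask = finite & (p < p_threshold)
    if not mask.any():
        raise StructuralError(
            f"feature selection at p<{p_threshold} rejected all "
            f"{training.shape[1]} voxels"
        )
    return FeatureMask(mask=mask, p_threshold=p_threshold, p_values=p)


def _stack_condition(
    vols: VolumePatternSet,
    subject: int,
    roi: str,
    body_type: str,
    emotion: str,
    runs: tuple[int, ...],
) -> np.ndarray:
    return np.vstack([vols.get(subject, r, roi, body_type, emotion) for r in runs])


def build_training_patterns(
    vols: VolumePatternSet,
    subject: int,
    roi: str,
    training_type: str,
    alpha: dict[str, float] | float | None = None,
    runs: tuple[int, ...] = (0, 1, 2),
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled training exemplars of one flavour from the analysis runs.

    ``mean`` and ``weighted_mean`` exemplars pair the k-th face volume with
    the k-th body volume of the same run and emotion.  ``weighted_mean``
    needs the subject's optimal face weight(s): a scalar or an
    emotion → α̂ mapping.

    Returns (X, y) with y the emotion labels.
    """
    if training_type not in TRAINING_TYPES:
        raise StructuralError(
            f"training_type must be one of {TRAINING_TYPES}; got {training_type!r}"
        )
    X_parts = []
    y_parts = []
    for emo in EMOTIONS:
        if training_type in ("face", "body"):
            X_e = _stack_condition(vols, subject, roi, training_type, emo, runs)
        else:
            face = _stack_condition(vols, subject, roi, "face", emo, runs)
            body = _stack_condition(vols, subject, roi, "body", emo, runs)
            if face.shape != body.shape:
                raise StructuralError(
                    "face and body exemplar counts differ; cannot pair volume-wise"
                )
            if training_type == "mean":
                a = 0.5
            else:
                if alpha is None:
                    raise StructuralError(
                        "weighted_mean training requires the optimal alpha estimates"
                    )
                a = float(alpha[emo]) if isinstance(alpha, dict) else float(alpha)
            X_e = a * face + (1 - a) * body
        X_parts.append(X_e)
        y_parts.append(np.full(X_e.shape[0], emo))
    return np.vstack(X_parts), np.concatenate(y_parts)


def decode_person_emotions(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    mask: FeatureMask | None = None,
    C: float = 1.0,
) -> float:
    """Linear SVM accuracy on whole-person test volumes."""
    if len(np.unique(train_y)) < 2:
        raise StructuralError("training set has a single class")
    if mask is not None:
        train_X = train_X[:, mask.mask]
        test_X = test_X[:, mask.mask]
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    clf.fit(train_X, train_y)
    return float(np.mean(clf.predict(test_X) == test_y))


def person_test_set(
    vols: VolumePatternSet, subject: int, roi: str, block_wise: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """The final run's whole-person volumes and labels.

    With ``block_wise=True`` volumes are averaged within consecutive
    10-volume groups before classification.
    """
    last = vols.n_runs - 1
    X_parts, y_parts = [], []
    for emo in EMOTIONS:
        X_e = vols.get(subject, last, roi, "person", emo)
        if block_wise:
            n_per_block = 10
            nb = X_e.shape[0] // n_per_block
            X_e = X_e[: nb * n_per_block].reshape(nb, n_per_block, -1).mean(axis=1)
        X_parts.append(X_e)
        y_parts.append(np.full(X_e.shape[0], emo))
    return np.vstack(X_parts), np.concatenate(y_parts)


def classify_subject_roi(
    vols: VolumePatternSet,
    subject: int,
    roi: str,
    alpha: dict[str, float] | float | None = None,
    p_threshold: float = 0.05,
    runs: tuple[int, ...] = (0, 1, 2),
    block_wise: bool = False,
    training_types: tuple[str, ...] = TRAINING_TYPES,
) -> dict[str, float]:
    """All four training flavours for one subject × ROI.

    The feature mask is computed once from the 9-condition training-run
    volumes only (never from the test run).
    """
    mask = training_run_feature_mask(vols, subject, roi, p_threshold, runs)
    test_X, test_y = person_test_set(vols, subject, roi, block_wise=block_wise)
    out = {}
    for ttype in training_types:
        X, y = build_training_patterns(vols, subject, roi, ttype, alpha=alpha, runs=runs)
        out[ttype] = decode_person_emotions(X, y, test_X, test_y, mask=mask)
    return out


def training_run_feature_mask(
    vols: VolumePatternSet,
    subject: int,
    roi: str,
    p_threshold: float = 0.05,
    runs: tuple[int, ...] = (0, 1, 2),
) -> FeatureMask:
    """ANOVA mask over all 9 conditions of the training runs only."""
    X_parts, labels = [], []
    for bt, emo in CONDITIONS:
        block = _stack_condition(vols, subject, roi, bt, emo, runs)
        X_parts.append(block)
        labels.extend([f"{bt}/{emo}"] * block.shape[0])
    return anova_feature_select(np.vstack(X_parts), np.asarray(labels), p_threshold)


def classify_dataset(
    vols: VolumePatternSet,
    alphas: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    block_wise: bool = False,
) -> pd.DataFrame:
    """Per-subject × ROI × training-type accuracies for a whole dataset.

    ``alphas`` is the optima table from
    :func:`partwhole.weights.fit_optimal_weights` (columns subject, roi,
    emotion, alpha_hat); without it the weighted-mean flavour is skipped.
    """
    types = TRAINING_TYPES if alphas is not None else ("face", "body", "mean")
    rows = []
    for s in range(vols.n_subjects):
        for roi in vols.roi_names:
            alpha = None
            if alphas is not None:
                cell = alphas[(alphas["subject"] == s) & (alphas["roi"] == roi)]
                alpha = dict(zip(cell["emotion"], cell["alpha_hat"]))
            accs = classify_subject_roi(
                vols,
                s,
                roi,
                alpha=alpha,
                p_threshold=p_threshold,
                block_wise=block_wise,
                training_types=types,
            )
            for ttype, acc in accs.items():
                rows.append(
                    {"subject": s, "roi": roi, "training_type": ttype, "accuracy": acc}
                )
    return pd.DataFrame(rows)


def permutation_null(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    test_y: np.ndarray,
    mask: FeatureMask | None,
    n_permutations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Accuracies after shuffling training labels; the empirical chance null."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_y = rng.permutation(train_y)
        while len(np.unique(perm_y[: len(perm_y)])) < 2:  # pragma: no cover
            perm_y = rng.permutation(train_y)
        accs[i] = decode_person_emotions(train_X, perm_y, test_X, test_y, mask=mask)
    return accs


def group_test_and_fdr(
    accuracies: pd.DataFrame, q: float = 0.05, chance: float = CHANCE
) -> pd.DataFrame:
    """One-sample t vs chance per ROI × training type, BH-corrected jointly.

    Returns one row per ROI × type with mean accuracy, t, raw p, adjusted p
    and significance at level ``q``.
    """
    cells = (
        accuracies.groupby(["roi", "training_type"], sort=True)["accuracy"]
        .apply(list)
        .reset_index()
    )
    n_subj = accuracies["subject"].nunique()
    for _, row in cells.iterrows():
        if len(row["accuracy"]) != n_subj:
            raise StructuralError(
                f"missing subjects in cell ({row['roi']}, {row['training_type']})"
            )
    stats_rows = []
    for _, row in cells.iterrows():
        vals = np.asarray(row["accuracy"])
        try:
            t, p, df = one_sample_t(vals, chance)
            degenerate = False
        except DegenerateDataError:
            # all subjects identical but off chance: t undefined; report a
            # conservative p = 1 so the FDR family size is preserved
            t, p, df, degenerate = np.nan, 1.0, len(vals) - 1, True
        stats_rows.append(
            {
                "roi": row["roi"],
                "training_type": row["training_type"],
                "mean_accuracy": float(vals.mean()),
                "t": t,
                "df": df,
                "p_raw": p,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(stats_rows)
    reject, p_adj, *_ = multipletests(out["p_raw"], alpha=q, method="fdr_bh")
    out["p_fdr"] = p_adj
    out["significant"] = reject
    out.attrs["n_comparisons"] = len(out)
    return out
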