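"""Recover condition patterns from time series: GLM betas and direct volumes.

Two routes mirror the two MVPA procedures used downstream: ordinary
least-squares beta patterns (feeding the similarity and weight analyses)
and direct extraction of stimulus-block volumes from the time series
(feeding classification, 20 volumes per condition per run under the
default design).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .config import DesignSpec
from .datasets import PatternDataset, TimeSeriesDataset, VolumePatternSet
from .errors import DegenerateDataError, StructuralError
from .simulate import condition_regressors

#: default hemodynamic alignment shift for volume extraction (1 TR); with the
#: default design this labels exactly 20 volumes per condition per run.
DEFAULT_SHIFT_S = 2.0


def discard_initial_volumes(ts: TimeSeriesDataset) -> TimeSeriesDataset:
    """Drop each run's equilibration volumes and shift its timeline."""
    volumes = {}
    nuisance = {}
    designs = {}
    for (s, r), design in ts.designs.items():
        k = design.n_discard
        designs[(s, r)] = design.shifted(k)
        nuisance[(s, r)] = ts.nuisance[(s, r)][k:]
    for (s, r, roi), mat in ts.volumes.items():
        k = ts.designs[(s, r)].n_discard
        if mat.shape[0] <= k:
            raise StructuralError(
                f"run ({s},{r}) roi {roi} has {mat.shape[0]} volumes, cannot "
                f"discard {k}"
            )
        volumes[(s, r, roi)] = mat[k:]
    return TimeSeriesDataset(
        volumes=volumes,
        nuisance=nuisance,
        designs=designs,
        roi_names=ts.roi_names,
        n_subjects=ts.n_subjects,
        n_runs=ts.n_runs,
        provenance={**ts.provenance, "discarded": True},
    )


@dataclass
class DesignMatrix:
    """time × regressor matrix with labelled columns."""

    matrix: np.ndarray
    condition_labels: list[tuple[str, str]]
    nuisance_labels: list[str]

    @property
    def labels(self) -> list:
        return list(self.condition_labels) + list(self.nuisance_labels) + ["intercept"]

    @property
    def n_condition(self) -> int:
        return len(self.condition_labels)


def build_design_matrix(design: DesignSpec, nuisance: np.ndarray) -> DesignMatrix:
    """Condition regressors + nuisance + temporal derivatives + intercept.

    Zero nuisance columns (and the then-zero derivative columns) are dropped
    with a warning; genuine collinearity among the remaining columns raises
    with the offending labels.
    """
    X_cond, conds = condition_regressors(design)
    if nuisance.shape[0] != X_cond.shape[0]:
        raise StructuralError(
            f"nuisance rows {nuisance.shape[0]} != design volumes {X_cond.shape[0]}"
        )
    if not np.any(np.abs(X_cond) > 1e-12):
        warnings.warn("all condition regressors are zero (degenerate design)")
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for j in range(nuisance.shape[1]):
        col = nuisance[:, j]
        if np.allclose(col, 0):
            warnings.warn(f"nuisance_{j} is all zero; column dropped")
            continue
        cols.append(col)
        labels.append(f"nuisance_{j}")
        d = np.gradient(col)
        if np.allclose(d, 0):
            warnings.warn(f"derivative of nuisance_{j} is zero; column dropped")
        else:
            cols.append(d)
            labels.append(f"d_nuisance_{j}")
    parts = [X_cond] + ([np.column_stack(cols)] if cols else [])
    parts.append(np.ones((X_cond.shape[0], 1)))
    X = np.column_stack(parts)
    all_labels = list(conds) + labels + ["intercept"]
    _check_rank(X, all_labels)
    return DesignMatrix(matrix=X, condition_labels=conds, nuisance_labels=labels)


def _check_rank(X: np.ndarray, labels: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the deficiency via QR pivoting
        from scipy.linalg import qr

        _, r, piv = qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [labels[p] for p in piv[len(diag) :]]
        raise DegenerateDataError(f"design matrix rank deficient; collinear columns: {bad}")


def estimate_betas(ts: TimeSeriesDataset, shift_timeline: bool = True) -> PatternDataset:
    """Per-run OLS beta patterns for every condition regressor.

    ``ts`` should already have its initial volumes discarded (pass a raw
    dataset through :func:`discard_initial_volumes` first, or leave
    ``shift_timeline=True`` to have it applied here when needed).
    """
    if shift_timeline and any(d.n_discard > 0 for d in ts.designs.values()):
        ts = discard_initial_volumes(ts)
    patterns = {}
    for (s, r), design in ts.designs.items():
        dm = build_design_matrix(design, ts.nuisance[(s, r)])
        X = dm.matrix
        for roi in ts.roi_names:
            Y = ts.volumes[(s, r, roi)]
            if not np.all(np.isfinite(Y)):
                raise StructuralError(f"non-finite values in run ({s},{r}) roi {roi}")
            beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
            for j, (bt, emo) in enumerate(dm.condition_labels):
                patterns[(s, r, roi, bt, emo)] = beta[j]
    return PatternDataset(
        patterns=patterns,
        roi_names=ts.roi_names,
        n_subjects=ts.n_subjects,
        n_runs=ts.n_runs,
        provenance={**ts.provenance, "source": "glm_betas"},
    )


def condition_volume_indices(
    design: DesignSpec, shift_s: float = DEFAULT_SHIFT_S
) -> dict[tuple[str, str], np.ndarray]:
    """Volume indices per condition on the design's own timeline.

    A volume acquired at time t is labelled with a condition when
    ``t - shift`` falls inside one of that condition's stimulation blocks
    (half-open [onset, onset + block duration)).  Response-window and
    fixation volumes receive no label.  Shifted windows extending past the
    run end are truncated with a warning; a window starting past the run
    end raises.
    """
    if shift_s < 0:
        raise StructuralError(f"shift_s must be >= 0; got {shift_s}")
    if design.condition_order is None:
        raise StructuralError("design has no condition_order")
    run_end = design.total_duration_s
    times = np.arange(design.n_volumes) * design.tr_s
    out: dict[tuple[str, str], list[int]] = {}
    claimed = np.zeros(design.n_volumes, dtype=bool)
    for onset, cond in zip(design.block_onsets_s(), design.condition_order):
        lo = onset + shift_s
        hi = onset + design.block_duration_s + shift_s
        if lo >= run_end:
            raise StructuralError(
                f"shift {shift_s} s pushes block at {onset} s past run end {run_end} s"
            )
        if hi > run_end + 1e-9:
            warnings.warn(
                f"shifted block window [{lo}, {hi}) truncated at run end {run_end} s"
            )
        sel = np.nonzero((times >= lo - 1e-9) & (times < hi - 1e-9))[0]
        if np.any(claimed[sel]):
            raise StructuralError("shifted block windows overlap; reduce shift")
        claimed[sel] = True
        out.setdefault(tuple(cond), []).extend(sel.tolist())
    return {c: np.asarray(sorted(idx)) for c, idx in out.items()}


def extract_condition_volumes(
    ts: TimeSeriesDataset, shift_s: float = DEFAULT_SHIFT_S, shift_timeline: bool = True
) -> VolumePatternSet:
    """Label stimulus volumes by condition (second MVPA procedure)."""
    if shift_timeline and any(d.n_discard > 0 for d in ts.designs.values()):
        ts = discard_initial_volumes(ts)
    volumes = {}
    for (s, r), design in ts.designs.items():
        idx_map = condition_volume_indices(design, shift_s)
        for roi in ts.roi_names:
            Y = ts.volumes[(s, r, roi)]
            for (bt, emo), idx in idx_map.items():
                volumes[(s, r, roi, bt, emo)] = Y[idx]
    return VolumePatternSet(
        volumes=volumes,
        roi_names=ts.roi_names,
        n_subjects=ts.n_subjects,
        n_runs=ts.n_runs,
        provenance={**ts.provenance, "source": "volume_extraction", "shift_s": shift_s},
    )
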