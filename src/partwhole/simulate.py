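"""Synthetic data generators for every stage of the pipeline.

Pattern model
-------------
Per subject and ROI, unit-variance Gaussian templates are drawn for each
emotion: a face template ``f_e``, a body template ``b_e`` (between-emotion
correlation ``rho`` induced by a shared + idiosyncratic mixture), and an
independent person-only component ``u_e``.  The whole-person template is

    p_e = gamma * (alpha_e * f_e + (1 - alpha_e) * b_e) + (1 - gamma) * u_e

so ``gamma = 1`` is the pure part-based scenario and ``gamma < 1`` mixes in
an integrated, person-only signal.  Every run-level pattern is its template
plus i.i.d. Gaussian noise of scale ``sigma_noise``; runs 1-3 carry all nine
conditions and the final run only the three whole-person conditions.

Forward time-series model
-------------------------
Each voxel's course is the sum of condition regressors (block boxcars
convolved with the canonical double-gamma response) weighted by that run's
pattern values, a nuisance contribution (six motion-like random walks and
two slow tissue-average signals), a constant baseline, and white (optionally
AR(1)) noise.  Ordinary least squares on the matching design matrix
therefore recovers the generating amplitudes exactly in the noiseless case.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .config import (
    CONDITIONS,
    EMOTIONS,
    DesignSpec,
    ScenarioConfig,
    balanced_condition_order,
)
from .datasets import PatternDataset, TimeSeriesDataset, person_conditions
from .errors import ConfigurationError, StructuralError
from .hrf import convolve_blocks
from .stimstats import VideoClip


# ---------------------------------------------------------------------------
# condition patterns


def _draw_templates(rng: np.random.Generator, config: ScenarioConfig, n_vox: int):
    """Per-emotion face/body/person templates for one subject × ROI."""
    rho = config.rho_emotion
    shared_f = rng.standard_normal(n_vox)
    shared_b = rng.standard_normal(n_vox)
    gamma = config.effective_gamma
    templates: dict[tuple[str, str], np.ndarray] = {}
    for emo in EMOTIONS:
        f = np.sqrt(rho) * shared_f + np.sqrt(1 - rho) * rng.standard_normal(n_vox)
        b = np.sqrt(rho) * shared_b + np.sqrt(1 - rho) * rng.standard_normal(n_vox)
        u = rng.standard_normal(n_vox)
        a = float(config.alpha_true[emo])
        p = gamma * (a * f + (1 - a) * b) + (1 - gamma) * u
        templates[("face", emo)] = f
        templates[("body", emo)] = b
        templates[("person", emo)] = p
    return templates


def generate_condition_patterns(config: ScenarioConfig) -> PatternDataset:
    """Draw the full subject × run × ROI × condition pattern dataset."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    sigma = config.sigma_noise
    patterns = {}
    full_runs = range(min(config.n_runs, 3))
    person_only_runs = range(3, config.n_runs)
    for s in range(config.n_subjects):
        for roi in config.roi_names:
            templ = _draw_templates(rng, config, config.n_voxels)
            for r in full_runs:
                for bt, emo in CONDITIONS:
                    noise = rng.standard_normal(config.n_voxels)
                    patterns[(s, r, roi, bt, emo)] = templ[(bt, emo)] + sigma * noise
            for r in person_only_runs:
                for bt, emo in person_conditions():
                    noise = rng.standard_normal(config.n_voxels)
                    patterns[(s, r, roi, bt, emo)] = templ[(bt, emo)] + sigma * noise
    ds = PatternDataset(
        patterns=patterns,
        roi_names=tuple(config.roi_names),
        n_subjects=config.n_subjects,
        n_runs=config.n_runs,
        provenance={"config": config.to_dict(), "source": "generator"},
    )
    ds.validate_condition_layout()
    return ds


def noise_for_person_synthetic_r(
    target_r: float, alpha: float = 0.5, gamma: float = 1.0
) -> float:
    """Pattern-noise sigma giving an expected person–synthetic-mean cross-run
    Pearson correlation of ``target_r`` under the generative model.

    With unit-variance independent templates, cov(person, synthetic) = gamma/2,
    var(person) = gamma^2 (alpha^2 + (1-alpha)^2) + (1-gamma)^2 and
    var(synthetic mean of two noisy runs' parts) = 1/2 + sigma^2/2, so the
    expected cross-run correlation is available in closed form and the target
    is inverted numerically.
    """
    if not (0 < target_r < 1):
        raise ConfigurationError(f"target_r must be in (0, 1); got {target_r}")
    var_p = gamma**2 * (alpha**2 + (1 - alpha) ** 2) + (1 - gamma) ** 2
    cov = gamma / 2.0

    def expected_r(sig: float) -> float:
        return cov / np.sqrt((var_p + sig**2) * (0.5 + sig**2 / 2))

    if expected_r(0.0) < target_r:
        raise ConfigurationError(
            f"target_r={target_r} unreachable: noiseless correlation is "
            f"{expected_r(0.0):.3f} for alpha={alpha}, gamma={gamma}"
        )
    return float(brentq(lambda s: expected_r(s) - target_r, 0.0, 1e3))


# ---------------------------------------------------------------------------
# time series


def _nuisance_regressors(rng: np.random.Generator, n_vol: int) -> np.ndarray:
    """Six motion-like random walks plus two slow tissue-average signals."""
    motion = np.cumsum(rng.normal(0.0, 0.05, size=(n_vol, 6)), axis=0)
    t = np.arange(n_vol)
    tissue = np.column_stack(
        [
            np.sin(2 * np.pi * t / rng.uniform(40, 120) + rng.uniform(0, 2 * np.pi))
            + rng.normal(0, 0.1, n_vol)
            for _ in range(2)
        ]
    )
    nuis = np.column_stack([motion, tissue])
    nuis -= nuis.mean(axis=0)
    return nuis


def generate_timeseries(
    patterns: PatternDataset,
    design: DesignSpec,
    noise_sd: float,
    seed: int,
    nuisance_scale: float = 0.3,
    baseline: float = 100.0,
    ar_coef: float = 0.0,
) -> TimeSeriesDataset:
    """Forward-model block-design time series from a pattern dataset.

    ``noise_sd`` is the white-noise SD in the same response units as the
    pattern amplitudes; ``nuisance_scale`` scales per-voxel loadings on the
    eight nuisance regressors (0 disables the nuisance contribution);
    ``ar_coef`` optionally colours the noise as AR(1).
    """
    if not (0 <= ar_coef < 1):
        raise ConfigurationError(f"ar_coef must be in [0, 1); got {ar_coef}")
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0; got {noise_sd}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_vol = design.n_volumes
    volumes: dict[tuple[int, int, str], np.ndarray] = {}
    nuisance: dict[tuple[int, int], np.ndarray] = {}
    designs: dict[tuple[int, int], DesignSpec] = {}

    for s in patterns.subjects:
        for r in range(patterns.n_runs):
            conds = (
                list(CONDITIONS)
                if r in patterns.analysis_runs()
                else list(person_conditions())
            )
            order = balanced_condition_order(conds, design.n_blocks, rng)
            run_design = design.with_order(order)
            designs[(s, r)] = run_design
            nuis = _nuisance_regressors(rng, n_vol)
            nuisance[(s, r)] = nuis
            X, conds = condition_regressors(run_design)
            for roi in patterns.roi_names:
                n_vox = patterns.n_voxels(roi)
                A = np.column_stack(
                    [patterns.get(s, r, roi, bt, emo) for bt, emo in conds]
                )  # (n_vox, n_cond)
                W = nuisance_scale * rng.standard_normal((8, n_vox))
                eps = rng.normal(0.0, noise_sd, size=(n_vol, n_vox)) if noise_sd else 0.0
                if ar_coef and noise_sd:
                    from scipy.signal import lfilter

                    eps = lfilter([1.0], [1.0, -ar_coef], eps, axis=0)
                Y = X @ A.T + nuis @ W + baseline + eps
                volumes[(s, r, roi)] = Y
    return TimeSeriesDataset(
        volumes=volumes,
        nuisance=nuisance,
        designs=designs,
        roi_names=patterns.roi_names,
        n_subjects=patterns.n_subjects,
        n_runs=patterns.n_runs,
        provenance={
            "patterns": patterns.provenance,
            "noise_sd": noise_sd,
            "nuisance_scale": nuisance_scale,
            "ar_coef": ar_coef,
            "seed": seed,
        },
    )


def condition_regressors(design: DesignSpec) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Convolved boxcar matrix (volumes × conditions) plus its column labels.

    Columns follow first appearance in the run's block order.
    """
    if design.condition_order is None:
        raise StructuralError("design has no condition_order")
    onsets = np.asarray(design.block_onsets_s())
    conds = list(dict.fromkeys(design.condition_order))
    cols = []
    for c in conds:
        c_onsets = onsets[[i for i, cc in enumerate(design.condition_order) if cc == c]]
        cols.append(
            convolve_blocks(
                c_onsets, design.block_duration_s, design.total_duration_s, design.tr_s
            )
        )
    return np.column_stack(cols), conds


# ---------------------------------------------------------------------------
# video fixtures


def generate_video(
    height: int,
    width: int,
    n_frames: int,
    change_spec: dict | None = None,
    seed: int = 0,
    frame_rate: float = 25.0,
) -> VideoClip:
    """Grayscale frame stack with programmable inter-frame changes.

    ``change_spec`` options:

    * ``None`` or ``{"kind": "none"}`` — all frames identical;
    * ``{"kind": "pixel_step", "frame": k, "pixel": (r, c), "from": a, "to": b}``
      — one pixel jumps from ``a`` to ``b`` at frame ``k``;
    * ``{"kind": "random_motion", "n_pixels": k, "amplitude": a}`` — each
      frame displaces ``k`` random pixels by ±``a`` around the base image.

    A ``"base"`` key (scalar in [0, 255]) fixes the background luminance;
    otherwise the base image is drawn uniformly in [0, 255].
    """
    if height < 1 or width < 1 or n_frames < 1:
        raise ConfigurationError("video dimensions must be >= 1")
    spec = dict(change_spec or {"kind": "none"})
    kind = spec.get("kind", "none")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if "base" in spec:
        base_val = float(spec["base"])
        _check_lum(base_val)
        base = np.full((height, width), base_val)
    else:
        base = rng.uniform(0, 255, size=(height, width))
    frames = np.repeat(base[None], n_frames, axis=0)

    if kind == "none":
        pass
    elif kind == "pixel_step":
        k = int(spec["frame"])
        r, c = spec["pixel"]
        lo, hi = float(spec["from"]), float(spec["to"])
        _check_lum(lo)
        _check_lum(hi)
        frames[:k, r, c] = lo
        frames[k:, r, c] = hi
    elif kind == "random_motion":
        k = int(spec["n_pixels"])
        amp = float(spec["amplitude"])
        if amp < 0:
            raise ConfigurationError("amplitude must be >= 0")
        for i in range(n_frames):
            idx = rng.choice(height * width, size=min(k, height * width), replace=False)
            rr, cc = np.unravel_index(idx, (height, width))
            frames[i, rr, cc] = np.clip(
                base[rr, cc] + rng.choice([-amp, amp], size=rr.size), 0, 255
            )
    else:
        raise ConfigurationError(f"unknown change_spec kind {kind!r}")
    return VideoClip(frames=frames, frame_rate=frame_rate)


def _check_lum(v: float) -> None:
    if not (0 <= v <= 255):
        raise ConfigurationError(f"luminance {v} outside [0, 255]")


def generate_stimulus_corpus(
    n_actors: int = 8,
    seed: int = 0,
    height: int = 24,
    width: int = 18,
    n_frames: int = 50,
    emotion_movement_shift: dict[str, float] | None = None,
) -> list[dict]:
    """Synthetic stand-in for a dynamic emotion-stimulus corpus.

    ``n_actors`` actors × 3 emotions × 3 stimulus types (face / body /
    person) = 72 clips at the default.  Movement parameters are drawn
    independently of emotion (the corpus-validation null); stimulus type
    modulates contrast, mirroring the one low-level dimension on which real
    cut-out stimuli genuinely differ.  ``emotion_movement_shift`` optionally
    adds a per-emotion movement offset to construct a non-null corpus.

    Returns a list of ``{"clip", "actor", "emotion", "stim_type"}`` records.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shift = emotion_movement_shift or {}
    contrast_by_type = {"face": 18.0, "body": 24.0, "person": 30.0}
    records = []
    for actor in range(n_actors):
        for emo in EMOTIONS:
            for bt in ("face", "body", "person"):
                field = rng.standard_normal((height, width))
                base = np.clip(24.0 + contrast_by_type[bt] * field, 0, 255)
                frames = np.repeat(base[None], n_frames, axis=0)
                n_moving = rng.integers(8, 25)
                amp = rng.uniform(25, 60) + float(shift.get(emo, 0.0))
                for i in range(1, n_frames):
                    idx = rng.choice(height * width, size=n_moving, replace=False)
                    rr, cc = np.unravel_index(idx, (height, width))
                    frames[i, rr, cc] = np.clip(
                        base[rr, cc] + rng.choice([-amp, amp], size=n_moving), 0, 255
                    )
                records.append(
                    {
                        "clip": VideoClip(frames=frames, frame_rate=25.0),
                        "actor": actor,
                        "emotion": emo,
                        "stim_type": bt,
                    }
                )
    return records
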