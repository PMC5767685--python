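"""Low-level stimulus statistics for grayscale video clips.

Three per-clip scalars characterise a clip on the 0–255 luminance scale:

* **movement** — for each adjacent frame pair, the absolute luminance change
  per pixel is averaged over the pixels whose change exceeds a threshold
  (default 10; pairs with no supra-threshold pixel contribute 0), then
  averaged over pairs;
* **RMS contrast** — the population standard deviation of pixel luminance
  within a frame, averaged over frames;
* **mean luminance** — the grand mean over all pixels and frames.

Group comparisons run pairwise t-tests between emotions (paired by actor
when the groups align, otherwise independent) and a one-way ANOVA across
stimulus types, per statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ConfigurationError, DegenerateDataError, StructuralError


@dataclass
class VideoClip:
    """time × height × width luminance stack, values in [0, 255]."""

    frames: np.ndarray
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise StructuralError("frames must be a non-empty (time, height, width) array")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise ConfigurationError("luminance values outside [0, 255]")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def movement_score(
    clip: VideoClip, threshold: float = 10.0, threshold_on: str = "difference"
) -> float:
    """Mean supra-threshold inter-frame luminance change.

    With ``threshold_on="difference"`` (default) the threshold applies to the
    inter-frame difference image: pixels whose absolute change exceeds
    ``threshold`` enter the average.  The alternative reading,
    ``threshold_on="luminance"``, averages the change over pixels whose
    luminance (max of the two frames) exceeds the threshold.  Frame pairs
    with no qualifying pixel count as zero movement.
    """
    if clip.n_frames < 2:
        raise StructuralError("movement_score needs at least 2 frames")
    if threshold_on not in ("difference", "luminance"):
        raise ConfigurationError(
            f"threshold_on must be 'difference' or 'luminance'; got {threshold_on!r}"
        )
    diffs = np.abs(np.diff(clip.frames, axis=0))  # (pairs, h, w)
    per_pair = np.zeros(diffs.shape[0])
    for i, d in enumerate(diffs):
        if threshold_on == "difference":
            mask = d > threshold
        else:
            mask = np.maximum(clip.frames[i], clip.frames[i + 1]) > threshold
        per_pair[i] = d[mask].mean() if mask.any() else 0.0
    return float(per_pair.mean())


def rms_contrast(clip: VideoClip) -> float:
    """Per-frame population SD of pixel luminance, averaged over frames."""
    return float(clip.frames.reshape(clip.n_frames, -1).std(axis=1, ddof=0).mean())


def mean_luminance(clip: VideoClip) -> float:
    return float(clip.frames.mean())


def clip_stats(
    clip: VideoClip, threshold: float = 10.0, threshold_on: str = "difference"
) -> dict[str, float]:
    return {
        "movement": (
            movement_score(clip, threshold, threshold_on) if clip.n_frames >= 2 else 0.0
        ),
        "contrast": rms_contrast(clip),
        "luminance": mean_luminance(clip),
    }


def corpus_stats(records: list[dict], threshold: float = 10.0) -> pd.DataFrame:
    """Per-clip statistics table for a list of labelled clip records."""
    rows = []
    for rec in records:
        row = {k: v for k, v in rec.items() if k != "clip"}
        row.update(clip_stats(rec["clip"], threshold))
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    stats_df: pd.DataFrame,
    group_col: str = "emotion",
    type_col: str | None = "stim_type",
    statistics: tuple[str, ...] = ("movement", "contrast", "luminance"),
    paired: bool = True,
) -> pd.DataFrame:
    """Pairwise group t-tests per statistic, plus a one-way ANOVA across types.

    With ``paired=True`` clips are paired by their order within each group
    (e.g. by actor) and group sizes must match; otherwise Welch t-tests are
    used.  Returns a long table with columns
    (statistic, test, group_a, group_b, t_or_F, df, p).
    """
    groups = list(dict.fromkeys(stats_df[group_col]))
    if len(groups) < 2:
        raise StructuralError("need at least two groups to compare")
    rows = []
    for stat in statistics:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                xa = stats_df.loc[stats_df[group_col] == ga, stat].to_numpy()
                xb = stats_df.loc[stats_df[group_col] == gb, stat].to_numpy()
                if len(xa) < 2 or len(xb) < 2:
                    raise DegenerateDataError(
                        f"group sizes too small for {ga!r} vs {gb!r}"
                    )
                if paired:
                    if len(xa) != len(xb):
                        raise StructuralError(
                            f"paired comparison needs equal sizes ({ga}: {len(xa)}, "
                            f"{gb}: {len(xb)})"
                        )
                    d = xa - xb
                    if np.allclose(d, 0):
                        # identical groups: difference is exactly zero
                        res = type("R", (), {"statistic": 0.0, "pvalue": 1.0})
                    else:
                        res = sstats.ttest_rel(xa, xb)
                    df = len(xa) - 1
                else:
                    res = sstats.ttest_ind(xa, xb, equal_var=False)
                    df = res.df
                rows.append(
                    {
                        "statistic": stat,
                        "test": "paired_t" if paired else "welch_t",
                        "group_a": ga,
                        "group_b": gb,
                        "t_or_F": float(res.statistic),
                        "df": float(df),
                        "p": float(res.pvalue),
                    }
                )
        if type_col is not None and type_col in stats_df.columns:
            type_groups = [
                stats_df.loc[stats_df[type_col] == t, stat].to_numpy()
                for t in dict.fromkeys(stats_df[type_col])
            ]
            if len(type_groups) >= 2:
                f_res = sstats.f_oneway(*type_groups)
                rows.append(
                    {
                        "statistic": stat,
                        "test": "anova_types",
                        "group_a": "all_types",
                        "group_b": "",
                        "t_or_F": float(f_res.statistic),
                        "df": float(len(type_groups) - 1),
                        "p": float(f_res.pvalue),
                    }
                )
    return pd.DataFrame(rows)
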