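"""In-memory containers shared by every analysis stage.

``PatternDataset`` is the common currency: one voxel vector per
(subject, run, ROI, body type, emotion) cell.  Runs 1..R-1 hold all nine
conditions; the last run holds only the three whole-person conditions.
``TimeSeriesDataset`` carries the simulated (or imported) volume × voxel
matrices plus the nuisance regressors and the design they were built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import BODY_TYPES, CONDITIONS, EMOTIONS, DesignSpec
from .errors import StructuralError

#: key of one pattern cell
Key = tuple[int, int, str, str, str]  # (subject, run, roi, body_type, emotion)


def person_conditions() -> tuple[tuple[str, str], ...]:
    return tuple((bt, emo) for bt, emo in CONDITIONS if bt == "person")


@dataclass
class PatternDataset:
    """Subject × run × ROI × condition → voxel vector."""

    patterns: dict[Key, np.ndarray]
    roi_names: tuple[str, ...]
    n_subjects: int
    n_runs: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths: dict[str, int] = {}
        for (s, r, roi, bt, emo), v in self.patterns.items():
            v = np.asarray(v, dtype=float)
            if v.ndim != 1:
                raise StructuralError(f"pattern {(s, r, roi, bt, emo)} is not a vector")
            if roi in lengths and lengths[roi] != v.size:
                raise StructuralError(
                    f"ROI {roi!r} mixes voxel counts {lengths[roi]} and {v.size}"
                )
            lengths.setdefault(roi, v.size)
        self._lengths = lengths

    def get(self, subject: int, run: int, roi: str, body_type: str, emotion: str) -> np.ndarray:
        key = (subject, run, roi, body_type, emotion)
        try:
            return self.patterns[key]
        except KeyError:
            raise StructuralError(f"missing pattern cell {key}") from None

    def has(self, subject: int, run: int, roi: str, body_type: str, emotion: str) -> bool:
        return (subject, run, roi, body_type, emotion) in self.patterns

    def n_voxels(self, roi: str) -> int:
        return self._lengths[roi]

    @property
    def subjects(self) -> range:
        return range(self.n_subjects)

    def analysis_runs(self) -> range:
        """Runs carrying all nine conditions (all but the final person-only run)."""
        return range(min(self.n_runs, 3))

    def to_frame(self) -> pd.DataFrame:
        """Long/wide tabular layout: one row per cell, voxels as v0..v{V-1}."""
        rows = []
        for (s, r, roi, bt, emo), v in sorted(self.patterns.items()):
            row = {"subject": s, "run": r, "roi": roi, "body_type": bt, "emotion": emo}
            row.update({f"v{i}": x for i, x in enumerate(v)})
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "PatternDataset":
        vox_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
        vox_cols.sort(key=lambda c: int(c[1:]))
        patterns: dict[Key, np.ndarray] = {}
        for _, row in df.iterrows():
            key = (
                int(row["subject"]),
                int(row["run"]),
                str(row["roi"]),
                str(row["body_type"]),
                str(row["emotion"]),
            )
            vals = row[vox_cols].to_numpy(dtype=float)
            patterns[key] = vals[~np.isnan(vals)]
        rois = tuple(dict.fromkeys(df["roi"].astype(str)))
        return cls(
            patterns=patterns,
            roi_names=rois,
            n_subjects=int(df["subject"].max()) + 1,
            n_runs=int(df["run"].max()) + 1,
            provenance=provenance or {},
        )

    def validate_condition_layout(self) -> None:
        """Runs 1..R-1 must hold all 9 conditions; the last run person only."""
        for s in self.subjects:
            for roi in self.roi_names:
                for r in self.analysis_runs():
                    for bt, emo in CONDITIONS:
                        if not self.has(s, r, roi, bt, emo):
                            raise StructuralError(
                                f"subject {s} run {r} roi {roi} misses ({bt}, {emo})"
                            )
                if self.n_runs > 3:
                    last = self.n_runs - 1
                    for bt, emo in person_conditions():
                        if not self.has(s, last, roi, bt, emo):
                            raise StructuralError(
                                f"subject {s} final run roi {roi} misses ({bt}, {emo})"
                            )


@dataclass
class TimeSeriesDataset:
    """Simulated BOLD-like volumes plus nuisance regressors per run.

    ``volumes``:  (subject, run, roi) → (time × voxel) matrix on the acquired
    timeline (discarded volumes still present until
    :func:`partwhole.glm.discard_initial_volumes` removes them).
    ``nuisance``: (subject, run) → (time × 8) matrix emulating six
    motion-like regressors and two tissue-average signals.
    ``designs``:  (subject, run) → DesignSpec with that run's condition order.
    """

    volumes: dict[tuple[int, int, str], np.ndarray]
    nuisance: dict[tuple[int, int], np.ndarray]
    designs: dict[tuple[int, int], DesignSpec]
    roi_names: tuple[str, ...]
    n_subjects: int
    n_runs: int
    provenance: dict = field(default_factory=dict)

    N_NUISANCE: int = 8

    def __post_init__(self) -> None:
        for (s, r), nuis in self.nuisance.items():
            if nuis.shape[1] != self.N_NUISANCE:
                raise StructuralError(
                    f"run ({s},{r}) has {nuis.shape[1]} nuisance regressors, expected 8"
                )
            design = self.designs[(s, r)]
            if nuis.shape[0] != design.n_volumes:
                raise StructuralError(
                    f"run ({s},{r}) nuisance rows {nuis.shape[0]} != design "
                    f"volumes {design.n_volumes}"
                )
        for (s, r, roi), mat in self.volumes.items():
            design = self.designs[(s, r)]
            if mat.shape[0] != design.n_volumes:
                raise StructuralError(
                    f"run ({s},{r}) roi {roi} has {mat.shape[0]} volumes, design "
                    f"says {design.n_volumes}"
                )

    def get(self, subject: int, run: int, roi: str) -> np.ndarray:
        return self.volumes[(subject, run, roi)]


@dataclass
class VolumePatternSet:
    """Per (subject, run, ROI, condition): a (volumes × voxel) matrix.

    Produced by direct time-series volume extraction (the second MVPA
    procedure); consumed by the classification stage.
    """

    volumes: dict[Key, np.ndarray]
    roi_names: tuple[str, ...]
    n_subjects: int
    n_runs: int
    provenance: dict = field(default_factory=dict)

    def get(self, subject: int, run: int, roi: str, body_type: str, emotion: str) -> np.ndarray:
        key = (subject, run, roi, body_type, emotion)
        try:
            return self.volumes[key]
        except KeyError:
            raise StructuralError(f"missing volume cell {key}") from None

    def conditions_in(self, subject: int, run: int, roi: str) -> list[tuple[str, str]]:
        return [
            (bt, emo)
            for (s, r, rr, bt, emo) in self.volumes
            if (s, r, rr) == (subject, run, roi)
        ]
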