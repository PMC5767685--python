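"""Configuration objects for the generative scenarios and the block design.

The two generative scenarios formalise the competing hypotheses about
whole-person coding:

* ``part_based`` — the whole-person template is exactly a convex combination
  of the face and body templates (equivalently ``gamma = 1``);
* ``integrated`` — a fraction ``1 - gamma`` of the whole-person template is
  carried by a person-only component independent of face and body.

The block design mirrors a standard slow event/block emotion-judgement
protocol: each run holds 18 blocks of 8 trials (2 s video + 0.5 s ISI),
a 2 s response window after each block, 10 s fixation between adjacent
blocks, TR = 2 s, and 5 initial equilibration volumes that are discarded
before analysis.  That arithmetic gives 288 acquired and 283 retained
volumes per run, and 20 stimulus volumes per condition per run.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ConfigurationError

EMOTIONS: tuple[str, ...] = ("happiness", "anger", "fear")
BODY_TYPES: tuple[str, ...] = ("face", "body", "person")
#: similarity-analysis categories; "synthetic" is the elementwise face/body mean
CATEGORIES: tuple[str, ...] = ("face", "body", "person", "synthetic")
#: the 9 experimental conditions of runs 1-3
CONDITIONS: tuple[tuple[str, str], ...] = tuple(
    (bt, emo) for emo in EMOTIONS for bt in BODY_TYPES
)
SCENARIOS: tuple[str, ...] = ("part_based", "integrated")

DEFAULT_ROIS: tuple[str, ...] = ("AMG", "IFG", "OFA", "EBA", "STS", "FG", "insula")


def _check_unit_interval(name: str, value: float, *, open_right: bool = False) -> None:
    hi_ok = value < 1 if open_right else value <= 1
    if not (0 <= value and hi_ok and math.isfinite(value)):
        hi = "1)" if open_right else "1]"
        raise ConfigurationError(f"{name} must lie in [0, {hi}; got {value!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative parameters for a synthetic multi-subject pattern dataset.

    Parameters
    ----------
    scenario:
        ``"part_based"`` or ``"integrated"``.  ``part_based`` forces the
        person template to be the pure convex combination (gamma is treated
        as 1 regardless of the ``gamma`` field).
    alpha_true:
        Face weight per emotion, each in [0, 1]; the body weight is
        ``1 - alpha``.
    gamma:
        Fraction of the person template explained by the face/body
        combination (1 = pure part-based); only meaningful for the
        integrated scenario.
    sigma_noise:
        Standard deviation of the i.i.d. Gaussian run-level pattern noise,
        in the same arbitrary response units as the unit-variance templates.
    rho_emotion:
        Target correlation between the templates of different emotions
        within a body type, in [0, 1).
    n_voxels, n_subjects, n_runs:
        Dataset dimensions.  Runs 1..n_runs-1 carry all 9 conditions; the
        final run carries only the 3 whole-person conditions.
    roi_names:
        Opaque region labels; each region gets independent templates.
    seed:
        Master seed; all randomness fans out from it deterministically.
    """

    scenario: str = "part_based"
    alpha_true: Mapping[str, float] = field(
        default_factory=lambda: {"happiness": 0.65, "anger": 0.5, "fear": 0.5}
    )
    gamma: float = 1.0
    sigma_noise: float = 0.41
    rho_emotion: float = 0.3
    n_voxels: int = 400
    n_subjects: int = 20
    n_runs: int = 4
    roi_names: Sequence[str] = DEFAULT_ROIS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"scenario must be one of {SCENARIOS}; got {self.scenario!r}"
            )
        missing = [e for e in EMOTIONS if e not in self.alpha_true]
        if missing:
            raise ConfigurationError(f"alpha_true missing emotions: {missing}")
        for emo, a in self.alpha_true.items():
            _check_unit_interval(f"alpha_true[{emo!r}]", float(a))
        _check_unit_interval("gamma", self.gamma)
        _check_unit_interval("rho_emotion", self.rho_emotion, open_right=True)
        if not (self.sigma_noise >= 0 and math.isfinite(self.sigma_noise)):
            raise ConfigurationError(f"sigma_noise must be >= 0; got {self.sigma_noise!r}")
        if self.n_voxels < 2:
            raise ConfigurationError(f"n_voxels must be >= 2; got {self.n_voxels}")
        for name in ("n_subjects", "n_runs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1; got {getattr(self, name)}")
        if not self.roi_names:
            raise ConfigurationError("roi_names must be non-empty")
        if len(set(self.roi_names)) != len(tuple(self.roi_names)):
            raise ConfigurationError("roi_names must be unique")

    @property
    def effective_gamma(self) -> float:
        """gamma actually used by the generator (part_based pins it to 1)."""
        return 1.0 if self.scenario == "part_based" else self.gamma

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alpha_true"] = dict(self.alpha_true)
        d["roi_names"] = list(self.roi_names)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "roi_names" in d:
            d["roi_names"] = tuple(d["roi_names"])
        return cls(**d)


@dataclass(frozen=True)
class DesignSpec:
    """Block/trial timing of one run.

    The run timeline is: an initial equilibration period of
    ``n_discard * tr_s`` seconds (its volumes are the ones discarded before
    analysis), then for each block ``trials_per_block * (trial + ISI)``
    seconds of stimulation followed by a ``response_window_s`` response
    period, with ``fixation_s`` of fixation between adjacent blocks.
    """

    n_blocks: int = 18
    trials_per_block: int = 8
    trial_duration_s: float = 2.0
    isi_s: float = 0.5
    response_window_s: float = 2.0
    fixation_s: float = 10.0
    tr_s: float = 2.0
    n_discard: int = 5
    condition_order: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        for name in (
            "trial_duration_s",
            "tr_s",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0; got {getattr(self, name)}")
        for name in ("isi_s", "response_window_s", "fixation_s"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0; got {getattr(self, name)}")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("n_blocks and trials_per_block must be >= 1")
        if self.n_discard < 0:
            raise ConfigurationError(f"n_discard must be >= 0; got {self.n_discard}")
        if self.condition_order is not None and len(self.condition_order) != self.n_blocks:
            raise ConfigurationError(
                f"condition_order has {len(self.condition_order)} entries "
                f"for {self.n_blocks} blocks"
            )
        total = self.total_duration_s
        n_vol = total / self.tr_s
        if abs(n_vol - round(n_vol)) > 1e-9:
            raise ConfigurationError(
                f"total run duration {total} s is not divisible by TR {self.tr_s} s"
            )

    @property
    def block_duration_s(self) -> float:
        """Stimulation duration of one block (trials + ISIs)."""
        return self.trials_per_block * (self.trial_duration_s + self.isi_s)

    @property
    def total_duration_s(self) -> float:
        return (
            self.n_discard * self.tr_s
            + self.n_blocks * (self.block_duration_s + self.response_window_s)
            + (self.n_blocks - 1) * self.fixation_s
        )

    @property
    def n_volumes(self) -> int:
        """Acquired volumes per run, before discarding."""
        return round(self.total_duration_s / self.tr_s)

    @property
    def n_retained(self) -> int:
        """Volumes kept for analysis after discarding the equilibration ones."""
        return self.n_volumes - self.n_discard

    def block_onsets_s(self) -> list[float]:
        """Stimulation onset of every block on the acquired (full) timeline."""
        cycle = self.block_duration_s + self.response_window_s + self.fixation_s
        start = self.n_discard * self.tr_s
        return [start + b * cycle for b in range(self.n_blocks)]

    def with_order(self, order: Sequence[tuple[str, str]]) -> "DesignSpec":
        return dataclasses.replace(self, condition_order=tuple(tuple(c) for c in order))

    def shifted(self, n_removed: int) -> "DesignSpec":
        """Design after removing ``n_removed`` initial volumes from bookkeeping."""
        return dataclasses.replace(self, n_discard=self.n_discard - n_removed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.condition_order is not None:
            d["condition_order"] = [list(c) for c in self.condition_order]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpec":
        d = dict(d)
        if d.get("condition_order") is not None:
            d["condition_order"] = tuple(tuple(c) for c in d["condition_order"])
        return cls(**d)


def balanced_condition_order(
    conditions: Sequence[tuple[str, str]], n_blocks: int, rng
) -> tuple[tuple[str, str], ...]:
    """Pseudo-random block order with each condition appearing equally often."""
    if n_blocks % len(conditions) != 0:
        raise ConfigurationError(
            f"{n_blocks} blocks cannot be balanced over {len(conditions)} conditions"
        )
    reps = n_blocks // len(conditions)
    order = [tuple(c) for c in conditions for _ in range(reps)]
    perm = rng.permutation(len(order))
    return tuple(order[i] for i in perm)


def config_hash(obj: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    import hashlib

    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
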