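#!/usr/bin/env python
"""Forward-model time series for the part-based cohort and recover patterns.

Runs both MVPA procedures on simulated block-design runs (288 acquired
volumes, first 5 discarded): GLM beta patterns per run for the similarity
and weight analyses, and condition-labelled z-scored stimulus volumes
(20 per condition per run) for classification.  The raw series are not
persisted; they are regenerated deterministically from the saved patterns.

Writes results/data/betas/ and results/data/volumes/.
"""

from pathlib import Path

from partwhole.config import DesignSpec
from partwhole.glm import estimate_betas, extract_condition_volumes
from partwhole.io import load_patterns, save_patterns, save_volume_set
from partwhole.simulate import generate_timeseries

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
TS_NOISE_SD = 0.5
TS_SEED = 21


def main() -> None:
    patterns = load_patterns(DATA / "patterns_part_based")
    design = DesignSpec()
    ts = generate_timeseries(patterns, design, noise_sd=TS_NOISE_SD, seed=TS_SEED)
    print(f"time series: {len(ts.volumes)} run x ROI matrices, "
          f"{design.n_volumes} volumes acquired, {design.n_retained} retained")

    betas = estimate_betas(ts)
    save_patterns(betas, DATA / "betas")
    print(f"betas: {len(betas.patterns)} per-run condition patterns -> {DATA/'betas'}")

    vols = extract_condition_volumes(ts)
    n20 = vols.get(0, 0, betas.roi_names[0], "face", "anger").shape[0]
    save_volume_set(vols, DATA / "volumes")
    print(f"volumes: {n20} stimulus volumes per condition per run -> {DATA/'volumes'}")


if __name__ == "__main__":
    main()
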