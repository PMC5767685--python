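# partwhole

Are whole-person multi-voxel response patterns part-based linear combinations
of face and body patterns — and does emotion change the mix?

`partwhole` implements, end to end, the MVPA procedure for answering that
question in region-of-interest fMRI data: pattern-similarity analysis with
synthetic mean patterns, convex weight estimation by grid search, and
emotion decoding with classifiers trained on synthesized patterns.  Because
no public dataset exists for this paradigm, the package ships a first-class
synthetic-data generator that draws cohorts under the two competing
hypotheses — **part-based** (whole-person responses arise only from face-
and body-selective populations) and **integrated** (an additional
person-only population contributes) — so every stage is testable and the
whole analysis is reproducible from a seed.

## The model

For each emotion *e* (happiness, anger, fear), a region's face pattern
**f**ₑ and body pattern **b**ₑ are combined with total weight 1:

    w(α) = α · f_e + (1 − α) · b_e ,   α ∈ [0, 1]

* **Synthetic mean pattern**: w(0.5), the equal-weight part-based model of
  the whole-person pattern.
* **Pattern similarity**: Pearson correlations between face, body, person,
  and synthetic-mean patterns are computed across run pairs (pattern from
  run *i* against pattern from run *j* ≠ *i*, all 3 run pairs, both
  directions), Fisher-z transformed (z = atanh r), and assembled into a
  4×4 representational similarity matrix per subject, ROI, and emotion.
  2 (Category) × 3 (Emotion) repeated-measures ANOVAs contrast the
  person–synthetic correlation with person–face and person–body.
* **Weight analysis**: α is swept over 0.00–1.00 in 0.01 steps; the optimal
  α̂ maximises the correlation of w(α) with the run-averaged person pattern.
  Group tests run on body weights β̂ = 1 − α̂ (one-sample t vs 0.5 per
  emotion; 3 × 4 Emotion × ROI repeated-measures ANOVA).
* **Classification**: linear SVMs (C = 1, one-vs-one) decode the three
  emotions from run-4 whole-person volumes after training on z-scored
  stimulus volumes of runs 1–3 (20 volumes per condition per run) in four
  flavours — face, body, synthetic mean, and synthetic weighted mean at α̂ —
  with per-ROI ANOVA feature selection (p < 0.05, training runs only),
  group tests against the 33.33 % chance level, and Benjamini–Hochberg FDR
  across all ROI × training-type comparisons.
* **Stimulus statistics**: per-clip movement (mean supra-threshold
  inter-frame luminance change, threshold 10 on the 0–255 scale), RMS
  contrast (per-frame population SD of luminance, averaged over frames),
  and mean luminance, with paired group comparisons between emotions.

The generator's whole-person template is
p*ₑ* = γ(αₑ fₑ + (1−αₑ) bₑ) + (1−γ) uₑ with an independent person-only
component uₑ; γ = 1 is the part-based scenario.  The block design mirrors a
standard slow emotion-judgement protocol: 4 runs, 18 blocks of 8 trials
(2 s video + 0.5 s ISI), 2 s response window, 10 s inter-block fixation,
TR 2 s — 288 acquired volumes per run of which the first 5 are discarded
(283 retained), and exactly 20 stimulus volumes per condition per run.

## Worked example

The numbered scripts under `analysis/` run the full study on a 20-subject
part-based cohort (4 ROIs, 300 voxels each, pattern noise calibrated to a
person–synthetic correlation of ≈ 0.8, face weight 0.65 for happiness and
0.50 for anger/fear):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_estimate_patterns.py
python analysis/03_pattern_similarity.py
python analysis/04_weight_analysis.py
python analysis/05_classification.py
python analysis/06_stimulus_statistics.py
```

Script 04 prints, for the EBA-labelled region:

```
mean recovered face weight alpha by ROI x emotion:
emotion  anger   fear  happiness
EBA      0.497  0.493      0.653

EBA body weight vs 0.5 (one-sample t):
             mean        t       p
anger      0.5030   1.5519  0.1372
fear       0.5065   2.5573  0.0193
happiness  0.3470 -60.6283  0.0000
```

The grid search recovers the generating weights through the full
time-series → GLM → optimisation path: happy expressions need more face
than body information (body weight 0.347, significantly below 0.5), while
the threat emotions sit at equal weights.  Script 03 reports the
person–synthetic Fisher z at 1.08 (r ≈ 0.79) under part-based generation
versus 0.48 under the integrated scenario — the similarity signature that
separates the two hypotheses — and script 05 shows mean/weighted-mean
trained classifiers (0.83/0.85) beating face- or body-only training
(0.64/0.59) at decoding whole-person emotions.

A `partwhole` console script exposes the same stages
(`partwhole simulate|estimate|similarity|weights|classify|run|report|stimstats`);
`partwhole run --out report/` executes both MVPA branches from one JSON
config with a single fan-out seed.

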