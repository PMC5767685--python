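"""Canonical double-gamma hemodynamic response and block regressor construction.

The canonical response is the SPM-style double gamma: a response gamma
peaking at 6 s minus an undershoot gamma peaking at 16 s scaled by 1/6,
normalised to unit peak.  Regressors are built by convolving a block
boxcar sampled on a fine grid (dt = 0.1 s) with the response, then reading
the result at volume acquisition times.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

PEAK_DELAY_S = 6.0
UNDERSHOOT_DELAY_S = 16.0
UNDERSHOOT_RATIO = 6.0
DISPERSION_S = 1.0
HRF_LENGTH_S = 32.0
DT = 0.1


def double_gamma_hrf(dt: float = DT, duration_s: float = HRF_LENGTH_S) -> np.ndarray:
    """Sampled canonical response, unit peak."""
    t = np.arange(0, duration_s, dt)
    peak = gamma_dist.pdf(t, PEAK_DELAY_S / DISPERSION_S, scale=DISPERSION_S)
    under = gamma_dist.pdf(t, UNDERSHOOT_DELAY_S / DISPERSION_S, scale=DISPERSION_S)
    h = peak - under / UNDERSHOOT_RATIO
    return h / h.max()


def convolve_blocks(
    onsets_s: np.ndarray,
    duration_s: float,
    total_duration_s: float,
    tr_s: float,
    dt: float = DT,
) -> np.ndarray:
    """Convolved boxcar regressor sampled at volume onsets 0, TR, 2·TR, ...

    ``onsets_s`` are the block stimulation onsets of one condition on the
    same timeline as the returned samples.
    """
    n_fine = int(round(total_duration_s / dt))
    box = np.zeros(n_fine)
    grid = np.arange(n_fine) * dt
    for onset in np.atleast_1d(onsets_s):
        box[(grid >= onset) & (grid < onset + duration_s)] = 1.0
    sig = np.convolve(box, double_gamma_hrf(dt))[:n_fine]
    n_vol = int(round(total_duration_s / tr_s))
    idx = np.round(np.arange(n_vol) * tr_s / dt).astype(int)
    return sig[idx]
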