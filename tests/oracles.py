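"""Independent brute-force references used by the test suite only.

These deliberately avoid the package's measurement code paths: the bar
response is a closed-form sum of error-function edge profiles evaluated on a
dense grid, and the dense gamma is an exhaustive search on a 0.01 mm grid.
"""

import numpy as np
from scipy.special import ndtr  # standard normal CDF


def square_wave_response(width_mm: float, sigma_mm: float,
                         n_periods: int = 4, hi: float = 1.0,
                         lo: float = 0.5) -> float:
    """Square-wave contrast response of a Gaussian PSF, by direct convolution.

    The pattern has bars (level ``lo``) of width w in the first half of each
    period, background ``hi`` elsewhere; its convolution with a Gaussian is a
    sum of erf steps.  Returns blurred contrast / ideal contrast, both as
    (max-min)/(max+min), read off the two interior periods on a dense grid.
    """
    if sigma_mm == 0:
        return 1.0
    start = -width_mm * n_periods

    def blurred(x):
        bar_sum = np.zeros_like(x)
        for k in range(n_periods):
            a = start + 2 * k * width_mm
            bar_sum += ndtr((x - a) / sigma_mm) - ndtr((x - a - width_mm) / sigma_mm)
        return hi - (hi - lo) * bar_sum

    # read max/min per interior period and average, as a bar-pattern contrast
    # measurement on a finite pattern does (pattern-end bleed is part of the
    # signal at high frequency x blur)
    peaks, troughs = [], []
    for k in (1, n_periods - 2):
        x = np.arange(start + 2 * k * width_mm, start + 2 * (k + 1) * width_mm,
                      width_mm / 500.0)
        t = blurred(x)
        peaks.append(t.max())
        troughs.append(t.min())
    hi_m, lo_m = np.mean(peaks), np.mean(troughs)
    k_blur = (hi_m - lo_m) / (hi_m + lo_m)
    k_ideal = (hi - lo) / (hi + lo)
    return float(k_blur / k_ideal)


def dense_gamma_max(ref_x, ref_d, ev_x, ev_d, dose_tol_percent, dta_mm,
                    grid_mm: float = 0.01) -> float:
    """Max gamma with the evaluated curve resampled to a near-continuous grid."""
    grid = np.arange(ev_x[0], ev_x[-1] + grid_mm / 2, grid_mm)
    de = np.interp(grid, ev_x, ev_d)
    delta_d = dose_tol_percent / 100.0 * float(np.max(ref_d))
    worst = 0.0
    for xr, dr in zip(ref_x, ref_d):
        m = np.abs(grid - xr) <= 3 * dta_mm
        g2 = ((grid[m] - xr) / dta_mm) ** 2 + ((de[m] - dr) / delta_d) ** 2
        worst = max(worst, float(np.sqrt(g2.min())))
    return worst
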