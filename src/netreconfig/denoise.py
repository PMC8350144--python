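"""Parcellated-signal denoising: confound regression, bandpass, detrend, despike.

The chain mirrors standard connectivity preprocessing of extracted ROI
time series: nuisance regression (CompCor components + 24 motion-derived
regressors), 0.008-0.09 Hz bandpass, linear detrend, and a hyperbolic-tangent
"squashing" despike.  Global signal regression is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import gamma as gamma_dist

from .core import RoiTimeSeries, logger


@dataclass
class DenoiseConfig:
    """Band edges in Hz; despike scale in robust-SD units."""

    band_low: float = 0.008
    band_high: float = 0.09
    despike_scale_multiplier: float = 3.0
    detrend: bool = True
    apply_bandpass: bool = True
    apply_despike: bool = True

    def validate(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if not (0.0 < self.band_low < self.band_high < nyquist):
            raise ValueError(
                f"band ({self.band_low}, {self.band_high}) Hz invalid for "
                f"tr={tr}s (Nyquist {nyquist:.4f} Hz)"
            )


@dataclass
class HrfConfig:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length: float = 32.0


def motion_expansion(params: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-motion traces to the 24-regressor set.

    Columns: the 6 parameters, their backward-difference derivatives
    (first row zero), and the squares of both.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must have exactly 6 columns")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(params, axis=0)])
    return np.hstack([params, deriv, params**2, deriv**2])


def regress_confounds(
    ts: RoiTimeSeries, regressors: np.ndarray, add_intercept: bool = True
) -> RoiTimeSeries:
    """Remove nuisance regressors from every node by least squares.

    Residuals are orthogonal to every regressor column. Rank-deficient
    designs are handled by a minimum-norm solve (equivalent to dropping
    the dependent columns) with a logged warning.
    """
    R = np.asarray(regressors, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    if R.shape[0] != ts.n_volumes:
        raise ValueError("regressor rows must match number of volumes")
    design = np.hstack([np.ones((R.shape[0], 1)), R]) if add_intercept else R
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "confound design is rank deficient (%d < %d); dependent columns "
            "carry no unique variance and are effectively dropped",
            rank,
            design.shape[1],
        )
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return ts.with_data(ts.data - design @ beta)


def bandpass(ts: RoiTimeSeries, config: DenoiseConfig | None = None) -> RoiTimeSeries:
    """Zero-phase 4th-order Butterworth bandpass, applied per node."""
    config = config or DenoiseConfig()
    config.validate(ts.tr)
    fs = 1.0 / ts.tr
    sos = sps.butter(
        4, [config.band_low, config.band_high], btype="bandpass", fs=fs, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, ts.data, axis=0)
    return ts.with_data(filtered)


def despike_tanh(ts: RoiTimeSeries, multiplier: float = 3.0) -> RoiTimeSeries:
    """Squash deviations from the column median through a scaled tanh.

    Scale s = multiplier * 1.4826 * MAD; output = median + s*tanh((x-med)/s),
    so every value is bounded within median +/- s.  Zero-variance columns are
    returned unchanged.
    """
    if not multiplier > 0:
        raise ValueError("multiplier must be positive")
    X = ts.data
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    s = multiplier * 1.4826 * mad
    out = X.copy()
    ok = s > 0
    if not ok.all():
        logger.warning("despike: %d zero-variance columns left unchanged", (~ok).sum())
    out[:, ok] = med[ok] + s[ok] * np.tanh((X[:, ok] - med[ok]) / s[ok])
    return ts.with_data(out)


def linear_detrend(ts: RoiTimeSeries) -> RoiTimeSeries:
    return ts.with_data(sps.detrend(ts.data, axis=0, type="linear"))


def hrf_kernel(hrf: HrfConfig | None = None, dt: float = 0.1) -> np.ndarray:
    """Canonical double-gamma HRF sampled at resolution dt seconds."""
    hrf = hrf or HrfConfig()
    t = np.arange(0.0, hrf.length + dt / 2, dt)
    peak = gamma_dist.pdf(t, hrf.peak_delay / hrf.peak_dispersion, scale=hrf.peak_dispersion)
    under = gamma_dist.pdf(
        t, hrf.undershoot_delay / hrf.undershoot_dispersion, scale=hrf.undershoot_dispersion
    )
    h = peak - under / hrf.ratio
    if h.sum() <= 0:
        raise ValueError("HRF kernel must integrate to a positive value")
    return h


def hrf_task_regressors(
    onsets: np.ndarray,
    durations: np.ndarray,
    tr: float,
    n_volumes: int,
    hrf: HrfConfig | None = None,
) -> np.ndarray:
    """Boxcar design convolved with the HRF, plus its temporal derivative.

    Returns a (n_volumes, 2) matrix: [convolved regressor, backward-difference
    derivative] sampled at volume acquisition times k*tr.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if onsets.size != durations.size:
        raise ValueError("onsets and durations must have equal length")
    scan_end = n_volumes * tr
    if onsets.size and (onsets.min() < 0 or onsets.max() > scan_end):
        raise ValueError("onset outside scan")
    if onsets.size and (durations < 0).any():
        raise ValueError("durations must be non-negative")
    dt = 0.1
    hrf = hrf or HrfConfig()
    n_fine = int(np.ceil((scan_end + hrf.length) / dt)) + 1
    boxcar = np.zeros(n_fine)
    tfine = np.arange(n_fine) * dt
    for on, dur in zip(onsets, durations):
        boxcar[(tfine >= on) & (tfine < on + max(dur, dt))] = 1.0
    conv = np.convolve(boxcar, hrf_kernel(hrf, dt))[:n_fine] * dt
    vol_idx = np.clip(np.round(np.arange(n_volumes) * tr / dt).astype(int), 0, n_fine - 1)
    col = conv[vol_idx]
    deriv = np.diff(col, prepend=0.0) / tr
    return np.column_stack([col, deriv])


def denoise_pipeline(
    ts: RoiTimeSeries,
    regressors: np.ndarray | None,
    config: DenoiseConfig | None = None,
) -> RoiTimeSeries:
    """Confound regression -> bandpass -> linear detrend -> tanh despike."""
    config = config or DenoiseConfig()
    out = ts
    if regressors is not None:
        out = regress_confounds(out, regressors)
    if config.apply_bandpass:
        out = bandpass(out, config)
    if config.detrend:
        out = linear_detrend(out)
    if config.apply_despike:
        out = despike_tanh(out, config.despike_scale_multiplier)
    return out
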