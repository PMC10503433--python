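"""Bipolar-electrogram metrics and the source-activity comparison statistics.

Dominant frequency (DF) is the maximal Welch-spectrum peak inside a
physiological band (default 3-15 Hz); f-wave amplitude is a robust
peak-to-peak statistic of the atrial deflections outside ventricular
blanking windows.  Both are computed per overlapping 4-s window (2-s step),
matching the segmentation that pairs them with per-window source activity
(SAC), and compared with ordinary least squares (r^2 and the F-test of the
slope) and Welch two-sample t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

__all__ = [
    "SpectralConfig",
    "SpectralWindowMetrics",
    "RegressionResult",
    "window_segments",
    "dominant_frequency",
    "f_wave_amplitude",
    "ols_fit",
    "two_sample_t",
    "sac_vs_local_metrics",
]


@dataclass(frozen=True)
class SpectralConfig:
    window_s: float = 4.0
    step_s: float = 2.0
    df_band_hz: tuple[float, float] = (3.0, 15.0)
    welch_subwindow_s: float = 2.0
    nfft_factor: int = 8            # zero-padding factor for peak localization
    amplitude_chunk_s: float = 0.5  # f-wave peak-to-peak chunk length
    qrst_window_s: tuple[float, float] = (-0.05, 0.25)
    min_peak_prominence_frac: float = 0.05  # of total band power; else low confidence


@dataclass
class SpectralWindowMetrics:
    window_start_s: float
    dominant_frequency_hz: float | None
    f_wave_amplitude_mv: float
    df_low_confidence: bool = False
    paired_sac_pct: float | None = None


@dataclass
class RegressionResult:
    """OLS line of best fit with the F-test of the slope."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def window_segments(
    duration: float, window: float = 4.0, step: float = 2.0
) -> list[float]:
    """Start times of overlapping analysis windows: 0, step, 2*step, ...

    A 60-s recording with 4-s windows at a 2-s step yields 29 windows.
    """
    if duration < window:
        raise ValueError(f"duration {duration} s shorter than the {window}-s window")
    if window < step:
        warnings.warn("window shorter than step leaves unanalysed gaps", stacklevel=2)
    starts = []
    t = 0.0
    while t + window <= duration + 1e-9:
        starts.append(round(t, 9))
        t += step
    return starts


def dominant_frequency(
    signal: np.ndarray,
    rate: float,
    band: tuple[float, float] | None = None,
    config: SpectralConfig | None = None,
) -> tuple[float | None, bool]:
    """Welch-spectrum dominant frequency within the band.

    Returns (frequency_hz, low_confidence).  All-zero input has no defined DF
    and returns (None, True).
    """
    config = config or SpectralConfig()
    band = band or config.df_band_hz
    signal = np.asarray(signal, dtype=float)
    if band[1] >= rate / 2:
        raise ValueError("band must lie below the Nyquist frequency")
    if not np.any(signal):
        return None, True
    nperseg = min(int(config.welch_subwindow_s * rate), signal.size)
    f, p = sps.welch(
        signal,
        fs=rate,
        nperseg=nperseg,
        noverlap=nperseg // 2,
        nfft=config.nfft_factor * nperseg,
        detrend="constant",
    )
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel):
        return None, True
    fb, pb = f[sel], p[sel]
    k = int(np.argmax(pb))
    # peak prominence relative to total band power flags noise-like spectra
    low_conf = pb[k] < config.min_peak_prominence_frac * pb.sum()
    return float(fb[k]), bool(low_conf)


def _blanking_mask(
    n: int, rate: float, ventricular_times, qrst_window_s: tuple[float, float]
) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    if ventricular_times is None:
        return mask
    for tv in np.asarray(ventricular_times, dtype=float):
        a = max(int((tv + qrst_window_s[0]) * rate), 0)
        b = min(int((tv + qrst_window_s[1]) * rate), n)
        mask[a:b] = True
    return mask


def f_wave_amplitude(
    signal: np.ndarray,
    rate: float,
    ventricular_times=None,
    config: SpectralConfig | None = None,
) -> float:
    """Median peak-to-peak amplitude of atrial deflections, in mV.

    The signal (outside ventricular blanking windows) is cut into short
    chunks (default 0.5 s) and the median of the per-chunk max-min spans is
    returned; for a pure sinusoid of amplitude a this is 2a.
    """
    config = config or SpectralConfig()
    signal = np.asarray(signal, dtype=float)
    mask = _blanking_mask(signal.size, rate, ventricular_times, config.qrst_window_s)
    atrial = signal[~mask]
    chunk = max(int(config.amplitude_chunk_s * rate), 2)
    if atrial.size < 2:
        warnings.warn("no atrial samples outside blanking; amplitude 0", stacklevel=2)
        return 0.0
    n = (atrial.size // chunk) * chunk
    spans = (
        np.ptp(atrial[:n].reshape(-1, chunk), axis=1)
        if n
        else np.array([np.ptp(atrial)])
    )
    amp = float(np.median(spans))
    if amp == 0.0:
        warnings.warn("no detectable atrial deflections; amplitude 0", stacklevel=2)
    return amp


def ols_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least-squares line of best fit, r^2, and slope F-test p-value."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("OLS needs paired samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance; slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
        n=int(x.size),
    )


def two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed two-sample t-test (Welch, unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def sac_vs_local_metrics(
    summary,
    bipolar: np.ndarray,
    rate: float,
    source=None,
    ventricular_times=None,
    config: SpectralConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, RegressionResult]]:
    """Pair per-window SAC with DF and f-wave amplitude; regress SAC on each.

    ``summary`` is a flow SummaryMap time-aligned with the bipolar trace; the
    highest-activity source is used unless one is given.  Windows are 4 s with
    a 2-s step, so each covers two 2-s segments whose activities are averaged.
    """
    config = config or SpectralConfig()
    seg_s = 2.0
    sources = summary.all_sources if source is None else [source]
    if not sources:
        raise ValueError("summary map contains no tracked sources")
    src = sources[0]
    activity = src.per_segment_activity
    map_duration = len(summary.segment_maps) * seg_s
    bip_duration = bipolar.size / rate
    duration = min(map_duration, bip_duration)
    if abs(map_duration - bip_duration) > seg_s:
        warnings.warn(
            f"recordings differ in length ({map_duration:.0f} vs {bip_duration:.0f} s); "
            "trimmed to overlap",
            stacklevel=2,
        )
    rows = []
    for t0 in window_segments(duration, config.window_s, config.step_s):
        seg0 = int(t0 // seg_s)
        segs = [s for s in (seg0, seg0 + 1) if s < len(activity)]
        sac = float(np.mean([activity[s] for s in segs]))
        a, b = int(t0 * rate), int((t0 + config.window_s) * rate)
        vt = None
        if ventricular_times is not None:
            vt = np.asarray(ventricular_times) - t0
            vt = vt[(vt > -1) & (vt < config.window_s + 1)]
        df, low_conf = dominant_frequency(bipolar[a:b], rate, config=config)
        amp = f_wave_amplitude(bipolar[a:b], rate, ventricular_times=vt, config=config)
        rows.append(
            SpectralWindowMetrics(
                window_start_s=t0,
                dominant_frequency_hz=df,
                f_wave_amplitude_mv=amp,
                df_low_confidence=low_conf,
                paired_sac_pct=sac,
            )
        )
    table = pd.DataFrame(
        dict(
            window_start_s=[m.window_start_s for m in rows],
            SAC_pct=[m.paired_sac_pct for m in rows],
            DF_hz=[m.dominant_frequency_hz for m in rows],
            fwave_mv=[m.f_wave_amplitude_mv for m in rows],
            DF_low_confidence=[m.df_low_confidence for m in rows],
        )
    )
    fits: dict[str, RegressionResult] = {}
    valid = table.dropna(subset=["DF_hz"])
    for metric in ("DF_hz", "fwave_mv"):
        x = valid["SAC_pct"].to_numpy()
        if len(valid) >= 3 and np.ptp(x) > 0:
            fits[metric] = ols_fit(x, valid[metric].to_numpy())
    return table, fits
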