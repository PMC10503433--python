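"""Raw unipolar signals -> per-frame intensity images; electrode contact scoring.

The electrode voltages are turned into an "optical intensity" (band-passed,
rectified, smoothed activation energy), averaged within consecutive 19-ms
frames, min-max normalized per channel over the whole recording, and spatially
interpolated from the 8x8 electrode grid to a dense pixel grid with a
biharmonic (thin-plate-spline-type) Green's-function interpolant that wraps on
the circumferential spline axis.

Pixel-grid convention: ``pixels_per_span`` pixels per inter-electrode spacing
(default 4), giving a periodic 32-row spline axis and an open 29-column
electrode axis.  Electrode (r, c) sits at pixel (4r, 4c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .geometry import BasketGeometry
from .recording import EGMRecording

__all__ = [
    "PreprocessConfig",
    "FrameStack",
    "ContactReport",
    "PixelGrid",
    "greens_interpolate",
    "voltage_to_intensity",
    "near_field_score",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Intensity-map construction parameters."""

    pixels_per_span: int = 4            # pixels per inter-electrode spacing
    band_pass_hz: tuple[float, float] = (30.0, 300.0)
    smooth_ms: float = 10.0             # rectified-intensity smoothing window
    frame_ms: float = 19.0
    segment_s: float = 2.0
    blank_qrst: bool = False            # optionally zero intensity in QRST windows
    qrst_window_s: tuple[float, float] = (-0.05, 0.25)  # around each QRS onset

    @property
    def frames_per_segment(self) -> int:
        return int(self.segment_s * 1000.0 // self.frame_ms)


@dataclass(frozen=True)
class PixelGrid:
    """Dense interpolation grid tied to a basket geometry.

    ``n_rows`` is periodic (spline axis), ``n_cols`` open (electrode axis).
    """

    geometry: BasketGeometry
    pixels_per_span: int = 4

    @property
    def n_rows(self) -> int:
        return self.geometry.n_splines * self.pixels_per_span  # periodic

    @property
    def n_cols(self) -> int:
        return (self.geometry.n_electrodes_per_spline - 1) * self.pixels_per_span + 1

    @property
    def row_period(self) -> float:
        return float(self.geometry.n_splines)  # grid units

    def pixel_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) grid-unit coordinates of every pixel."""
        r = np.arange(self.n_rows) / self.pixels_per_span
        c = np.arange(self.n_cols) / self.pixels_per_span
        return np.meshgrid(r, c, indexing="ij")

    def electrode_pixel(self, row: int, col: int) -> tuple[int, int]:
        return (row * self.pixels_per_span, col * self.pixels_per_span)

    def pixel_to_grid_units(self, pr: float, pc: float) -> tuple[float, float]:
        return (pr / self.pixels_per_span, pc / self.pixels_per_span)


@dataclass
class FrameStack:
    """Sequence of 2-D intensity images, one per frame."""

    frames: np.ndarray            # (n_frames, n_rows, n_cols), values in [0,1]
    frame_ms: float
    grid: PixelGrid
    segment_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ContactReport:
    """Per-channel near-field score and low-contact flags (score < 0.7)."""

    near_field_score: dict[str, float]
    low_contact_flags: set[str]

    LOW_CONTACT_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# biharmonic Green's-function interpolation


def _biharmonic_kernel(r: np.ndarray) -> np.ndarray:
    """g(r) = r^2 (ln r - 1), with the removable singularity g(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * (np.log(r[nz]) - 1.0)
    return out


def _wrapped_sq_dist(
    ra: np.ndarray, ca: np.ndarray, rb: np.ndarray, cb: np.ndarray, period: float
) -> np.ndarray:
    dr = np.abs(ra[:, None] - rb[None, :])
    dr = np.minimum(dr, period - dr)
    dc = ca[:, None] - cb[None, :]
    return dr**2 + dc**2


class GreensInterpolator:
    """Precomputed linear operator: 64 electrode values -> dense pixel image.

    Solves the biharmonic radial-basis system with a constant term and a
    sum-to-zero weight constraint, using circular row distances so the
    interpolant is exactly periodic on the spline axis.  The operator is a
    single (n_pixels, 64) matrix, so per-frame interpolation is one matmul.
    """

    def __init__(self, grid: PixelGrid):
        self.grid = grid
        g = grid.geometry
        er = np.repeat(np.arange(g.n_splines, dtype=float), g.n_electrodes_per_spline)
        ec = np.tile(np.arange(g.n_electrodes_per_spline, dtype=float), g.n_splines)
        n = er.size
        period = grid.row_period
        K = _biharmonic_kernel(np.sqrt(_wrapped_sq_dist(er, ec, er, ec, period)))
        # bordered system [[K, 1], [1^T, 0]] for exact reproduction of constants
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = K
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        pr, pc = grid.pixel_positions()
        E = _biharmonic_kernel(
            np.sqrt(_wrapped_sq_dist(pr.ravel(), pc.ravel(), er, ec, period))
        )
        Efull = np.hstack([E, np.ones((E.shape[0], 1))])
        # operator = Efull @ A^{-1} restricted to the value rows
        self._op = np.linalg.solve(A.T, Efull.T).T[:, :n]
        self._shape = (grid.n_rows, grid.n_cols)

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """Interpolate one 8x8 field (or a stack (..., 8, 8)) to pixel images."""
        values = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("interpolation input must be finite")
        flat = values.reshape(*values.shape[:-2], 64)
        out = flat @ self._op.T
        return out.reshape(*values.shape[:-2], *self._shape)


_INTERP_CACHE: dict[tuple, GreensInterpolator] = {}


def _interpolator(grid: PixelGrid) -> GreensInterpolator:
    key = (grid.geometry.n_splines, grid.geometry.n_electrodes_per_spline, grid.pixels_per_span)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = GreensInterpolator(grid)
    return _INTERP_CACHE[key]


def greens_interpolate(
    values: np.ndarray,
    geometry: BasketGeometry | None = None,
    pixels_per_span: int = 4,
) -> np.ndarray:
    """Interpolate an 8x8 scalar field to the dense pixel grid.

    Reproduces the input values exactly at electrode pixels, reproduces
    constants exactly, and is linear in its inputs.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-2:] != (8, 8):
        raise ValueError("expected an (..., 8, 8) electrode field")
    if np.ptp(values) == 0:  # degenerate all-equal field: constant shortcut
        grid = PixelGrid(geometry or BasketGeometry(), pixels_per_span)
        return np.full(
            (*values.shape[:-2], grid.n_rows, grid.n_cols), values.flat[0], dtype=float
        )
    grid = PixelGrid(geometry or BasketGeometry(), pixels_per_span)
    return _interpolator(grid)(values)


# ---------------------------------------------------------------------------
# voltage -> intensity frames


def _intensity_traces(recording: EGMRecording, config: PreprocessConfig) -> np.ndarray:
    """Band-pass, rectify, smooth and per-channel min-max normalize all channels."""
    fs = recording.sampling_rate
    lo, hi = config.band_pass_hz
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = recording.signals
    if not np.all(np.isfinite(x)):
        raise ValueError("recording contains non-finite samples")
    y = np.abs(sps.sosfiltfilt(sos, x, axis=1))
    win = max(int(round(config.smooth_ms * fs / 1000.0)), 1)
    kernel = np.ones(win) / win
    y = sps.fftconvolve(y, kernel[None, :], mode="same", axes=1)
    if config.blank_qrst and recording.ventricular_times is not None:
        t = np.arange(y.shape[1]) / fs
        mask = np.zeros(y.shape[1], dtype=bool)
        for tv in recording.ventricular_times:
            a, b = tv + config.qrst_window_s[0], tv + config.qrst_window_s[1]
            mask |= (t >= a) & (t < b)
        y[:, mask] = 0.0
    lo_v = y.min(axis=1, keepdims=True)
    rng_v = np.ptp(y, axis=1, keepdims=True)
    rng_v[rng_v == 0] = 1.0  # degenerate flat channel stays at zero
    return (y - lo_v) / rng_v


def voltage_to_intensity(
    recording: EGMRecording,
    segment_start: float = 0.0,
    config: PreprocessConfig | None = None,
    _traces: np.ndarray | None = None,
) -> FrameStack:
    """Build the FrameStack for one 2-s segment beginning at ``segment_start``.

    A 2-s segment yields exactly 105 frames of 19 ms.  ``_traces`` lets the
    pipeline reuse the (whole-recording) normalized intensity traces across
    segments; normalization is always over the full recording either way.
    """
    config = config or PreprocessConfig()
    fs = recording.sampling_rate
    if segment_start < 0 or segment_start + config.segment_s > recording.duration + 1e-9:
        raise ValueError(
            f"segment [{segment_start}, {segment_start + config.segment_s}] s exceeds "
            f"the {recording.duration:.2f}-s recording"
        )
    traces = _traces if _traces is not None else _intensity_traces(recording, config)
    n_frames = config.frames_per_segment
    spf = config.frame_ms * fs / 1000.0  # samples per frame (may be fractional)
    start = int(round(segment_start * fs))
    grid8 = np.empty((n_frames, 8, 8))
    order = np.empty((8, 8), dtype=int)
    from .geometry import label_to_grid

    for i, lab in enumerate(recording.channel_labels):
        loc = label_to_grid(lab)
        order[loc.row, loc.col] = i
    for k in range(n_frames):
        a = start + int(round(k * spf))
        b = start + int(round((k + 1) * spf))
        frame_means = traces[:, a:b].mean(axis=1)
        grid8[k] = frame_means[order]
    grid = PixelGrid(recording.geometry, config.pixels_per_span)
    images = _interpolator(grid)(grid8)
    np.clip(images, 0.0, 1.0, out=images)  # interpolation overshoot guard
    return FrameStack(
        frames=images, frame_ms=config.frame_ms, grid=grid, segment_start_s=segment_start
    )


# ---------------------------------------------------------------------------
# near-field contact score


def _chunk_p2p(x: np.ndarray, chunk: int) -> np.ndarray:
    """Peak-to-peak of consecutive chunks of ``x`` (tail chunk dropped)."""
    n = (x.shape[-1] // chunk) * chunk
    if n == 0:
        return np.atleast_1d(np.ptp(x, axis=-1))
    xr = x[..., :n].reshape(*x.shape[:-1], -1, chunk)
    return np.ptp(xr, axis=-1)


def near_field_score(
    recording: EGMRecording,
    ventricular_times: np.ndarray | None = None,
    qrst_window_s: tuple[float, float] = (-0.05, 0.25),
    atrial_chunk_s: float = 0.5,
) -> ContactReport:
    """Score each electrode's tissue contact.

    score = median peak-to-peak amplitude in atrial windows (outside
    ventricular blanking) / median peak-to-peak amplitude inside ventricular
    QRST windows.  Channels scoring strictly below 0.7 are flagged low-contact.
    """
    if ventricular_times is None:
        ventricular_times = recording.ventricular_times
    if ventricular_times is None or len(ventricular_times) == 0:
        raise ValueError(
            "near-field scoring requires ventricular (QRS) event times; none available"
        )
    fs = recording.sampling_rate
    n = recording.n_samples
    v_mask = np.zeros(n, dtype=bool)
    for tv in np.asarray(ventricular_times, dtype=float):
        a = max(int((tv + qrst_window_s[0]) * fs), 0)
        b = min(int((tv + qrst_window_s[1]) * fs), n)
        v_mask[a:b] = True

    scores: dict[str, float] = {}
    flags: set[str] = set()
    chunk = max(int(atrial_chunk_s * fs), 1)
    for lab, sig in zip(recording.channel_labels, recording.signals):
        vent_p2ps = []
        for tv in np.asarray(ventricular_times, dtype=float):
            a = max(int((tv + qrst_window_s[0]) * fs), 0)
            b = min(int((tv + qrst_window_s[1]) * fs), n)
            if b - a > 2:
                vent_p2ps.append(np.ptp(sig[a:b]))
        atrial = sig[~v_mask]
        atrial_med = float(np.median(_chunk_p2p(atrial, chunk))) if atrial.size else 0.0
        vent_med = float(np.median(vent_p2ps)) if vent_p2ps else 0.0
        if vent_med == 0.0:
            warnings.warn(
                f"channel {lab}: zero ventricular amplitude; near-field score undefined "
                "(reported +inf, not flagged)",
                stacklevel=2,
            )
            scores[lab] = np.inf
            continue
        s = atrial_med / vent_med
        scores[lab] = s
        if s < ContactReport.LOW_CONTACT_THRESHOLD:
            flags.add(lab)
    return ContactReport(near_field_score=scores, low_contact_flags=flags)
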