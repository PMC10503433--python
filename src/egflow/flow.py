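"""Horn-Schunck optical flow on intensity frames; segment and summary maps.

The solver is the classical Horn-Schunck fixed point (brightness-constancy
data term plus an alpha^2-weighted smoothness term, Jacobi-style iteration)
with two modifications for basket-electrogram maps: spatial gradients and
neighbourhood averages wrap on the circumferential spline axis (rows) and
reflect on the electrode axis (cols), and the per-frame-pair flow fields of a
segment are smoothed temporally over a 3-pair window before singularity
detection.  Both behaviours are configurable.

A 2-s segment of 105 frames yields 104 frame-pair flow fields; thirty
back-to-back segments aggregate into the 1-minute summary map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import GridLocation
from .preprocess import FrameStack, PreprocessConfig, PixelGrid, voltage_to_intensity, _intensity_traces
from .recording import EGMRecording

__all__ = [
    "FlowConfig",
    "FlowField",
    "SegmentMap",
    "SummaryMap",
    "horn_schunck",
    "hs_energy",
    "build_segment_map",
    "build_summary_map",
]


@dataclass(frozen=True)
class FlowConfig:
    """Flow-estimation and detection parameters."""

    alpha: float = 1.0           # smoothness regularization weight
    iters: int = 100             # max Jacobi iterations
    tol: float = 1e-4            # stop when the max flow update falls below this
    wrap_rows: bool = True       # spline axis is circumferential
    temporal_window: int = 3     # flow smoothing across adjacent frame pairs
    noise_floor_frac: float = 0.05   # of the 95th-percentile flow magnitude
    min_summary_sac: float = 10.0    # % display threshold for summary sources
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)


@dataclass
class FlowField:
    """Per-pixel flow for one frame pair; ``u`` along cols, ``v`` along rows."""

    u: np.ndarray
    v: np.ndarray
    frame_index: int = 0
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow must be finite")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class SegmentMap:
    """Flow analysis of one 2-s segment (104 frame-pair fields)."""

    segment_index: int
    mean_u: np.ndarray
    mean_v: np.ndarray
    coherence: float
    detections: list  # per frame-pair: list of sources.Detection
    grid: PixelGrid
    n_frame_pairs: int
    flow_u: np.ndarray | None = None  # (n_pairs, R, C), retained when requested
    flow_v: np.ndarray | None = None


@dataclass
class SummaryMap:
    """One-minute aggregation of segment maps."""

    segment_maps: list[SegmentMap]
    sources: list            # sources.Source above the display threshold
    all_sources: list        # every tracked cluster (diagnostics)
    flow_origin: GridLocation
    flow_origin_pixel: tuple[int, int]
    mean_u: np.ndarray
    mean_v: np.ndarray
    grid: PixelGrid
    contact: object | None = None  # preprocess.ContactReport when computed


# ---------------------------------------------------------------------------
# gradients and neighbourhood averages (wrap rows / reflect cols)


def _d_col(x: np.ndarray) -> np.ndarray:
    return np.gradient(x, axis=-1)


def _d_row(x: np.ndarray, wrap: bool) -> np.ndarray:
    if wrap:
        return 0.5 * (np.roll(x, -1, axis=-2) - np.roll(x, 1, axis=-2))
    return np.gradient(x, axis=-2)


def _smooth121_rows(x: np.ndarray, wrap: bool) -> np.ndarray:
    if wrap:
        return 0.25 * (np.roll(x, 1, axis=-2) + 2.0 * x + np.roll(x, -1, axis=-2))
    up = np.concatenate([x[..., :1, :], x[..., :-1, :]], axis=-2)
    dn = np.concatenate([x[..., 1:, :], x[..., -1:, :]], axis=-2)
    return 0.25 * (up + 2.0 * x + dn)


def _smooth121_cols(x: np.ndarray) -> np.ndarray:
    lf = np.concatenate([x[..., :, :1], x[..., :, :-1]], axis=-1)
    rt = np.concatenate([x[..., :, 1:], x[..., :, -1:]], axis=-1)
    return 0.25 * (lf + 2.0 * x + rt)


def _neighbour_avg(x: np.ndarray, wrap: bool) -> np.ndarray:
    """Horn-Schunck weighted neighbour average (corner 1/12, edge 1/6)."""
    sep = _smooth121_cols(_smooth121_rows(x, wrap))
    return (4.0 * sep - x) / 3.0


def _gradients(
    frames: np.ndarray, wrap: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, b = frames[:-1], frames[1:]
    Ix = 0.5 * (_d_col(a) + _d_col(b))
    Iy = 0.5 * (_d_row(a, wrap) + _d_row(b, wrap))
    It = b - a
    return Ix, Iy, It


def _hs_stack_numpy(
    frames: np.ndarray, config: FlowConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference vectorized Horn-Schunck solver (see :func:`_hs_stack`)."""
    frames = np.asarray(frames, dtype=float)
    wrap = config.wrap_rows
    Ix, Iy, It = _gradients(frames, wrap)
    den = config.alpha**2 + Ix**2 + Iy**2
    u = np.zeros_like(Ix)
    v = np.zeros_like(Ix)
    for _ in range(config.iters):
        ubar = _neighbour_avg(u, wrap)
        vbar = _neighbour_avg(v, wrap)
        rate = (Ix * ubar + Iy * vbar + It) / den
        un = ubar - Ix * rate
        vn = vbar - Iy * rate
        delta = max(np.abs(un - u).max(), np.abs(vn - v).max())
        u, v = un, vn
        if delta < config.tol:
            break
    resid = (Ix * u + Iy * v + It) ** 2
    return u, v, resid.mean(axis=(-2, -1))


try:
    import numba

    @numba.njit(cache=False, fastmath=True)
    def _hs_iterate_numba(Ix, Iy, It, alpha2, iters, tol, wrap):  # pragma: no cover
        T, R, C = Ix.shape
        u = np.zeros((T, R, C))
        v = np.zeros((T, R, C))
        un = np.zeros((T, R, C))
        vn = np.zeros((T, R, C))
        for _ in range(iters):
            maxd = 0.0
            for t in range(T):
                for r in range(R):
                    if wrap:
                        rm = (r - 1) % R
                        rp = (r + 1) % R
                    else:
                        rm = r - 1 if r > 0 else 0
                        rp = r + 1 if r < R - 1 else R - 1
                    for c in range(C):
                        cm = c - 1 if c > 0 else 0
                        cp = c + 1 if c < C - 1 else C - 1
                        # separable (1,2,1)^2/16 smooth, then (4*sep - x)/3:
                        # classic HS kernel (edges 1/6, corners 1/12)
                        su = (
                            2.0 * (u[t, rm, c] + u[t, rp, c] + u[t, r, cm] + u[t, r, cp])
                            + u[t, rm, cm] + u[t, rm, cp] + u[t, rp, cm] + u[t, rp, cp]
                            + 4.0 * u[t, r, c]
                        ) / 16.0
                        sv = (
                            2.0 * (v[t, rm, c] + v[t, rp, c] + v[t, r, cm] + v[t, r, cp])
                            + v[t, rm, cm] + v[t, rm, cp] + v[t, rp, cm] + v[t, rp, cp]
                            + 4.0 * v[t, r, c]
                        ) / 16.0
                        ub = (4.0 * su - u[t, r, c]) / 3.0
                        vb = (4.0 * sv - v[t, r, c]) / 3.0
                        ix = Ix[t, r, c]
                        iy = Iy[t, r, c]
                        rate = (ix * ub + iy * vb + It[t, r, c]) / (
                            alpha2 + ix * ix + iy * iy
                        )
                        nu = ub - ix * rate
                        nv = vb - iy * rate
                        d = abs(nu - u[t, r, c])
                        if d > maxd:
                            maxd = d
                        d = abs(nv - v[t, r, c])
                        if d > maxd:
                            maxd = d
                        un[t, r, c] = nu
                        vn[t, r, c] = nv
            u, un = un, u
            v, vn = vn, v
            if maxd < tol:
                break
        return u, v

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _hs_stack(
    frames: np.ndarray, config: FlowConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve Horn-Schunck for every consecutive frame pair of a stack at once.

    Returns (u, v, residual) with u, v of shape (n_frames-1, R, C).  Uses a
    fused compiled kernel when numba is available; the numpy reference path
    computes the identical fixed point.
    """
    if not _HAVE_NUMBA:  # pragma: no cover
        return _hs_stack_numpy(frames, config)
    frames = np.ascontiguousarray(frames, dtype=float)
    wrap = config.wrap_rows
    Ix, Iy, It = _gradients(frames, wrap)
    u, v = _hs_iterate_numba(
        np.ascontiguousarray(Ix),
        np.ascontiguousarray(Iy),
        np.ascontiguousarray(It),
        config.alpha**2,
        config.iters,
        config.tol,
        wrap,
    )
    resid = (Ix * u + Iy * v + It) ** 2
    return u, v, resid.mean(axis=(-2, -1))


def horn_schunck(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    alpha: float = 1.0,
    iters: int = 100,
    tol: float = 1e-4,
    wrap_rows: bool = True,
) -> FlowField:
    """Estimate the flow between two intensity images."""
    frame_a = np.asarray(frame_a, dtype=float)
    frame_b = np.asarray(frame_b, dtype=float)
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have the same shape")
    if not (np.all(np.isfinite(frame_a)) and np.all(np.isfinite(frame_b))):
        raise ValueError("frames must be finite")
    if alpha <= 0 or iters < 1:
        raise ValueError("alpha must be positive and iters >= 1")
    cfg = FlowConfig(alpha=alpha, iters=iters, tol=tol, wrap_rows=wrap_rows)
    u, v, resid = _hs_stack(np.stack([frame_a, frame_b]), cfg)
    return FlowField(u=u[0], v=v[0], residual=float(resid[0]))


def hs_energy(
    u: np.ndarray,
    v: np.ndarray,
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    alpha: float = 1.0,
    wrap_rows: bool = True,
) -> float:
    """Horn-Schunck objective: data term + alpha^2-weighted smoothness term."""
    Ix = 0.5 * (_d_col(frame_a) + _d_col(frame_b))
    Iy = 0.5 * (_d_row(frame_a, wrap_rows) + _d_row(frame_b, wrap_rows))
    It = frame_b - frame_a
    data = (Ix * u + Iy * v + It) ** 2
    smooth = 0.0
    # neighbour-difference smoothness matching the HS averaging kernel
    for x in (u, v):
        for dr, dc, w in ((0, 1, 1 / 6), (1, 0, 1 / 6), (1, 1, 1 / 12), (1, -1, 1 / 12)):
            shifted = np.roll(x, (dr, dc), axis=(0, 1))
            d2 = (x - shifted) ** 2
            if not wrap_rows and dr:
                d2[0, :] = 0.0
            if dc == 1:
                d2[:, 0] = 0.0
            elif dc == -1:
                d2[:, -1] = 0.0
            smooth += w * d2.sum()
    return float(data.sum() + alpha**2 * 2.0 * smooth)


def _temporal_smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over the frame-pair axis, truncated at the ends."""
    if window <= 1:
        return x
    half = window // 2
    n = x.shape[0]
    csum = np.cumsum(x, axis=0)
    out = np.empty_like(x)
    for i in range(n):
        a, b = max(i - half, 0), min(i + half + 1, n)
        total = csum[b - 1] - (csum[a - 1] if a > 0 else 0)
        out[i] = total / (b - a)
    return out


def _coherence(u: np.ndarray, v: np.ndarray, noise_floor_frac: float) -> float:
    """Mean resultant length of flow angles over pixels above the noise floor."""
    mag = np.hypot(u, v)
    floor = noise_floor_frac * np.percentile(mag, 95)
    sel = mag > max(floor, 1e-12)
    if not np.any(sel):
        return 0.0
    ang = np.arctan2(v[sel], u[sel])
    return float(np.abs(np.exp(1j * ang).mean()))


def build_segment_map(
    frames: FrameStack,
    config: FlowConfig | None = None,
    segment_index: int = 0,
    keep_flows: bool = False,
) -> SegmentMap:
    """Flow fields, coherence and singularity detections for one segment."""
    from .sources import detect_singularities_stack

    config = config or FlowConfig()
    expected = config.preprocess.frames_per_segment
    if frames.n_frames != expected:
        raise ValueError(
            f"segment must contain {expected} frames, got {frames.n_frames}"
        )
    u, v, _resid = _hs_stack(frames.frames, config)
    us = _temporal_smooth(u, config.temporal_window)
    vs = _temporal_smooth(v, config.temporal_window)
    detections = detect_singularities_stack(us, vs, config)
    mean_u, mean_v = us.mean(axis=0), vs.mean(axis=0)
    return SegmentMap(
        segment_index=segment_index,
        mean_u=mean_u,
        mean_v=mean_v,
        coherence=_coherence(mean_u, mean_v, config.noise_floor_frac),
        detections=detections,
        grid=frames.grid,
        n_frame_pairs=u.shape[0],
        flow_u=us if keep_flows else None,
        flow_v=vs if keep_flows else None,
    )


def _divergence(u: np.ndarray, v: np.ndarray, wrap: bool) -> np.ndarray:
    return _d_col(u) + _d_row(v, wrap)


def build_summary_map(
    recording: EGMRecording,
    config: FlowConfig | None = None,
    contact: object | None = None,
) -> SummaryMap:
    """Full-recording aggregation: 30 segment maps, tracked sources, flow origin."""
    from .sources import track_sources

    config = config or FlowConfig()
    pconf = config.preprocess
    if recording.duration < pconf.segment_s:
        raise ValueError("recording shorter than one segment")
    n_segments = int(recording.duration // pconf.segment_s)
    if n_segments < 30:
        warnings.warn(
            f"recording yields {n_segments} segment maps (canonical summary uses 30)",
            stacklevel=2,
        )
    traces = _intensity_traces(recording, pconf)
    segment_maps = []
    for s in range(n_segments):
        frames = voltage_to_intensity(
            recording, segment_start=s * pconf.segment_s, config=pconf, _traces=traces
        )
        segment_maps.append(build_segment_map(frames, config, segment_index=s))

    sources, all_sources = track_sources(segment_maps, config, contact=contact)

    grid = segment_maps[0].grid
    wrap = config.wrap_rows
    div_total = np.zeros((grid.n_rows, grid.n_cols))
    mean_u = np.zeros_like(div_total)
    mean_v = np.zeros_like(div_total)
    for sm in segment_maps:
        div_total += _divergence(sm.mean_u, sm.mean_v, wrap)
        mean_u += sm.mean_u
        mean_v += sm.mean_v
    mean_u /= n_segments
    mean_v /= n_segments
    interior = div_total.copy()
    interior[:, 0] = -np.inf  # open-boundary columns excluded
    interior[:, -1] = -np.inf
    pr, pc = np.unravel_index(np.argmax(interior), interior.shape)
    gr, gc = grid.pixel_to_grid_units(pr, pc)
    origin = GridLocation(
        row=int(round(gr)) % grid.geometry.n_splines,
        col=int(np.clip(round(gc), 0, grid.geometry.n_electrodes_per_spline - 1)),
    )
    return SummaryMap(
        segment_maps=segment_maps,
        sources=sources,
        all_sources=all_sources,
        flow_origin=origin,
        flow_origin_pixel=(int(pr), int(pc)),
        mean_u=mean_u,
        mean_v=mean_v,
        grid=grid,
        contact=contact,
    )
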