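"""Flow-singularity detection, source tracking, and the pacing-validation experiment.

A singularity is declared at a pixel when, inside its 3x3 window, the eight
surrounding flow vectors' angles cover the full 360 deg — walked in ring
order they sweep one net full turn, passing through every 45-deg sector
(equivalently, the Poincare index of the ring is +/-1).  The sign of the
mean radial component of the ring vectors
classifies the point: outward (centrifugal) flow marks an *active divergent*
source — a candidate AF driver — while inward flow and dominantly tangential
flow mark *passive* convergent and rotational phenomena.

Detections close in space are tracked across the 2-s segments of a recording
into Source objects; the per-segment source activity (SAC) is the percentage
of a segment's 104 frame pairs in which the cluster shows a qualifying active
divergent detection, and the summary SAC is its mean over all segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .geometry import BasketGeometry, GridLocation, electrode_distance, grid_to_label

if TYPE_CHECKING:  # pragma: no cover
    from .flow import FlowConfig, FlowField, SegmentMap
    from .synth import WaveScenario

__all__ = [
    "SourceType",
    "Detection",
    "Source",
    "detect_singularities",
    "detect_singularities_stack",
    "track_sources",
    "match_location",
    "run_detection_experiment",
]

ACTIVE_DIVERGENT = "active_divergent"
PASSIVE_ROTATIONAL = "passive_rotational"
PASSIVE_CONVERGENT = "passive_convergent"
SourceType = str

# ring offsets (dr, dc) of the 3x3 window in counter-clockwise ring order
# (CCW in the (x=col, y=row) frame used for flow angles), and their radii
_OFFSETS = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)
_OFFSET_NORM = np.linalg.norm(_OFFSETS, axis=1)


@dataclass(frozen=True)
class Detection:
    """One per-frame singularity: pixel position, type, strength."""

    row_px: int
    col_px: int
    type: SourceType
    radial: float      # mean radial ring component (>0 outward)
    tangential: float  # mean tangential ring component (signed, CCW positive)


@dataclass
class Source:
    """A tracked flow singularity with its activity history."""

    anchor: GridLocation
    pixel: tuple[float, float]
    type: SourceType
    per_segment_activity: np.ndarray  # %, one value per 2-s segment
    summary_sac: float                # % = mean(per_segment_activity)
    first_segment_active: int | None
    last_segment_active: int | None
    n_detections: int
    unreliable_contact: bool = False

    @property
    def label(self) -> str:
        return grid_to_label(self.anchor)


# ---------------------------------------------------------------------------
# sector-coverage singularity detector


def _ring_components(
    u: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stacked ring vectors around every pixel.

    Returns (ru, rv, radial, tangential), each (8, ..., R, C): the k-th slice
    holds, for every pixel p, the flow at its k-th ring neighbour and that
    flow's radial/tangential component relative to p.  Rows wrap (spline
    axis); column edges are handled by excluding boundary columns downstream.
    """
    ru = np.stack([np.roll(u, (-dr, -dc), axis=(-2, -1)) for dr, dc in _OFFSETS])
    rv = np.stack([np.roll(v, (-dr, -dc), axis=(-2, -1)) for dr, dc in _OFFSETS])
    # radial unit vector at offset (dr, dc) is (dc, dr)/|.| in (x=col, y=row)
    rad_x = (_OFFSETS[:, 1] / _OFFSET_NORM).reshape(-1, *([1] * (u.ndim)))
    rad_y = (_OFFSETS[:, 0] / _OFFSET_NORM).reshape(-1, *([1] * (u.ndim)))
    radial = ru * rad_x + rv * rad_y
    tangential = -ru * rad_y + rv * rad_x  # 90 deg CCW of radial
    return ru, rv, radial, tangential


def _detect_mask(
    u: np.ndarray, v: np.ndarray, noise_floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sector-coverage test at every pixel of (..., R, C) flow arrays.

    The 8 ring vectors are walked in counter-clockwise ring order and the
    wrapped angle increments are summed: a singularity exists when the angles
    sweep one net full turn ("flow vector angles around the point cover
    360 deg"; a net +/-360-deg sweep necessarily passes through all eight
    45-deg sectors).  Every ring vector must exceed the noise floor to vote.
    Returns (mask, mean_radial, mean_tangential); boundary columns are False.
    """
    ru, rv, radial, tangential = _ring_components(u, v)
    mag = np.hypot(ru, rv)
    ang = np.arctan2(rv, ru)
    two_pi = 2 * np.pi
    all_above = np.all(mag >= noise_floor, axis=0)
    diffs = (ang[list(range(1, 8)) + [0]] - ang + np.pi) % two_pi - np.pi
    winding = np.rint(diffs.sum(axis=0) / two_pi)
    mask = all_above & (np.abs(winding) == 1)
    mask[..., :, 0] = False
    mask[..., :, -1] = False
    return mask, radial.mean(axis=0), tangential.mean(axis=0)


def _classify(radial: float, tangential: float) -> SourceType:
    if abs(tangential) > abs(radial):
        return PASSIVE_ROTATIONAL
    return ACTIVE_DIVERGENT if radial > 0 else PASSIVE_CONVERGENT


def _merge_frame(
    mask: np.ndarray, radial: np.ndarray, tangential: np.ndarray, wrap: bool
) -> list[Detection]:
    """Merge touching detections of one frame to the local strength maximum."""
    from scipy import ndimage

    if not mask.any():
        return []
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if wrap and n > 1:
        # stitch components touching across the periodic row seam
        top, bot = labels[0], labels[-1]
        parent = list(range(n + 1))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for c in range(mask.shape[1]):
            a = top[c]
            if a == 0:
                continue
            for cc in (c - 1, c, c + 1):
                if 0 <= cc < mask.shape[1] and bot[cc] != 0:
                    ra, rb = find(a), find(bot[cc])
                    if ra != rb:
                        parent[rb] = ra
        labels = np.array([0] + [find(i) for i in range(1, n + 1)])[labels]
    out = []
    strength = np.abs(radial) + np.abs(tangential)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        best = np.argmax(np.abs(radial[rows, cols]))
        if np.abs(radial[rows, cols]).max() == 0:
            best = np.argmax(strength[rows, cols])
        r, c = int(rows[best]), int(cols[best])
        out.append(
            Detection(
                row_px=r,
                col_px=c,
                type=_classify(radial[r, c], tangential[r, c]),
                radial=float(radial[r, c]),
                tangential=float(tangential[r, c]),
            )
        )
    return out


def _noise_floor(u: np.ndarray, v: np.ndarray, frac: float) -> float:
    mag = np.hypot(u, v)
    return max(frac * float(np.percentile(mag, 95)), 1e-12)


def detect_singularities(
    flow: "FlowField | tuple[np.ndarray, np.ndarray]",
    config: "FlowConfig | None" = None,
) -> list[Detection]:
    """Detect and classify flow singularities in a single flow field."""
    from .flow import FlowConfig

    config = config or FlowConfig()
    if isinstance(flow, tuple):
        u, v = flow
    else:
        u, v = flow.u, flow.v
    floor = _noise_floor(u, v, config.noise_floor_frac)
    mask, radial, tangential = _detect_mask(u, v, floor)
    return _merge_frame(mask, radial, tangential, config.wrap_rows)


def detect_singularities_stack(
    u: np.ndarray, v: np.ndarray, config: "FlowConfig"
) -> list[list[Detection]]:
    """Per-frame detections for a (n_pairs, R, C) flow stack.

    The noise floor is shared across the segment (95th-percentile magnitude of
    the whole stack), so a momentary lull cannot promote jitter to a source.
    """
    floor = _noise_floor(u, v, config.noise_floor_frac)
    mask, radial, tangential = _detect_mask(u, v, floor)
    return [
        _merge_frame(mask[k], radial[k], tangential[k], config.wrap_rows)
        for k in range(u.shape[0])
    ]


# ---------------------------------------------------------------------------
# winding-number (Poincare-index) oracle — independent cross-check


def poincare_index(
    u: np.ndarray, v: np.ndarray, row: int, col: int, noise_floor: float = 0.0
) -> int | None:
    """Brute-force winding number of the flow angle around a pixel's 3x3 ring.

    Walks the ring counter-clockwise summing wrapped angle increments.
    Returns None when any ring vector falls below the noise floor.
    """
    ring = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    # order the ring CCW in (x=col, y=row *downward*): use geometric angle order
    ring = sorted(ring, key=lambda d: np.arctan2(d[0], d[1]))
    angles = []
    R = u.shape[0]
    for dr, dc in ring:
        r, c = (row + dr) % R, col + dc
        if not (0 <= c < u.shape[1]):
            return None
        if np.hypot(u[r, c], v[r, c]) < noise_floor:
            return None
        angles.append(np.arctan2(v[r, c], u[r, c]))
    total = 0.0
    for i in range(len(angles)):
        d = angles[(i + 1) % len(angles)] - angles[i]
        total += (d + np.pi) % (2 * np.pi) - np.pi
    return int(round(total / (2 * np.pi)))


# ---------------------------------------------------------------------------
# tracking and SAC


class _Cluster:
    def __init__(self, grid, geometry: BasketGeometry):
        self.grid = grid
        self.geometry = geometry
        self.rows: list[float] = []
        self.cols: list[float] = []
        self.types: list[SourceType] = []
        # (segment, frame) indices of qualifying active-divergent detections
        self.active_frames: set[tuple[int, int]] = set()
        self.n = 0

    def mean_position(self) -> tuple[float, float]:
        # circular mean on the periodic row axis, in pixel units
        period = self.grid.n_rows
        ang = 2 * np.pi * np.asarray(self.rows) / period
        mrow = (np.angle(np.exp(1j * ang).mean()) / (2 * np.pi) * period) % period
        return float(mrow), float(np.mean(self.cols))

    def mean_grid_units(self) -> tuple[float, float]:
        mr, mc = self.mean_position()
        return self.grid.pixel_to_grid_units(mr, mc)

    def distance_to(self, gr: float, gc: float) -> float:
        """Continuous wrap-aware Chebyshev distance (grid units) to the mean."""
        mr, mc = self.mean_grid_units()
        period = self.grid.row_period
        dr = abs(mr - gr)
        dr = min(dr, period - dr)
        return max(dr, abs(mc - gc))

    def anchor(self) -> GridLocation:
        gr, gc = self.mean_grid_units()
        return GridLocation(
            row=int(round(gr)) % self.geometry.n_splines,
            col=int(np.clip(round(gc), 0, self.geometry.n_electrodes_per_spline - 1)),
        )

    def add(self, det: Detection, segment: int, frame: int) -> None:
        self.rows.append(det.row_px)
        self.cols.append(det.col_px)
        self.types.append(det.type)
        self.n += 1
        if det.type == ACTIVE_DIVERGENT:
            self.active_frames.add((segment, frame))

    def absorb(self, other: "_Cluster") -> None:
        self.rows.extend(other.rows)
        self.cols.extend(other.cols)
        self.types.extend(other.types)
        self.active_frames |= other.active_frames
        self.n += other.n


def track_sources(
    segment_maps: "list[SegmentMap]",
    config: "FlowConfig | None" = None,
    contact=None,
) -> tuple[list[Source], list[Source]]:
    """Cluster per-frame detections into Sources and quantify their activity.

    Returns (summary_sources, all_sources): the first list keeps only sources
    at or above the summary display threshold (default 10% SAC); the second
    retains every cluster for diagnostics.  SAC itself is never thresholded.
    """
    from .flow import FlowConfig

    config = config or FlowConfig()
    if not segment_maps:
        raise ValueError("at least one segment map is required")
    grid = segment_maps[0].grid
    geometry = grid.geometry
    clusters: list[_Cluster] = []
    for sm in segment_maps:
        for frame_idx, dets in enumerate(sm.detections):
            for det in dets:
                gr, gc = grid.pixel_to_grid_units(det.row_px, det.col_px)
                best, best_d = None, np.inf
                for cl in clusters:
                    d = cl.distance_to(gr, gc)
                    if d <= 1.0 and (
                        d < best_d
                        or (
                            d == best_d
                            and best is not None
                            and (cl.anchor().row, cl.anchor().col)
                            < (best.anchor().row, best.anchor().col)
                        )
                    ):
                        best, best_d = cl, d
                if best is None:
                    best = _Cluster(grid, geometry)
                    clusters.append(best)
                best.add(det, sm.segment_index, frame_idx)

    # final pass: fuse clusters whose mean positions drifted within one
    # electrode of each other (a source straddling a cell boundary must not
    # have its activity split between two anchors)
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                gr, gc = clusters[j].mean_grid_units()
                if clusters[i].distance_to(gr, gc) <= 1.0:
                    clusters[i].absorb(clusters[j])
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break

    n_segments = len(segment_maps)
    seg_pairs = {sm.segment_index: sm.n_frame_pairs for sm in segment_maps}
    seg_order = sorted(seg_pairs)
    sources_all: list[Source] = []
    for cl in clusters:
        activity = np.zeros(n_segments)
        for i, seg in enumerate(seg_order):
            n_active = sum(1 for (s, _f) in cl.active_frames if s == seg)
            activity[i] = 100.0 * n_active / seg_pairs[seg]
        anchor = cl.anchor()
        active_segs = [seg_order[i] for i in range(n_segments) if activity[i] > 0]
        types, counts = np.unique(cl.types, return_counts=True)
        dominant = str(types[np.argmax(counts)])
        unreliable = False
        if contact is not None:
            for lab in contact.low_contact_flags:
                if electrode_distance(anchor, lab, geometry) <= 1.0:
                    unreliable = True
                    break
        sources_all.append(
            Source(
                anchor=anchor,
                pixel=cl.mean_position(),
                type=dominant,
                per_segment_activity=activity,
                summary_sac=float(activity.mean()),
                first_segment_active=active_segs[0] if active_segs else None,
                last_segment_active=active_segs[-1] if active_segs else None,
                n_detections=cl.n,
                unreliable_contact=unreliable,
            )
        )
    sources_all.sort(key=lambda s: -s.summary_sac)
    summary = [s for s in sources_all if s.summary_sac >= config.min_summary_sac]
    return summary, sources_all


def match_location(
    source: Source | GridLocation | str,
    pacing_site: GridLocation | str,
    geometry: BasketGeometry | None = None,
) -> bool:
    """True when the source sits within one electrode distance of the pacing site."""
    loc = source.anchor if isinstance(source, Source) else source
    return electrode_distance(loc, pacing_site, geometry or BasketGeometry()) <= 1.0


# ---------------------------------------------------------------------------
# pacing-validation experiment


def run_detection_experiment(
    scenarios: "list[WaveScenario]",
    config: "FlowConfig | None" = None,
    duration: float = 60.0,
) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline over a batch of scenarios and score detections.

    For each recording: detected active sources (summary threshold applied)
    are matched against the scenario's true source / stimulus site within one
    electrode distance.  Returns a per-recording table and a per-condition
    summary with detection and spurious-source rates (in percent).
    """
    from .flow import FlowConfig, build_summary_map
    from .synth import simulate

    config = config or FlowConfig()
    rows = []
    for scn in scenarios:
        target = scn.origin  # pacing/stimulus site (or designated source)
        try:
            rec, truth = simulate(scn, duration=duration)
            summary = build_summary_map(rec, config)
            active = [s for s in summary.sources if s.type == ACTIVE_DIVERGENT]
            matched = target is not None and any(
                match_location(s, target) for s in active
            )
            true_locs = [truth.true_source_location] if truth.true_source_location else []
            spurious = sum(
                1
                for s in active
                if not any(match_location(s, t) for t in true_locs)
            )
            rows.append(
                dict(
                    condition=scn.kind,
                    seed=scn.seed,
                    true_site=grid_to_label(target) if target else "",
                    detected_sites=";".join(s.label for s in active),
                    n_active=len(active),
                    match=bool(matched),
                    spurious=spurious,
                    error="",
                )
            )
        except Exception as exc:  # a failed recording must not abort the batch
            rows.append(
                dict(
                    condition=scn.kind,
                    seed=scn.seed,
                    true_site=grid_to_label(target) if target else "",
                    detected_sites="",
                    n_active=0,
                    match=False,
                    spurious=0,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    table = pd.DataFrame(rows)
    report = {}
    for cond, grp in table.groupby("condition"):
        ok = grp[grp["error"] == ""]
        report[cond] = dict(
            n=int(len(grp)),
            n_failed=int((grp["error"] != "").sum()),
            detection_rate_pct=float(100.0 * ok["match"].mean()) if len(ok) else np.nan,
            spurious_rate_pct=float(100.0 * (ok["spurious"] > 0).mean())
            if len(ok)
            else np.nan,
            mean_spurious_per_recording=float(ok["spurious"].mean())
            if len(ok)
            else np.nan,
        )
    return table, report
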