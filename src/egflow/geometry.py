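"""Basket-catheter grid geometry and channel-label conventions.

A 64-pole basket catheter carries 8 splines (labelled A-H) of 8 electrodes
(numbered 1-8).  Splines wrap circumferentially around the atrial chamber, so
the spline axis is periodic; the electrode axis runs from the distal to the
proximal end of each spline and does not wrap.  All distances are expressed in
grid units (one inter-electrode spacing = 1.0 on both axes).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BasketGeometry",
    "GridLocation",
    "label_to_grid",
    "grid_to_label",
    "electrode_distance",
    "wave_distance",
]

_LABEL_RE = re.compile(r"^([A-H])([1-8])$")


@dataclass(frozen=True)
class BasketGeometry:
    """Layout of the basket electrode array.

    Splines map to rows 0-7 (circumferential, wrapped when ``wrap_splines``);
    electrode numbers map to columns 0-7 (longitudinal, never wrapped).
    """

    n_splines: int = 8
    n_electrodes_per_spline: int = 8
    wrap_splines: bool = True
    inter_electrode_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.n_splines * self.n_electrodes_per_spline != 64:
            raise ValueError("basket must have 8 splines x 8 electrodes = 64 poles")

    @property
    def spline_labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_splines)]

    @property
    def channel_labels(self) -> list[str]:
        """All 64 labels in row-major (spline-major) order: A1..A8, B1..B8, ..."""
        return [
            f"{s}{e + 1}"
            for s in self.spline_labels
            for e in range(self.n_electrodes_per_spline)
        ]


@dataclass(frozen=True)
class GridLocation:
    """Electrode-grid position; ``row`` is the spline index, ``col`` the electrode index.

    ``row_off``/``col_off`` carry optional sub-electrode offsets used for
    pixel-grid positions.
    """

    row: int
    col: int
    row_off: float = 0.0
    col_off: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.row < 8 and 0 <= self.col < 8):
            raise ValueError(f"grid location out of range: ({self.row}, {self.col})")

    @property
    def position(self) -> tuple[float, float]:
        return (self.row + self.row_off, self.col + self.col_off)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return grid_to_label(self)


def label_to_grid(label: str) -> GridLocation:
    """Convert a basket channel label such as ``"G1"`` to a :class:`GridLocation`.

    Rows follow spline letters A-H, columns electrode numbers 1-8, so
    ``"A1"`` is (0, 0) and ``"H8"`` is (7, 7).
    """
    m = _LABEL_RE.match(str(label).strip().upper())
    if m is None:
        raise ValueError(
            f"malformed channel label {label!r}: expected spline letter A-H "
            "followed by electrode number 1-8 (e.g. 'G1')"
        )
    return GridLocation(row=ord(m.group(1)) - ord("A"), col=int(m.group(2)) - 1)


def grid_to_label(loc: GridLocation) -> str:
    """Inverse of :func:`label_to_grid`."""
    return f"{chr(ord('A') + loc.row)}{loc.col + 1}"


def _row_delta(a: float, b: float, geometry: BasketGeometry) -> float:
    d = abs(a - b)
    if geometry.wrap_splines:
        d = min(d, geometry.n_splines - d)
    return d


def electrode_distance(
    a: GridLocation | str,
    b: GridLocation | str,
    geometry: BasketGeometry | None = None,
) -> float:
    """Chebyshev distance in grid units, wrapped on the spline axis.

    "Within one electrode distance" therefore means the 8-neighbourhood of an
    electrode, with splines A and H treated as adjacent.
    """
    geometry = geometry or BasketGeometry()
    if isinstance(a, str):
        a = label_to_grid(a)
    if isinstance(b, str):
        b = label_to_grid(b)
    (ra, ca), (rb, cb) = a.position, b.position
    return max(_row_delta(ra, rb, geometry), abs(ca - cb))


def wave_distance(
    a: tuple[float, float],
    b: tuple[float, float],
    geometry: BasketGeometry | None = None,
) -> float:
    """Euclidean propagation distance in grid units (wrapped on the spline axis).

    Used for wavefront travel times; contrast with :func:`electrode_distance`,
    the Chebyshev match criterion.
    """
    geometry = geometry or BasketGeometry()
    dr = _row_delta(a[0], b[0], geometry)
    return float(np.hypot(dr, a[1] - b[1]))
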