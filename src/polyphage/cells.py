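"""Per-cell smFISH quantification and induction-quadrant classification.

Spots are assigned to segmented cells through a 2D label mask (segmentation is
performed on z-projections, so z is ignored for assignment).  Per cell and
channel, the summed integrated spot intensity is reported with a pseudovalue
floor: totals <= 1 — including cells with no spots — are replaced by exactly 1,
so every cell appears on a log-scaled scatter.  Quadrant boundaries are
derived from an uninduced cell population, and each cell is classified as
``none`` / ``a_only`` / ``b_only`` / ``both`` by strict comparison of its two
channel totals against the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .spots import SpotFit

__all__ = [
    "CellMask",
    "CellQuant",
    "QuadrantBoundaries",
    "assign_spots_to_cells",
    "sum_cell_intensity",
    "derive_boundaries",
    "classify_cells",
    "QUADRANTS",
]

QUADRANTS = ("none", "a_only", "b_only", "both")

PSEUDOVALUE = 1.0


@dataclass
class CellMask:
    """2D integer label image over the (y, x) footprint of the stacks."""

    label_image: np.ndarray
    excluded_labels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        li = np.asarray(self.label_image)
        if li.ndim != 2 or not np.issubdtype(li.dtype, np.integer):
            raise ValueError("label_image must be a 2D integer array")
        if li.min() < 0:
            raise ValueError("labels must be non-negative")
        self.label_image = li
        self.excluded_labels = frozenset(int(l) for l in self.excluded_labels)

    @property
    def cell_ids(self) -> list[int]:
        ids = np.unique(self.label_image)
        return [int(i) for i in ids if i > 0 and i not in self.excluded_labels]


@dataclass
class CellQuant:
    """Per-cell channel totals (pseudovalue-floored) and quadrant class."""

    cell_id: int
    total_intensity: dict[str, float] = field(default_factory=dict)
    pseudovalue_applied: dict[str, bool] = field(default_factory=dict)
    quadrant: str = "none"


@dataclass(frozen=True)
class QuadrantBoundaries:
    """Per-channel induction boundaries derived from uninduced cells."""

    boundary: Mapping[str, float]
    method: str
    n_uninduced: int


@dataclass(frozen=True)
class SpotAssignment:
    assigned: dict[int, list[SpotFit]]  # cell id -> spots
    n_background: int
    n_excluded: int
    n_out_of_bounds: int


def assign_spots_to_cells(spots: Iterable[SpotFit], mask: CellMask) -> SpotAssignment:
    """Map each spot to the cell occupying the nearest pixel of its (x, y) centre.

    Spots landing on background or on an excluded label are dropped and
    counted separately, as are spots whose centres fall outside the mask.
    """
    li = mask.label_image
    assigned: dict[int, list[SpotFit]] = {}
    n_bg = n_exc = n_oob = 0
    for s in spots:
        x, y = s.center[0], s.center[1]
        yi, xi = int(round(y)), int(round(x))
        if not (0 <= yi < li.shape[0] and 0 <= xi < li.shape[1]):
            n_oob += 1
            continue
        lab = int(li[yi, xi])
        if lab == 0:
            n_bg += 1
        elif lab in mask.excluded_labels:
            n_exc += 1
        else:
            assigned.setdefault(lab, []).append(s)
    return SpotAssignment(assigned, n_bg, n_exc, n_oob)


def sum_cell_intensity(
    assignment: SpotAssignment,
    mask: CellMask,
    channel: str | None = None,
) -> dict[int, tuple[float, bool]]:
    """Per-cell summed integrated intensity with the pseudovalue floor.

    Every non-excluded cell in the mask is reported; totals <= 1 (including
    zero-spot cells) become exactly 1 with a ``pseudovalue_applied`` flag.
    Returns ``{cell_id: (total, pseudovalue_applied)}``.
    """
    out: dict[int, tuple[float, bool]] = {}
    for cid in mask.cell_ids:
        spots = assignment.assigned.get(cid, [])
        total = float(
            sum(s.integrated_intensity for s in spots if channel in (None, s.channel))
        )
        if total <= PSEUDOVALUE:
            out[cid] = (PSEUDOVALUE, True)
        else:
            out[cid] = (total, False)
    return out


def quantify_cells(
    spots_by_channel: Mapping[str, Iterable[SpotFit]], mask: CellMask
) -> list[CellQuant]:
    """Convenience: assign and sum every channel, returning one CellQuant per cell."""
    totals: dict[str, dict[int, tuple[float, bool]]] = {}
    for ch, spots in spots_by_channel.items():
        assignment = assign_spots_to_cells(spots, mask)
        totals[ch] = sum_cell_intensity(assignment, mask)
    quants = []
    for cid in mask.cell_ids:
        q = CellQuant(cell_id=cid)
        for ch in spots_by_channel:
            tot, pv = totals[ch][cid]
            q.total_intensity[ch] = tot
            q.pseudovalue_applied[ch] = pv
        quants.append(q)
    return quants


def derive_boundaries(
    uninduced: Sequence[CellQuant],
    method: str = "max_uninduced",
    q: float = 0.99,
) -> QuadrantBoundaries:
    """Per-channel boundary from uninduced cells: their max (default) or q-quantile.

    Boundaries are floored at the pseudovalue (1).
    """
    if not uninduced:
        raise ValueError("at least one uninduced cell is required")
    channels = sorted({ch for c in uninduced for ch in c.total_intensity})
    boundary = {}
    for ch in channels:
        vals = np.array([c.total_intensity[ch] for c in uninduced if ch in c.total_intensity])
        if vals.size == 0:
            raise ValueError(f"no uninduced totals for channel {ch!r}")
        if method == "max_uninduced":
            b = float(vals.max())
        elif method == "quantile":
            b = float(np.quantile(vals, q))
        else:
            raise ValueError(f"unknown boundary method {method!r}")
        boundary[ch] = max(b, PSEUDOVALUE)
    return QuadrantBoundaries(boundary=boundary, method=method, n_uninduced=len(uninduced))


def classify_cells(
    quants: Sequence[CellQuant],
    boundaries: QuadrantBoundaries,
    channel_a: str,
    channel_b: str,
) -> tuple[list[CellQuant], dict[str, float]]:
    """Assign each cell to a quadrant and return the four class fractions.

    A cell is induced in a channel when its total is strictly greater than
    that channel's boundary (a cell exactly at the boundary is not induced).
    Fractions are over the classified cells and sum to 1.
    """
    ba = boundaries.boundary[channel_a]
    bb = boundaries.boundary[channel_b]
    counts = dict.fromkeys(QUADRANTS, 0)
    for q in quants:
        a = q.total_intensity[channel_a] > ba
        b = q.total_intensity[channel_b] > bb
        q.quadrant = "both" if (a and b) else "a_only" if a else "b_only" if b else "none"
        counts[q.quadrant] += 1
    n = len(quants)
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return list(quants), fractions
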