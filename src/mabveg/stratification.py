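"""Terrain constraint factors: slope split, belt raster, object-belt assignment.

The slope split assumes a single dominant east-west ridge (adequate for the
synthetic scenes; a documented limitation for arbitrary real terrain): the
ridgeline is the per-column row of maximum elevation, median-smoothed, and
pixels on/above it are "north".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .mab_model import BeltDefinition, MabTable, belt_at
from .segmentation import ObjectMap

__all__ = [
    "SLOPE_UNDEFINED",
    "SLOPE_NORTH",
    "SLOPE_SOUTH",
    "BeltRaster",
    "split_slopes",
    "build_constraint_raster",
    "assign_objects",
]

SLOPE_UNDEFINED = 0
SLOPE_NORTH = 1
SLOPE_SOUTH = 2

_RIDGE_SMOOTH = 11  # median window (columns)


def split_slopes(dsm: np.ndarray) -> np.ndarray:
    """North/south slope mask from the per-column elevation maximum.

    Ridge pixels are assigned north (deterministic tie rule).  A flat DSM has
    no ridge and raises.
    """
    dsm = np.asarray(dsm, float)
    if dsm.ndim != 2 or dsm.size == 0:
        raise ValueError("dsm must be a non-empty 2-D raster")
    if np.ptp(dsm) == 0:
        raise ValueError("flat DSM: no ridgeline can be extracted")
    ridge_rows = np.argmax(dsm, axis=0)
    if dsm.shape[1] > 1:
        ridge_rows = median_filter(
            ridge_rows, size=min(_RIDGE_SMOOTH, dsm.shape[1]), mode="nearest"
        )
    rows = np.arange(dsm.shape[0])[:, None]
    mask = np.where(rows <= ridge_rows[None, :], SLOPE_NORTH, SLOPE_SOUTH)
    return mask.astype(np.int8)


@dataclass
class BeltRaster:
    """Integer-coded belt membership raster plus its legend."""

    belt_ids: np.ndarray  # (rows, cols) int32; -1 = no-data
    belts: tuple[BeltDefinition, ...]  # legend: belt id -> definition

    NODATA = -1

    def legend(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "belt_id": range(len(self.belts)),
                "slope": [b.slope for b in self.belts],
                "formation": [b.formation for b in self.belts],
                "alt_lo": [b.alt_lo for b in self.belts],
                "alt_hi": [b.alt_hi for b in self.belts],
            }
        )

    def id_of(self, slope: str, formation: str) -> int:
        for i, b in enumerate(self.belts):
            if b.slope == slope and b.formation == formation:
                return i
        raise KeyError(f"no belt for {formation!r} on the {slope} slope")


def build_constraint_raster(
    dsm: np.ndarray, mask: np.ndarray, table: MabTable
) -> BeltRaster:
    """Per-pixel belt id (belt_at semantics): no-data above the table summit."""
    dsm = np.asarray(dsm, float)
    if dsm.shape != mask.shape:
        raise ValueError("dsm and slope mask are not co-registered")
    belts = list(table.slope_belts("north")) + list(table.slope_belts("south"))
    ids = np.full(dsm.shape, BeltRaster.NODATA, dtype=np.int32)
    offset = 0
    for slope, code in (("north", SLOPE_NORTH), ("south", SLOPE_SOUTH)):
        sl_belts = table.slope_belts(slope)
        edges = np.array([b.alt_lo for b in sl_belts] + [sl_belts[-1].alt_hi])
        sel = mask == code
        e = dsm[sel]
        j = np.searchsorted(edges, e, side="right") - 1
        j[e == edges[-1]] = len(sl_belts) - 1  # summit belt closed at top
        j[(e < edges[0]) | (e > edges[-1])] = BeltRaster.NODATA - offset
        ids[sel] = j + offset
        offset += len(sl_belts)
    ids[ids < 0] = BeltRaster.NODATA
    return BeltRaster(belt_ids=ids, belts=tuple(belts))


def assign_objects(objects: ObjectMap, belts: BeltRaster) -> dict[int, int]:
    """Majority belt per object; ties go to the lower-altitude belt.

    Objects whose majority cover is no-data are omitted from the mapping.
    """
    if objects.labels.shape != belts.belt_ids.shape:
        raise ValueError("objects and belt raster are not co-registered")
    lab = objects.labels.ravel()
    bid = belts.belt_ids.ravel().astype(np.int64) + 1  # shift no-data to 0
    n_b = len(belts.belts) + 1
    counts = np.bincount(lab * n_b + bid, minlength=objects.n_objects * n_b)
    counts = counts.reshape(objects.n_objects, n_b)

    alt_lo = np.array([np.inf] + [b.alt_lo for b in belts.belts])
    # order candidate belts by (count desc, alt_lo asc) via lexsort per object
    out: dict[int, int] = {}
    best = np.argmax(counts, axis=1)
    maxc = counts[np.arange(len(counts)), best]
    for oid in range(objects.n_objects):
        tied = np.flatnonzero(counts[oid] == maxc[oid])
        if len(tied) > 1:
            tied = tied[np.argsort(alt_lo[tied], kind="stable")]
        winner = int(tied[0])
        if winner == 0:  # majority no-data
            continue
        out[oid] = winner - 1
    return out
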