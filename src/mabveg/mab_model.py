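"""Mountain altitudinal belt (MAB) table: the prior knowledge driving stratification.

A :class:`MabTable` holds, per mountain slope, an ordered list of vegetation
belts (formation name + altitude interval).  Intervals are half-open
``[alt_lo, alt_hi)`` so that a shared boundary altitude belongs to exactly one
belt; the summit belt is closed at the top so the peak is covered.

The packaged default table (``taibai_mab``) describes Taibai Mountain with
9 belts on the north slope and 8 on the south slope.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "SLOPES",
    "BeltDefinition",
    "MabTable",
    "SamplingParams",
    "MabValidationError",
    "load_mab_table",
    "default_mab_table",
    "belt_at",
    "formations_near",
    "cluster_count",
]

SLOPES = ("north", "south")


class MabValidationError(ValueError):
    """Raised when a belt table violates its structural invariants."""


def _check_slope(slope: str) -> str:
    if slope not in SLOPES:
        raise ValueError(f"unknown slope {slope!r}; expected one of {SLOPES}")
    return slope


@dataclass(frozen=True)
class BeltDefinition:
    """One vegetation belt: a formation occupying [alt_lo, alt_hi) on a slope."""

    formation: str
    slope: str
    alt_lo: float
    alt_hi: float

    def __post_init__(self) -> None:
        _check_slope(self.slope)
        if not self.formation:
            raise MabValidationError("formation name must be non-empty")
        if self.alt_lo < 0:
            raise MabValidationError(f"alt_lo must be >= 0, got {self.alt_lo}")
        if not self.alt_lo < self.alt_hi:
            raise MabValidationError(
                f"belt {self.formation!r}: alt_lo {self.alt_lo} must be < alt_hi {self.alt_hi}"
            )

    def contains(self, altitude: float, *, top: bool = False) -> bool:
        """Half-open membership test; ``top=True`` closes the upper bound."""
        if top:
            return self.alt_lo <= altitude <= self.alt_hi
        return self.alt_lo <= altitude < self.alt_hi


@dataclass(frozen=True)
class SamplingParams:
    """Tunables of the automatic sample-selection procedure."""

    k_multiplier: int = 3
    near_delta: float = 200.0
    target_n: int = 120
    top_m: int = 5
    balance_tol: float = 1.0
    max_iter: int = 10
    min_keep: int = 10

    def __post_init__(self) -> None:
        if self.k_multiplier < 1:
            raise ValueError("k_multiplier must be >= 1")
        if self.target_n < 1:
            raise ValueError("target_n must be >= 1")
        if not 3 <= self.top_m <= 5:
            raise ValueError("top_m must be in [3, 5]")
        if self.near_delta < 0:
            raise ValueError("near_delta must be >= 0")


@dataclass(frozen=True)
class MabTable:
    """Validated belt table: per-slope ordered, contiguous, non-overlapping belts."""

    belts: tuple[BeltDefinition, ...]
    name: str = "unnamed"
    basal_formation: str = "Basal zone"

    _by_slope: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_slope: dict[str, list[BeltDefinition]] = {}
        for b in self.belts:
            by_slope.setdefault(b.slope, []).append(b)
        if not by_slope:
            raise MabValidationError("table has no belts")
        for slope, belts in by_slope.items():
            belts.sort(key=lambda b: b.alt_lo)
            for lo, hi in zip(belts, belts[1:]):
                if hi.alt_lo < lo.alt_hi:
                    raise MabValidationError(
                        f"{slope} slope: belts {lo.formation!r} [{lo.alt_lo}, {lo.alt_hi}) and "
                        f"{hi.formation!r} [{hi.alt_lo}, {hi.alt_hi}) overlap"
                    )
                if hi.alt_lo > lo.alt_hi:
                    raise MabValidationError(
                        f"{slope} slope: gap between belts {lo.formation!r} "
                        f"[{lo.alt_lo}, {lo.alt_hi}) and {hi.formation!r} [{hi.alt_lo}, {hi.alt_hi})"
                    )
        object.__setattr__(self, "_by_slope", {s: tuple(v) for s, v in by_slope.items()})

    # -- queries ---------------------------------------------------------

    def slope_belts(self, slope: str) -> tuple[BeltDefinition, ...]:
        _check_slope(slope)
        return self._by_slope.get(slope, ())

    def summit(self, slope: str) -> float:
        return self.slope_belts(slope)[-1].alt_hi

    def formations(self, slope: str, *, include_basal: bool = False) -> list[str]:
        """Formation names on a slope in ascending-altitude order."""
        out = [b.formation for b in self.slope_belts(slope)]
        if not include_basal:
            out = [f for f in out if f != self.basal_formation]
        return out

    def vegetation_belts(self, slope: str) -> tuple[BeltDefinition, ...]:
        return tuple(
            b for b in self.slope_belts(slope) if b.formation != self.basal_formation
        )


def load_mab_table(path: str | Path) -> MabTable:
    """Load and validate a belt table from a YAML config file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "slopes" not in raw:
        raise MabValidationError(f"{path}: expected a mapping with a 'slopes' key")
    belts: list[BeltDefinition] = []
    for slope, entries in raw["slopes"].items():
        _check_slope(slope)
        for entry in entries:
            try:
                belts.append(
                    BeltDefinition(
                        formation=str(entry["formation"]),
                        slope=slope,
                        alt_lo=float(entry["alt_lo"]),
                        alt_hi=float(entry["alt_hi"]),
                    )
                )
            except KeyError as exc:  # pragma: no cover - config typo path
                raise MabValidationError(f"{path}: belt entry missing key {exc}") from exc
    return MabTable(
        belts=tuple(belts),
        name=str(raw.get("name", path.stem)),
        basal_formation=str(raw.get("basal_formation", "Basal zone")),
    )


def default_mab_table() -> MabTable:
    """The packaged Taibai Mountain belt table."""
    ref = importlib.resources.files("mabveg.data") / "taibai_mab.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_mab_table(path)


def belt_at(table: MabTable, slope: str, altitude: float) -> BeltDefinition | None:
    """The unique belt containing ``altitude`` on ``slope``, or ``None``.

    Intervals are half-open except the summit belt, which is closed at the top.
    Altitudes below 0 or above the summit return ``None``.
    """
    belts = table.slope_belts(slope)
    for i, belt in enumerate(belts):
        if belt.contains(altitude, top=(i == len(belts) - 1)):
            return belt
    return None


def formations_near(
    table: MabTable,
    slope: str,
    alt_lo: float,
    alt_hi: float,
    near_delta: float = 200.0,
) -> set[str]:
    """Formations on ``slope`` whose belt intersects [alt_lo-delta, alt_hi+delta).

    The basal formation is never counted: it is not a vegetation formation to
    be sampled.  An empty result means the queried interval lies outside the
    table and is an error.
    """
    if not alt_lo < alt_hi:
        raise ValueError("alt_lo must be < alt_hi")
    lo, hi = alt_lo - near_delta, alt_hi + near_delta
    found = {
        b.formation
        for b in table.vegetation_belts(slope)
        if b.alt_lo < hi and lo < b.alt_hi
    }
    if not found:
        raise ValueError(
            f"no vegetation formation near [{alt_lo}, {alt_hi}) on the {slope} slope"
        )
    return found


def cluster_count(n_formations: int, params: SamplingParams = SamplingParams()) -> int:
    """Cluster count used within a belt: k_multiplier x nearby formations."""
    if n_formations < 1:
        raise ValueError("n_formations must be >= 1")
    return params.k_multiplier * n_formations
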