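"""EAT-Lancet reference-diet targets and their energy-proportional rescaling.

The reference diet states, for an adult consuming 2500 kcal/day, a single
mass target (g/day) and a possible range per food group, each flagged as a
*minimum* (encouraged groups: whole grains, vegetables, fruits, fish,
legumes, nuts, unsaturated oils) or a *maximum* (limited groups: tubers,
dairy, red meat, poultry, eggs, saturated fats, added sugars).  Targets for
a child age group are obtained by multiplying every adult value by
mean energy intake / 2500 and rounding to the printed precision (integer
grams; saturated fats to one decimal), rounding halves away from zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MINIMUM",
    "MAXIMUM",
    "AdultTarget",
    "ScaledTarget",
    "ScaledTargetSet",
    "ADULT_TARGETS",
    "REFERENCE_ENERGY_KCAL",
    "scale_targets",
    "meets_target",
    "classify_vs_range",
    "diet_gap_percent",
]

MINIMUM = "minimum"
MAXIMUM = "maximum"

REFERENCE_ENERGY_KCAL = 2500.0


@dataclass(frozen=True)
class AdultTarget:
    """One food group's adult target at 2500 kcal/day."""

    group: str
    target_g: float
    range_lo_g: float | None
    range_hi_g: float | None
    direction: str
    decimals: int = 0  # rounding of scaled values, digits after the point

    def __post_init__(self) -> None:
        if self.direction not in (MINIMUM, MAXIMUM):
            raise ValueError(f"{self.group}: direction must be minimum/maximum")
        if (self.range_lo_g is None) != (self.range_hi_g is None):
            raise ValueError(f"{self.group}: range must have both endpoints or neither")
        if self.range_lo_g is not None:
            if not self.range_lo_g <= self.target_g <= self.range_hi_g:
                raise ValueError(f"{self.group}: target outside its range")


#: Adult reference-diet targets (g/day at 2500 kcal).  Red meat appears both
#: as the aggregate and as its beef+lamb / pork subgroups, each scaled
#: independently.  Whole grains carry no range.  Dairy fats are included in
#: dairy foods via the milk-equivalent route and have no row of their own.
ADULT_TARGETS: tuple[AdultTarget, ...] = (
    AdultTarget("whole_grains", 232, None, None, MINIMUM),
    AdultTarget("tubers", 50, 0, 100, MAXIMUM),
    AdultTarget("vegetables", 300, 200, 600, MINIMUM),
    AdultTarget("fruits", 200, 100, 300, MINIMUM),
    AdultTarget("dairy", 250, 0, 500, MAXIMUM),
    AdultTarget("red_meat", 14, 0, 28, MAXIMUM),
    AdultTarget("beef_lamb", 7, 0, 14, MAXIMUM),
    AdultTarget("pork", 7, 0, 14, MAXIMUM),
    AdultTarget("poultry", 29, 0, 58, MAXIMUM),
    AdultTarget("eggs", 13, 0, 25, MAXIMUM),
    AdultTarget("fish", 28, 0, 100, MINIMUM),
    AdultTarget("legumes", 75, 0, 150, MINIMUM),
    AdultTarget("nuts", 50, 25, 100, MINIMUM),
    AdultTarget("saturated_fats", 11.8, 0, 11.8, MAXIMUM, decimals=1),
    AdultTarget("unsaturated_oils", 40, 20, 80, MINIMUM),
    AdultTarget("added_sugars", 31, 0, 31, MAXIMUM),
)

#: Output row order of the consumption/target tables.
TABLE_ORDER: tuple[str, ...] = tuple(t.group for t in ADULT_TARGETS)


def _round_half_away(x: float, decimals: int) -> float:
    scale = 10.0 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * math.copysign(1.0, x)


@dataclass(frozen=True)
class ScaledTarget:
    group: str
    target_g: float
    range_lo_g: float | None
    range_hi_g: float | None
    direction: str

    @property
    def has_range(self) -> bool:
        return self.range_lo_g is not None


@dataclass(frozen=True)
class ScaledTargetSet:
    """Targets rescaled to one age group's mean energy intake."""

    age_group: str
    mean_energy_kcal: float
    targets: tuple[ScaledTarget, ...]

    def __getitem__(self, group: str) -> ScaledTarget:
        for t in self.targets:
            if t.group == group:
                return t
        raise KeyError(group)

    def __iter__(self):
        return iter(self.targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [t.group for t in self.targets],
                "target_g": [t.target_g for t in self.targets],
                "range_lo_g": [t.range_lo_g for t in self.targets],
                "range_hi_g": [t.range_hi_g for t in self.targets],
                "direction": [t.direction for t in self.targets],
            }
        )


def scale_targets(
    mean_energy_kcal: float,
    adult: Sequence[AdultTarget] = ADULT_TARGETS,
    age_group: str = "",
) -> ScaledTargetSet:
    """Rescale adult targets to an age group's mean energy intake.

    Every target and range endpoint is multiplied by
    ``mean_energy_kcal / 2500`` and rounded per the group's printed
    precision (half away from zero).
    """
    if not mean_energy_kcal > 0:
        raise ValueError(f"mean energy must be > 0 kcal, got {mean_energy_kcal}")
    ratio = mean_energy_kcal / REFERENCE_ENERGY_KCAL

    def conv(v: float | None, decimals: int) -> float | None:
        return None if v is None else _round_half_away(v * ratio, decimals)

    scaled = tuple(
        ScaledTarget(
            group=t.group,
            target_g=conv(t.target_g, t.decimals),
            range_lo_g=conv(t.range_lo_g, t.decimals),
            range_hi_g=conv(t.range_hi_g, t.decimals),
            direction=t.direction,
        )
        for t in adult
    )
    return ScaledTargetSet(age_group=age_group, mean_energy_kcal=mean_energy_kcal, targets=scaled)


def meets_target(usual_intake_g: float, target: ScaledTarget) -> bool:
    """Whether a usual intake meets a single-number target.

    Minimum targets: intake >= target; maximum targets: intake <= target;
    the boundary counts as met.
    """
    if usual_intake_g < 0:
        raise ValueError("usual intake must be >= 0")
    if target.direction == MINIMUM:
        return usual_intake_g >= target.target_g
    return usual_intake_g <= target.target_g


def classify_vs_range(usual_intake_g: float, range_lo: float, range_hi: float) -> str:
    """Classify an intake as below / within / above a target range.

    Both endpoints are inclusive: within iff lo <= intake <= hi.
    """
    if range_lo > range_hi:
        raise ValueError("range_lo must be <= range_hi")
    if usual_intake_g < range_lo:
        return "below"
    if usual_intake_g > range_hi:
        return "above"
    return "within"


def diet_gap_percent(mean_consumption_g: float, scaled_target_g: float) -> float:
    """Mean consumption as a percentage of the scaled target (100 = on target)."""
    if scaled_target_g <= 0:
        raise ValueError("diet gap undefined for non-positive target")
    return 100.0 * mean_consumption_g / scaled_target_g


def load_adult_targets(path: str | Path) -> tuple[AdultTarget, ...]:
    """Read adult targets from a JSON document (list of target objects)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for i, row in enumerate(data):
        try:
            out.append(
                AdultTarget(
                    group=row["group"],
                    target_g=float(row["target_g"]),
                    range_lo_g=None if row.get("range_lo_g") is None else float(row["range_lo_g"]),
                    range_hi_g=None if row.get("range_hi_g") is None else float(row["range_hi_g"]),
                    direction=row["direction"],
                    decimals=int(row.get("decimals", 0)),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"targets file {path}, entry {i}: {exc}") from exc
    return tuple(out)


def dump_adult_targets(targets: Iterable[AdultTarget], path: str | Path) -> None:
    rows = [
        {
            "group": t.group,
            "target_g": t.target_g,
            "range_lo_g": t.range_lo_g,
            "range_hi_g": t.range_hi_g,
            "direction": t.direction,
            "decimals": t.decimals,
        }
        for t in targets
    ]
    Path(path).write_text(json.dumps(rows, indent=2) + "\n", encoding="utf-8")
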