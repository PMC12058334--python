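"""Flow-state labels and the per-diameter velocity ranges that define them.

Four flow regimes are distinguished, mimicking an occlusion series in an
artificial artery: full occlusion (ZERO), restricted pre-stroke flow (LOW),
moderate flow (MEDIUM) and near-fully-open flow (HIGH).  Each regime maps to
a velocity interval (cm/s) that depends on the vessel's inner diameter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class FlowCondition(enum.IntEnum):
    """Ordered flow-state label; integer value doubles as the class index."""

    ZERO = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @property
    def short(self) -> str:
        return self.name.lower()


#: velocity intervals (cm/s) per vessel inner diameter (mm).  ZERO is the
#: degenerate interval {0}.
VELOCITY_RANGES: dict[float, dict[FlowCondition, tuple[float, float]]] = {
    3.0: {
        FlowCondition.ZERO: (0.0, 0.0),
        FlowCondition.LOW: (4.2, 6.8),
        FlowCondition.MEDIUM: (27.0, 54.0),
        FlowCondition.HIGH: (83.0, 111.0),
    },
    6.0: {
        FlowCondition.ZERO: (0.0, 0.0),
        FlowCondition.LOW: (2.7, 3.8),
        FlowCondition.MEDIUM: (21.0, 39.0),
        FlowCondition.HIGH: (61.0, 78.0),
    },
}


@dataclass(frozen=True)
class ConditionSpec:
    """One flow condition for one vessel diameter."""

    label: FlowCondition
    diameter_mm: float

    @property
    def velocity_range(self) -> tuple[float, float]:
        try:
            return VELOCITY_RANGES[self.diameter_mm][self.label]
        except KeyError:
            raise ValueError(
                f"no velocity range defined for diameter {self.diameter_mm} mm"
            ) from None

    @property
    def midpoint(self) -> float:
        lo, hi = self.velocity_range
        return 0.5 * (lo + hi)


def velocity_midpoints(diameter_mm: float) -> dict[FlowCondition, float]:
    """Midpoint velocity (cm/s) of each condition's range for a diameter."""
    return {
        c: ConditionSpec(c, diameter_mm).midpoint
        for c in FlowCondition
    }
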