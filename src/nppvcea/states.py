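"""Health states and strategy arms of the COPD progression model.

Disease progression is tracked over four states: a stable period (no
exacerbation), a nonserious exacerbation period (an event managed by
adjusting medication), a serious exacerbation period (an event leading to
hospitalization) and death, which is absorbing.
"""

from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    STABLE = "stable"
    NONSERIOUS = "nonserious"
    SERIOUS = "serious"
    DEATH = "death"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical state ordering used for every vector / matrix in the package.
STATE_ORDER: tuple[HealthState, ...] = (
    HealthState.STABLE,
    HealthState.NONSERIOUS,
    HealthState.SERIOUS,
    HealthState.DEATH,
)

ALIVE_STATES: tuple[HealthState, ...] = STATE_ORDER[:3]

STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATE_ORDER)}

#: The two management strategies compared by the model.
ARM_IOT = "iot"
ARM_STANDARD = "standard"
ARMS: tuple[str, str] = (ARM_IOT, ARM_STANDARD)
#: Marker for parameters shared by both arms (e.g. the serious-state row).
ARM_BOTH = "both"
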