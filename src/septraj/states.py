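"""Disease-state space and transition structure.

Patients are staged daily into one of three transient severity states --
at risk of organ failure, limited organ failure, multiple-organ failure
(MOF) -- and can leave the ICU through two absorbing states, discharge
alive or death.  Direct jumps that skip a severity level (at risk <->
MOF, at risk -> death, MOF -> discharge) are structural zeros: their
instantaneous rates are fixed at zero and never estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum


class DiseaseState(IntEnum):
    """Five-state space; DISCHARGED and DEAD are absorbing."""

    AT_RISK = 1
    LIMITED_OF = 2
    MOF = 3
    DISCHARGED = 4
    DEAD = 5

    @property
    def is_absorbing(self) -> bool:
        return self in (DiseaseState.DISCHARGED, DiseaseState.DEAD)

    @property
    def is_transient(self) -> bool:
        return not self.is_absorbing


TRANSIENT_STATES = (DiseaseState.AT_RISK, DiseaseState.LIMITED_OF, DiseaseState.MOF)
ABSORBING_STATES = (DiseaseState.DISCHARGED, DiseaseState.DEAD)

#: Transitions with estimable intensities (1-based state pairs).
DEFAULT_ALLOWED: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 4),
    (2, 1), (2, 3), (2, 4), (2, 5),
    (3, 2), (3, 5),
)

#: Pairs whose instantaneous rate is fixed at zero by design.
STRUCTURAL_ZEROS: tuple[tuple[int, int], ...] = ((1, 3), (1, 5), (3, 1), (3, 4))


@dataclass(frozen=True)
class TransitionStructure:
    """Allowed instantaneous transitions of the multi-state model.

    ``allowed`` lists ordered (from, to) pairs of 1-based state codes.
    Absorbing states never appear as origins.
    """

    allowed: tuple[tuple[int, int], ...] = DEFAULT_ALLOWED
    n_states: int = 5
    absorbing: tuple[int, ...] = field(
        default=tuple(int(s) for s in ABSORBING_STATES)
    )

    def __post_init__(self) -> None:
        for i, j in self.allowed:
            if i in self.absorbing:
                raise ValueError(f"absorbing state {i} cannot have exits")
            if i == j:
                raise ValueError("self-transitions are not intensities")
            if not (1 <= i <= self.n_states and 1 <= j <= self.n_states):
                raise ValueError(f"transition ({i},{j}) outside state space")

    @property
    def n_transitions(self) -> int:
        return len(self.allowed)

    def index(self, i: int, j: int) -> int:
        """Position of transition i->j in the parameter ordering."""
        return self.allowed.index((i, j))

    def labels(self) -> list[str]:
        return [f"{i}->{j}" for i, j in self.allowed]
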