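"""Receptor states of the desensitization scheme.

The concatemer fixes the subunit order beta2-alpha1-beta2-alpha1-gamma2
(SU1..SU5).  The reduced schemes let only SU3, SU4 and SU5 desensitize;
a gated receptor is then described by the subset of those subunits that
sit in their desensitized conformation (AO = none, AD_345 = all three).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Tuple


class SubunitID(enum.Enum):
    """The five subunits of the concatemeric receptor, in linker order."""

    SU1 = 1
    SU2 = 2
    SU3 = 3
    SU4 = 4
    SU5 = 5

    @property
    def role(self) -> str:
        """Subunit class: beta2 for SU1/SU3, alpha1 for SU2/SU4, gamma2 for SU5."""
        return {1: "beta2", 2: "alpha1", 3: "beta2", 4: "alpha1", 5: "gamma2"}[self.value]

    def __lt__(self, other: "SubunitID") -> bool:
        return self.value < other.value

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


#: The desensitizable subunits of the reduced (10-state) schemes.
REDUCED_DESENSITIZABLE: FrozenSet[SubunitID] = frozenset(
    {SubunitID.SU3, SubunitID.SU4, SubunitID.SU5}
)

ALL_SUBUNITS: FrozenSet[SubunitID] = frozenset(SubunitID)


@dataclass(frozen=True)
class DesensPattern:
    """Subset of desensitizable subunits currently in the desensitized conformation."""

    desensitized: FrozenSet[SubunitID]

    def __post_init__(self) -> None:
        object.__setattr__(self, "desensitized", frozenset(self.desensitized))

    @property
    def sorted_subunits(self) -> Tuple[SubunitID, ...]:
        return tuple(sorted(self.desensitized, key=lambda s: s.value))

    def with_flip(self, su: SubunitID) -> "DesensPattern":
        """Toggle one subunit's desensitized flag."""
        if su in self.desensitized:
            return DesensPattern(self.desensitized - {su})
        return DesensPattern(self.desensitized | {su})

    @property
    def label(self) -> str:
        if not self.desensitized:
            return "AO"
        return "AD" + "".join(str(s.value) for s in self.sorted_subunits)

    def sort_key(self) -> Tuple[int, Tuple[int, ...]]:
        """Canonical order: by cardinality, then lexicographic subunit labels."""
        return (len(self.desensitized), tuple(s.value for s in self.sorted_subunits))

    def __len__(self) -> int:
        return len(self.desensitized)

    def __contains__(self, su: SubunitID) -> bool:
        return su in self.desensitized


class StateTag(enum.Enum):
    R = "R"          # resting, unliganded
    AR = "AR"        # agonist bound, closed
    GATED = "GATED"  # agonist bound, gated; carries a desensitization pattern
    DFAST = "Dfast"  # concerted variant only: fast desensitized state
    DSLOW = "Dslow"  # concerted variant only: slow desensitized state


@dataclass(frozen=True)
class ReceptorState:
    """One vertex of the kinetic scheme.

    ``R`` and ``AR`` are never conducting.  A ``GATED`` state carries the
    per-subunit desensitization pattern; whether it conducts is decided by
    the model variant's conductance rule, stamped on the state at scheme
    build time.
    """

    tag: StateTag
    pattern: DesensPattern | None = None
    conducting: bool = False

    def __post_init__(self) -> None:
        if self.tag is StateTag.GATED and self.pattern is None:
            raise ValueError("GATED state requires a desensitization pattern")
        if self.tag is not StateTag.GATED:
            if self.pattern is not None:
                raise ValueError(f"{self.tag.name} state carries no pattern")
            if self.conducting:
                raise ValueError(f"{self.tag.name} state cannot conduct")

    @property
    def label(self) -> str:
        if self.tag is StateTag.GATED:
            return self.pattern.label
        return self.tag.value

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        star = "*" if self.conducting else ""
        return f"<{self.label}{star}>"


def resting() -> ReceptorState:
    return ReceptorState(StateTag.R)


def bound() -> ReceptorState:
    return ReceptorState(StateTag.AR)


def gated(subunits: Iterable[SubunitID] = (), conducting: bool = False) -> ReceptorState:
    return ReceptorState(StateTag.GATED, DesensPattern(frozenset(subunits)), conducting)
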