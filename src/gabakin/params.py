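"""Rate parameters, mutation profiles and model variants.

Units: second-order binding in M^-1 s^-1, every other rate in s^-1,
agonist concentrations in molar.  Multipliers and couplings are
dimensionless.  Gating efficacy E = beta/alpha is derived, never stored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, Mapping

from .states import SubunitID


class ModelVariant(enum.Enum):
    """The five kinetic-model variants.

    CONCERTED : pseudo-symmetric fast/slow desensitized states off AO.
    I         : one desensitized subunit shuts the pore; mutations scale
                desensitization entry only.
    II        : two desensitized subunits required to shut the pore;
                mutations may scale entry and recovery.
    II_BETA   : model II plus the SU3-mutation cross-effect on SU4 rates.
    III       : model II-beta plus gamma/epsilon inter-subunit couplings.
    """

    CONCERTED = "concerted"
    I = "I"  # noqa: E741 - the paper-facing roman numeral
    II = "II"
    II_BETA = "II-beta"
    III = "III"


#: Variants whose conductance rule tolerates one desensitized subunit.
TWO_SUBUNIT_OCCLUSION = {ModelVariant.II, ModelVariant.II_BETA, ModelVariant.III}

#: Variants in which the SU3 mutation also rescales SU4 rates (c34).
CROSS_EFFECT_VARIANTS = {ModelVariant.II_BETA, ModelVariant.III}


@dataclass(frozen=True)
class RateParameters:
    """Wild-type rate constants of the subunit-resolved scheme.

    Binding/gating defaults put activation (k_on*[A] ~ 1e4 s^-1 at 10 mM,
    beta/alpha = 200/20) far faster than second-scale desensitization, so
    the decay observables are insensitive to their exact values.

    ``delta*`` rates govern per-subunit desensitization entry (+) and
    recovery (-): SU3 has its own pair, SU4 and SU5 share one pair.
    ``gamma_coupling``/``epsilon_coupling`` are the model III couplings:
    desensitization of SU3 accelerates desensitization of SU4 by gamma
    (and vice versa); desensitization of SU4 slows recovery of SU5 by
    epsilon (and vice versa).

    ``conc_*`` are the four rates of the concerted variant: entry/exit of
    its fast and slow desensitized states.
    """

    k_on: float = 1.0e6          # M^-1 s^-1
    k_off: float = 1.0e3         # s^-1
    beta: float = 200.0          # s^-1, channel opening
    alpha: float = 20.0          # s^-1, channel closing
    delta3_plus: float = 0.04    # s^-1, SU3 desensitization
    delta3_minus: float = 0.01   # s^-1, SU3 recovery
    delta_plus: float = 0.14     # s^-1, SU4/SU5 desensitization
    delta_minus: float = 0.15    # s^-1, SU4/SU5 recovery
    gamma_coupling: float = 1.0  # dimensionless >= 1
    epsilon_coupling: float = 1.0
    conc_fast_plus: float = 0.2    # s^-1, concerted fast-state entry
    conc_fast_minus: float = 0.15  # s^-1, concerted fast-state exit
    conc_slow_plus: float = 0.05   # s^-1, concerted slow-state entry
    conc_slow_minus: float = 0.006  # s^-1, concerted slow-state exit

    def __post_init__(self) -> None:
        for name in (
            "k_on", "k_off", "beta", "alpha",
            "delta3_plus", "delta3_minus", "delta_plus", "delta_minus",
            "conc_fast_plus", "conc_fast_minus", "conc_slow_plus", "conc_slow_minus",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"rate {name} must be positive, got {getattr(self, name)}")
        if self.gamma_coupling < 1 or self.epsilon_coupling < 1:
            raise ValueError("couplings gamma and epsilon must be >= 1")

    @property
    def efficacy(self) -> float:
        """Gating efficacy E = beta/alpha."""
        return self.beta / self.alpha

    def evolve(self, **changes: float) -> "RateParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class ConcertedFactors:
    """Per-mutated-subunit rate multipliers of the concerted variant.

    ``gamma_f``/``epsilon_f`` scale entry/exit of the fast desensitized
    state, ``gamma_s``/``epsilon_s`` entry/exit of the slow one.  Factors
    of subunits mutated together multiply (energy-additive combination).
    """

    gamma_f: float = 1.0
    epsilon_f: float = 1.0
    gamma_s: float = 1.0
    epsilon_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_f", "epsilon_f", "gamma_s", "epsilon_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"concerted factor {name} must be positive")


@dataclass(frozen=True)
class MutationProfile:
    """Which subunits carry the M3-5' valine mutation, and its rate effects.

    ``c3..c5`` multipliers scale the mutated subunit's own desensitization
    (+) and recovery (-) rates; ``c34`` is the cross-effect of the SU3
    mutation on SU4's rates (models II-beta and III only).  Multipliers of
    unmutated subunits are forced to 1 so that profiles compose cleanly.
    """

    mutated: FrozenSet[SubunitID] = frozenset()
    c3_plus: float = 1.0
    c3_minus: float = 1.0
    c4_plus: float = 1.0
    c4_minus: float = 1.0
    c5_plus: float = 1.0
    c5_minus: float = 1.0
    c34_plus: float = 1.0
    c34_minus: float = 1.0
    concerted_factors: Mapping[SubunitID, ConcertedFactors] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutated", frozenset(self.mutated))
        object.__setattr__(self, "concerted_factors", dict(self.concerted_factors))
        for name in ("c3_plus", "c3_minus", "c4_plus", "c4_minus",
                     "c5_plus", "c5_minus", "c34_plus", "c34_minus"):
            if not getattr(self, name) > 0:
                raise ValueError(f"multiplier {name} must be positive")
        # Unmutated subunits must carry unit multipliers.
        for su, plus, minus in (
            (SubunitID.SU3, "c3_plus", "c3_minus"),
            (SubunitID.SU4, "c4_plus", "c4_minus"),
            (SubunitID.SU5, "c5_plus", "c5_minus"),
        ):
            if su not in self.mutated:
                if getattr(self, plus) != 1.0 or getattr(self, minus) != 1.0:
                    raise ValueError(f"{su.name} is not mutated; its multipliers must be 1")
        if SubunitID.SU3 not in self.mutated and (
            self.c34_plus != 1.0 or self.c34_minus != 1.0
        ):
            raise ValueError("c34 multipliers require the SU3 mutation")
        extra = set(self.concerted_factors) - set(self.mutated)
        if extra:
            raise ValueError(f"concerted factors given for unmutated subunits: {extra}")

    @property
    def is_wild_type(self) -> bool:
        return not self.mutated

    def multiplier(self, su: SubunitID, entry: bool) -> float:
        """Own-subunit multiplier for desensitization entry or recovery."""
        table: Dict[SubunitID, tuple] = {
            SubunitID.SU3: (self.c3_plus, self.c3_minus),
            SubunitID.SU4: (self.c4_plus, self.c4_minus),
            SubunitID.SU5: (self.c5_plus, self.c5_minus),
        }
        if su not in table:
            return 1.0
        plus, minus = table[su]
        return plus if entry else minus

    def concerted_product(self, fast: bool, entry: bool) -> float:
        """Product of concerted factors over mutated subunits for one rate."""
        out = 1.0
        for su in self.mutated:
            f = self.concerted_factors.get(su, ConcertedFactors())
            if fast:
                out *= f.gamma_f if entry else f.epsilon_f
            else:
                out *= f.gamma_s if entry else f.epsilon_s
        return out


WILD_TYPE = MutationProfile()


def profile_from_multipliers(
    mutated: Iterable[SubunitID],
    *,
    c3: tuple[float, float] = (1.0, 1.0),
    c4: tuple[float, float] = (1.0, 1.0),
    c5: tuple[float, float] = (1.0, 1.0),
    c34: tuple[float, float] = (1.0, 1.0),
    concerted: Mapping[SubunitID, ConcertedFactors] | None = None,
) -> MutationProfile:
    """Assemble a profile for a construct from per-subunit multiplier pairs.

    Multipliers of subunits absent from ``mutated`` are dropped (forced to
    1), which is how single-mutant fits are combined into predictions for
    combination constructs.
    """
    mutated = frozenset(mutated)
    kw = {}
    if SubunitID.SU3 in mutated:
        kw["c3_plus"], kw["c3_minus"] = c3
        kw["c34_plus"], kw["c34_minus"] = c34
    if SubunitID.SU4 in mutated:
        kw["c4_plus"], kw["c4_minus"] = c4
    if SubunitID.SU5 in mutated:
        kw["c5_plus"], kw["c5_minus"] = c5
    conc = {su: f for su, f in (concerted or {}).items() if su in mutated}
    return MutationProfile(mutated=mutated, concerted_factors=conc, **kw)
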