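"""State enumeration and generator-matrix assembly for all model variants.

The scheme couples a linear activation limb (R <-> AR <-> AO, single
binding step, no unliganded opening) to a hypercube of gated states in
which each desensitizable subunit flips independently between its active
and desensitized conformation.  The generator (Q-matrix) holds the net
flow rates: off-diagonal Q[i, j] is the i -> j rate, rows sum to zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

import numpy as np

from .params import (
    CROSS_EFFECT_VARIANTS,
    TWO_SUBUNIT_OCCLUSION,
    ModelVariant,
    MutationProfile,
    RateParameters,
)
from .states import (
    REDUCED_DESENSITIZABLE,
    DesensPattern,
    ReceptorState,
    StateTag,
    SubunitID,
)


class InvalidTransitionError(ValueError):
    """Raised when two states are not connected by one elementary event."""


def enumerate_states(
    desensitizable: Iterable[SubunitID] = REDUCED_DESENSITIZABLE,
) -> List[ReceptorState]:
    """Enumerate the 2 + 2^n receptor states in canonical order.

    Order: R, AR, then gated states by increasing number of desensitized
    subunits and lexicographic subunit label (AO first).  Conducting flags
    are left False here; :func:`build_scheme` stamps them according to the
    variant's conductance rule.
    """
    subunits = sorted(set(desensitizable), key=lambda s: s.value)
    states = [ReceptorState(StateTag.R), ReceptorState(StateTag.AR)]
    patterns = [
        DesensPattern(frozenset(combo))
        for r in range(len(subunits) + 1)
        for combo in itertools.combinations(subunits, r)
    ]
    patterns.sort(key=DesensPattern.sort_key)
    states.extend(ReceptorState(StateTag.GATED, p) for p in patterns)
    return states


def concerted_states() -> List[ReceptorState]:
    """The five pseudo-symmetric states of the concerted variant."""
    return [
        ReceptorState(StateTag.R),
        ReceptorState(StateTag.AR),
        ReceptorState(StateTag.GATED, DesensPattern(frozenset())),
        ReceptorState(StateTag.DFAST),
        ReceptorState(StateTag.DSLOW),
    ]


def conductance_rule(state: ReceptorState, variant: ModelVariant) -> bool:
    """Does ``state`` conduct under ``variant``?

    CONCERTED and model I: only the fully open state AO conducts (a single
    desensitized subunit is enough to shut the pore).  Models II, II-beta
    and III: gated states with at most one desensitized subunit conduct
    (two desensitized subunits are required to occlude the pore).
    """
    if state.tag is not StateTag.GATED:
        return False
    n_desens = len(state.pattern)
    if variant in TWO_SUBUNIT_OCCLUSION:
        return n_desens <= 1
    return n_desens == 0


def _flip_between(a: ReceptorState, b: ReceptorState) -> Tuple[SubunitID, bool]:
    """The single subunit flipping between two gated states, and whether it
    is a desensitization entry (True) or a recovery (False)."""
    pa, pb = a.pattern.desensitized, b.pattern.desensitized
    gained, lost = pb - pa, pa - pb
    if len(gained) == 1 and not lost:
        return next(iter(gained)), True
    if len(lost) == 1 and not gained:
        return next(iter(lost)), False
    raise InvalidTransitionError(
        f"states {a.label} and {b.label} differ by more than one subunit flip"
    )


def effective_rate(
    from_state: ReceptorState,
    to_state: ReceptorState,
    params: RateParameters,
    profile: MutationProfile,
    variant: ModelVariant,
    *,
    agonist_conc: float = 0.01,
) -> float:
    """Rate (s^-1) of one elementary transition under variant/mutation rules.

    Base rates: ``k_on*[A]`` (R->AR), ``k_off``, ``beta``, ``alpha``,
    ``delta3+/-`` for SU3 and the shared ``delta+/-`` for SU4/SU5.  Mutated
    subunits scale their own rates by ``c_i+`` (entry; all subunit models)
    and ``c_i-`` (recovery; models II/II-beta/III).  In models II-beta and
    III a mutated SU3 additionally rescales SU4's rates by ``c34+/-``.  The
    model III couplings apply to wild type and mutant alike: SU3 and SU4
    mutually accelerate each other's desensitization by ``gamma``; SU4 and
    SU5 mutually slow each other's recovery by ``epsilon``.
    """
    ft, tt = from_state.tag, to_state.tag

    # Activation limb, shared by every variant.
    if ft is StateTag.R and tt is StateTag.AR:
        return params.k_on * agonist_conc
    if ft is StateTag.AR and tt is StateTag.R:
        return params.k_off
    gated_open = (
        lambda s: s.tag is StateTag.GATED and len(s.pattern) == 0
    )
    if ft is StateTag.AR and gated_open(to_state):
        return params.beta
    if gated_open(from_state) and tt is StateTag.AR:
        return params.alpha

    if variant is ModelVariant.CONCERTED:
        return _concerted_rate(from_state, to_state, params, profile)

    if ft is not StateTag.GATED or tt is not StateTag.GATED:
        raise InvalidTransitionError(
            f"no elementary event connects {from_state.label} and {to_state.label}"
        )

    su, entry = _flip_between(from_state, to_state)
    if su is SubunitID.SU3:
        rate = params.delta3_plus if entry else params.delta3_minus
    else:
        rate = params.delta_plus if entry else params.delta_minus

    # Own-subunit mutation multipliers.
    if su in profile.mutated:
        if entry:
            rate *= profile.multiplier(su, entry=True)
        elif variant is not ModelVariant.I:
            rate *= profile.multiplier(su, entry=False)
    # Cross-effect of the SU3 mutation on SU4 (models II-beta and III).
    if (
        variant in CROSS_EFFECT_VARIANTS
        and su is SubunitID.SU4
        and SubunitID.SU3 in profile.mutated
    ):
        rate *= profile.c34_plus if entry else profile.c34_minus

    # Model III inter-subunit couplings, mutation-independent.
    if variant is ModelVariant.III:
        neighbours = from_state.pattern.desensitized
        if entry:
            if su is SubunitID.SU3 and SubunitID.SU4 in neighbours:
                rate *= params.gamma_coupling
            if su is SubunitID.SU4 and SubunitID.SU3 in neighbours:
                rate *= params.gamma_coupling
        else:
            others = neighbours - {su}
            if su is SubunitID.SU5 and SubunitID.SU4 in others:
                rate /= params.epsilon_coupling
            if su is SubunitID.SU4 and SubunitID.SU5 in others:
                rate /= params.epsilon_coupling
    return rate


def _concerted_rate(
    from_state: ReceptorState,
    to_state: ReceptorState,
    params: RateParameters,
    profile: MutationProfile,
) -> float:
    ft, tt = from_state.tag, to_state.tag
    open_tag = StateTag.GATED
    if ft is open_tag and tt is StateTag.DFAST:
        return params.conc_fast_plus * profile.concerted_product(fast=True, entry=True)
    if ft is StateTag.DFAST and tt is open_tag:
        return params.conc_fast_minus * profile.concerted_product(fast=True, entry=False)
    if ft is open_tag and tt is StateTag.DSLOW:
        return params.conc_slow_plus * profile.concerted_product(fast=False, entry=True)
    if ft is StateTag.DSLOW and tt is open_tag:
        return params.conc_slow_minus * profile.concerted_product(fast=False, entry=False)
    raise InvalidTransitionError(
        f"no elementary event connects {from_state.label} and {to_state.label}"
    )


@dataclass(frozen=True)
class Transition:
    source: int
    target: int
    rate: float
    descriptor: str


@dataclass
class KineticScheme:
    """States, transitions and generator matrix of one built model.

    ``generator[i, j]`` (i != j) is the state-i -> state-j rate in s^-1;
    diagonal entries make every row sum to zero.  The binding rate scales
    linearly with agonist concentration; :meth:`generator_at` rebuilds the
    matrix for another concentration without touching any other entry.
    """

    variant: ModelVariant
    params: RateParameters
    profile: MutationProfile
    agonist_conc: float
    states: List[ReceptorState]
    transitions: List[Transition]
    generator: np.ndarray = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> List[str]:
        return [s.label for s in self.states]

    @property
    def conducting_mask(self) -> np.ndarray:
        return np.array([s.conducting for s in self.states], dtype=bool)

    def state_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no state labelled {label!r}") from None

    def generator_at(self, agonist_conc: float) -> np.ndarray:
        """Generator with the binding rate rescaled to ``agonist_conc``."""
        if agonist_conc == self.agonist_conc:
            return self.generator
        q = self.generator.copy()
        i_r = self.state_index("R")
        i_ar = self.state_index("AR")
        old = q[i_r, i_ar]
        new = self.params.k_on * agonist_conc
        q[i_r, i_ar] = new
        q[i_r, i_r] += old - new
        return q

    def edge_list(self) -> str:
        """Plain-text edge list: from_state, to_state, rate, descriptor."""
        lines = ["from_state\tto_state\trate_per_s\tdescriptor"]
        for tr in self.transitions:
            lines.append(
                f"{self.states[tr.source].label}\t{self.states[tr.target].label}"
                f"\t{tr.rate:.10g}\t{tr.descriptor}"
            )
        return "\n".join(lines) + "\n"


def _describe(a: ReceptorState, b: ReceptorState) -> str:
    pair = (a.tag, b.tag)
    if pair == (StateTag.R, StateTag.AR):
        return "binding"
    if pair == (StateTag.AR, StateTag.R):
        return "unbinding"
    if a.tag is StateTag.AR:
        return "opening"
    if b.tag is StateTag.AR:
        return "closing"
    if b.tag is StateTag.DFAST or b.tag is StateTag.DSLOW:
        return f"{b.tag.value}_entry"
    if a.tag is StateTag.DFAST or a.tag is StateTag.DSLOW:
        return f"{a.tag.value}_exit"
    su, entry = _flip_between(a, b)
    return f"{su.name}_{'desensitization' if entry else 'recovery'}"


def build_scheme(
    variant: ModelVariant,
    params: RateParameters,
    profile: MutationProfile = MutationProfile(),
    agonist_conc: float = 0.01,
    desensitizable: Iterable[SubunitID] = REDUCED_DESENSITIZABLE,
) -> KineticScheme:
    """Assemble the kinetic scheme for one variant/parameter/mutant triple.

    Subunit variants get the 2 + 2^n hypercube scheme over
    ``desensitizable`` (default {SU3, SU4, SU5}); CONCERTED gets the
    five-state scheme {R, AR, AO, Dfast, Dslow} with both desensitized
    states branching off AO.
    """
    if variant is ModelVariant.CONCERTED:
        raw_states = concerted_states()
    else:
        raw_states = enumerate_states(desensitizable)
    states = [
        ReceptorState(s.tag, s.pattern, conductance_rule(s, variant))
        for s in raw_states
    ]

    # Adjacency: activation limb plus single-subunit flips / branch entries.
    n = len(states)
    transitions: List[Transition] = []
    q = np.zeros((n, n))
    for i, j in itertools.permutations(range(n), 2):
        a, b = states[i], states[j]
        if not _adjacent(a, b):
            continue
        rate = effective_rate(
            a, b, params, profile, variant, agonist_conc=agonist_conc
        )
        q[i, j] = rate
        transitions.append(Transition(i, j, rate, _describe(a, b)))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return KineticScheme(
        variant=variant,
        params=params,
        profile=profile,
        agonist_conc=agonist_conc,
        states=states,
        transitions=transitions,
        generator=q,
    )


def _adjacent(a: ReceptorState, b: ReceptorState) -> bool:
    tags = (a.tag, b.tag)
    gated_open = lambda s: s.tag is StateTag.GATED and len(s.pattern) == 0
    if set(tags) == {StateTag.R, StateTag.AR}:
        return True
    if a.tag is StateTag.AR and gated_open(b) or b.tag is StateTag.AR and gated_open(a):
        return True
    if StateTag.DFAST in tags or StateTag.DSLOW in tags:
        other = b if a.tag in (StateTag.DFAST, StateTag.DSLOW) else a
        return gated_open(other)
    if a.tag is StateTag.GATED and b.tag is StateTag.GATED:
        return len(a.pattern.desensitized ^ b.pattern.desensitized) == 1
    return False


@dataclass(frozen=True)
class CycleViolation:
    labels: Tuple[str, str, str, str]
    forward_product: float
    backward_product: float
    relative_error: float


@dataclass
class DetailedBalanceReport:
    n_cycles: int
    violations: List[CycleViolation]

    @property
    def ok(self) -> bool:
        return not self.violations


def check_detailed_balance(
    scheme: KineticScheme, rel_tol: float = 1e-9
) -> DetailedBalanceReport:
    """Check detailed balance on every 4-cycle of the desensitization layer.

    For each gated pattern ``p`` and subunit pair {i, j} outside ``p``, the
    two orders of flipping i and j form a 4-cycle; its clockwise and
    counter-clockwise rate products must agree.  Rates are read back from
    the generator so that manual perturbations are caught.
    """
    gated = {
        s.pattern.desensitized: idx
        for idx, s in enumerate(scheme.states)
        if s.tag is StateTag.GATED
    }
    if not gated:
        return DetailedBalanceReport(0, [])
    subunits = sorted(
        set().union(*gated.keys()) if any(gated.keys()) else set(),
        key=lambda s: s.value,
    )
    q = scheme.generator
    violations: List[CycleViolation] = []
    n_cycles = 0
    for base in gated:
        for i, j in itertools.combinations(subunits, 2):
            if i in base or j in base:
                continue
            a = gated[base]
            b = gated[frozenset(base | {i})]
            c = gated[frozenset(base | {i, j})]
            d = gated[frozenset(base | {j})]
            n_cycles += 1
            fwd = q[a, b] * q[b, c] * q[c, d] * q[d, a]
            bwd = q[a, d] * q[d, c] * q[c, b] * q[b, a]
            scale = max(abs(fwd), abs(bwd), 1e-300)
            rel = abs(fwd - bwd) / scale
            if rel > rel_tol:
                violations.append(
                    CycleViolation(
                        (
                            scheme.states[a].label,
                            scheme.states[b].label,
                            scheme.states[c].label,
                            scheme.states[d].label,
                        ),
                        fwd,
                        bwd,
                        rel,
                    )
                )
    return DetailedBalanceReport(n_cycles, violations)
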