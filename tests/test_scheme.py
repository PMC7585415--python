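"""State enumeration, rate rules and generator-matrix structure."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gabakin.params import (
    ConcertedFactors,
    ModelVariant,
    MutationProfile,
    RateParameters,
    profile_from_multipliers,
)
from gabakin.scheme import (
    InvalidTransitionError,
    build_scheme,
    check_detailed_balance,
    conductance_rule,
    effective_rate,
    enumerate_states,
)
from gabakin.states import SubunitID, gated

SU = SubunitID
PARAMS = RateParameters()
PARAMS_III = RateParameters(gamma_coupling=100.0, epsilon_coupling=10.0)

ALL_PROFILES = [
    _mut for r in range(4) for _mut in itertools.combinations((SU.SU3, SU.SU4, SU.SU5), r)
]


def make_profile(mutated, variant):
    """A nontrivial profile exercising every licensed multiplier."""
    kw = {}
    if variant is ModelVariant.I:
        kw = dict(c3=(5.0, 1.0), c4=(7.0, 1.0), c5=(7.0, 1.0))
    elif variant is ModelVariant.III:
        kw = dict(c3=(5.0, 2.0), c4=(7.0, 1.0), c5=(7.0, 1.0), c34=(2.0, 3.0))
    else:
        kw = dict(c3=(5.0, 2.0), c4=(7.0, 3.0), c5=(7.0, 3.0), c34=(2.0, 3.0))
    conc = {su: ConcertedFactors(2.0, 3.0, 4.0, 5.0) for su in mutated}
    return profile_from_multipliers(mutated, concerted=conc, **kw)


class TestEnumeration:
    @pytest.mark.parametrize(
        "subunits, expected",
        [
            ({SU.SU3, SU.SU4, SU.SU5}, 10),
            (set(SubunitID), 34),
            (set(), 3),
        ],
    )
    def test_state_counts(self, subunits, expected):
        assert len(enumerate_states(subunits)) == expected

    @settings(deadline=None, max_examples=32, derandomize=True)
    @given(st.sets(st.sampled_from(list(SubunitID))))
    def test_count_is_two_plus_power_of_two(self, subunits):
        states = enumerate_states(subunits)
        assert len(states) == 2 + 2 ** len(subunits)
        # no duplicates, deterministic order
        labels = [s.label for s in states]
        assert len(set(labels)) == len(labels)
        assert labels == [s.label for s in enumerate_states(subunits)]

    def test_canonical_order(self):
        labels = [s.label for s in enumerate_states()]
        assert labels[:3] == ["R", "AR", "AO"]
        assert labels[3:] == ["AD3", "AD4", "AD5", "AD34", "AD35", "AD45", "AD345"]


class TestConductance:
    @pytest.mark.parametrize(
        "pattern, variant, expected",
        [
            ({SU.SU4}, ModelVariant.I, False),
            ({SU.SU4}, ModelVariant.II, True),
            ({SU.SU4}, ModelVariant.III, True),
            ({SU.SU4, SU.SU5}, ModelVariant.II, False),
            ((), ModelVariant.I, True),
            ((), ModelVariant.CONCERTED, True),
        ],
    )
    def test_rule(self, pattern, variant, expected):
        assert conductance_rule(gated(pattern), variant) is expected

    def test_closed_states_never_conduct(self):
        for variant in ModelVariant:
            scheme = build_scheme(variant, PARAMS)
            assert not scheme.states[scheme.state_index("R")].conducting
            assert not scheme.states[scheme.state_index("AR")].conducting

    def test_model_I_single_conducting_state(self):
        scheme = build_scheme(ModelVariant.I, PARAMS)
        assert int(scheme.conducting_mask.sum()) == 1


class TestEffectiveRate:
    def test_coupled_su3_entry(self):
        # SU3 desensitizing next to a desensitized SU4 is gamma-accelerated
        rate = effective_rate(
            gated({SU.SU4}), gated({SU.SU3, SU.SU4}),
            PARAMS_III, MutationProfile(), ModelVariant.III,
        )
        assert rate == pytest.approx(100.0 * PARAMS_III.delta3_plus)

    def test_coupled_su5_recovery(self):
        # SU5 recovering next to a desensitized SU4 is epsilon-slowed
        rate = effective_rate(
            gated({SU.SU4, SU.SU5}), gated({SU.SU4}),
            PARAMS_III, MutationProfile(), ModelVariant.III,
        )
        assert rate == pytest.approx(PARAMS_III.delta_minus / 10.0)

    def test_mutated_entry_multiplier(self):
        profile = profile_from_multipliers({SU.SU4}, c4=(6.0, 2.0))
        rate = effective_rate(
            gated(()), gated({SU.SU4}), PARAMS, profile, ModelVariant.II
        )
        assert rate == pytest.approx(6.0 * PARAMS.delta_plus)

    def test_wild_type_base_rate(self):
        rate = effective_rate(
            gated(()), gated({SU.SU4}), PARAMS, MutationProfile(), ModelVariant.I
        )
        assert rate == pytest.approx(PARAMS.delta_plus)

    def test_model_I_ignores_recovery_multiplier(self):
        profile = profile_from_multipliers({SU.SU4}, c4=(6.0, 3.0))
        rate = effective_rate(
            gated({SU.SU4}), gated(()), PARAMS, profile, ModelVariant.I
        )
        assert rate == pytest.approx(PARAMS.delta_minus)

    def test_cross_effect_on_su4(self):
        profile = profile_from_multipliers({SU.SU3}, c3=(2.0, 1.0), c34=(5.0, 7.0))
        rate = effective_rate(
            gated(()), gated({SU.SU4}), PARAMS, profile, ModelVariant.III
        )
        assert rate == pytest.approx(5.0 * PARAMS.delta_plus)
        # same transition under plain model II carries no cross-effect
        profile_ii = profile_from_multipliers({SU.SU3}, c3=(2.0, 1.0))
        rate_ii = effective_rate(
            gated(()), gated({SU.SU4}), PARAMS, profile_ii, ModelVariant.II
        )
        assert rate_ii == pytest.approx(PARAMS.delta_plus)

    def test_non_adjacent_raises(self):
        with pytest.raises(InvalidTransitionError):
            effective_rate(
                gated(()), gated({SU.SU4, SU.SU5}), PARAMS,
                MutationProfile(), ModelVariant.I,
            )


class TestGenerator:
    @pytest.mark.parametrize("variant", list(ModelVariant))
    @pytest.mark.parametrize("mutated", ALL_PROFILES)
    def test_row_sums_zero(self, variant, mutated):
        params = PARAMS_III if variant is ModelVariant.III else PARAMS
        scheme = build_scheme(variant, params, make_profile(mutated, variant))
        q = scheme.generator
        scale = np.abs(q).max()
        assert np.abs(q.sum(axis=1)).max() < 1e-9 * scale
        off_diag = q - np.diag(np.diag(q))
        assert (off_diag >= 0).all()

    def test_unit_multipliers_reproduce_wild_type(self):
        wt = build_scheme(ModelVariant.III, PARAMS_III)
        unit = profile_from_multipliers(
            {SU.SU3, SU.SU4, SU.SU5},
            c3=(1.0, 1.0), c4=(1.0, 1.0), c5=(1.0, 1.0), c34=(1.0, 1.0),
        )
        mut = build_scheme(ModelVariant.III, PARAMS_III, unit)
        np.testing.assert_array_equal(wt.generator, mut.generator)

    def test_model_II_equals_model_III_without_couplings(self):
        s2 = build_scheme(ModelVariant.II, PARAMS)
        s3 = build_scheme(ModelVariant.III, PARAMS)  # gamma = epsilon = 1
        np.testing.assert_allclose(s2.generator, s3.generator)

    def test_su4_su5_mutation_swap_leaves_spectrum(self):
        for variant in (ModelVariant.I, ModelVariant.II):
            a = build_scheme(
                variant, PARAMS, profile_from_multipliers({SU.SU4}, c4=(9.0, 1.0))
            )
            b = build_scheme(
                variant, PARAMS, profile_from_multipliers({SU.SU5}, c5=(9.0, 1.0))
            )
            ev_a = np.sort_complex(np.linalg.eigvals(a.generator))
            ev_b = np.sort_complex(np.linalg.eigvals(b.generator))
            np.testing.assert_allclose(ev_a, ev_b, atol=1e-9)

    def test_concerted_topology(self):
        scheme = build_scheme(ModelVariant.CONCERTED, PARAMS)
        assert scheme.labels == ["R", "AR", "AO", "Dfast", "Dslow"]
        q = scheme.generator
        i_f, i_s = scheme.state_index("Dfast"), scheme.state_index("Dslow")
        # desensitized branches talk only to AO
        for i in (i_f, i_s):
            connected = {j for j in range(5) if j != i and q[i, j] > 0}
            assert connected == {scheme.state_index("AO")}
        assert int(scheme.conducting_mask.sum()) == 1

    def test_agonist_rescaling(self):
        scheme = build_scheme(ModelVariant.I, PARAMS, agonist_conc=0.01)
        q0 = scheme.generator_at(0.0)
        i_r, i_ar = scheme.state_index("R"), scheme.state_index("AR")
        assert q0[i_r, i_ar] == 0.0
        assert np.abs(q0.sum(axis=1)).max() < 1e-9 * np.abs(q0).max()


class TestDetailedBalance:
    @pytest.mark.parametrize("variant", [ModelVariant.I, ModelVariant.II,
                                         ModelVariant.II_BETA, ModelVariant.III])
    @pytest.mark.parametrize("mutated", ALL_PROFILES)
    def test_all_cycles_balance(self, variant, mutated):
        params = PARAMS_III if variant is ModelVariant.III else PARAMS
        scheme = build_scheme(variant, params, make_profile(mutated, variant))
        report = check_detailed_balance(scheme)
        assert report.n_cycles == 6  # patterns {}, {3}, {4}, {5} x free pairs
        assert report.ok, report.violations

    def test_perturbed_rate_detected(self):
        scheme = build_scheme(ModelVariant.III, PARAMS_III)
        i = scheme.state_index("AD4")
        j = scheme.state_index("AD45")
        scheme.generator[i, j] *= 1.5
        report = check_detailed_balance(scheme)
        assert not report.ok
        labels = {lab for v in report.violations for lab in v.labels}
        assert "AD45" in labels


class TestValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateParameters(delta_plus=-0.1)
        with pytest.raises(ValueError):
            RateParameters(alpha=0.0)

    def test_coupling_below_one_rejected(self):
        with pytest.raises(ValueError):
            RateParameters(gamma_coupling=0.5)

    def test_unmutated_multiplier_rejected(self):
        with pytest.raises(ValueError):
            MutationProfile(mutated=frozenset(), c4_plus=2.0)
        with pytest.raises(ValueError):
            MutationProfile(mutated=frozenset({SU.SU4}), c34_plus=2.0)

    def test_efficacy_derived(self):
        assert PARAMS.efficacy == pytest.approx(10.0)


def test_edge_list_export():
    scheme = build_scheme(ModelVariant.III, PARAMS_III)
    text = scheme.edge_list()
    lines = text.strip().splitlines()
    assert lines[0].split("\t") == ["from_state", "to_state", "rate_per_s", "descriptor"]
    assert len(lines) - 1 == len(scheme.transitions)
    assert any("SU3_desensitization" in ln for ln in lines)
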