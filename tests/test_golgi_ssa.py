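"""Tests for the cisternal Gillespie simulator against exact CTMC results."""

import numpy as np
import pytest

from glygolgi.ctmc_reference import terminal_distribution
from glygolgi.glycan_network import MAN5, MAN9, GlycanState, default_rules
from glygolgi.golgi_ssa import (
    EnzymeParameterSet,
    compile_network,
    flux_localization,
    gillespie_step,
    simulate_glycan,
    simulate_profile,
)

from conftest import total_variation


def params_with(activities: dict, n_cisternae: int = 4, **kw) -> EnzymeParameterSet:
    return EnzymeParameterSet.from_enzyme_activities(
        activities, n_cisternae=n_cisternae, **kw
    )


ZERO = params_with({})


class TestParameterSet:
    def test_validation(self):
        with pytest.raises(ValueError):
            EnzymeParameterSet(activity=-np.ones((9, 4)))
        with pytest.raises(ValueError):
            EnzymeParameterSet(activity=np.ones((9, 4)), lock_resolution_rate=0.0)
        with pytest.raises(ValueError):
            EnzymeParameterSet(activity=np.ones((9, 4)), residence_time=-1.0)

    def test_json_round_trip(self, cho_params):
        restored = EnzymeParameterSet.from_json(cho_params.to_json())
        np.testing.assert_allclose(restored.activity, cho_params.activity)
        assert restored.lock_resolution_rate == cho_params.lock_resolution_rate

    def test_scaled_fold_change(self, cho_params):
        scaled = cho_params.scaled({"GalT": 4.0})
        ratio = scaled.activity / np.where(cho_params.activity > 0, cho_params.activity, 1.0)
        assert ratio[7].max() == pytest.approx(4.0)  # GalT row
        assert np.allclose(np.delete(ratio, 7, axis=0), 1.0)


class TestGillespieStep:
    def test_absorbing_state(self, rng):
        state, wait, fired = gillespie_step(MAN9, ZERO, 0, rng)
        assert (state, wait, fired) == (MAN9, np.inf, None)

    def test_waiting_time_mean(self, rng):
        p = params_with({"Mgat1": 2.0})
        waits = np.array([gillespie_step(MAN5, p, 0, rng)[1] for _ in range(10_000)])
        se = waits.std() / np.sqrt(len(waits))
        assert abs(waits.mean() - 0.5) < 3 * se

    def test_locked_state_only_resolves(self, rng):
        locked = GlycanState(3, 1, locked=True)
        p = params_with({e: 10.0 for e in ("Man1", "GalT", "Mgat2")}, lock_resolution_rate=2.0)
        nxt, wait, fired = gillespie_step(locked, p, 0, rng)
        assert fired == "LockResolution"
        assert nxt == GlycanState(3, 1, fuc=1)

    def test_bad_cisterna_index(self, rng):
        with pytest.raises(ValueError):
            gillespie_step(MAN5, ZERO, 7, rng)


class TestSimulateGlycan:
    def test_zero_activity_is_identity(self, rng):
        final, counts = simulate_glycan(MAN9, ZERO, rng)
        assert final == MAN9
        assert counts.sum() == 0

    def test_saturating_man1_reaches_man5(self, rng):
        p = params_with({"Man1": 1e6})
        final, counts = simulate_glycan(MAN9, p, rng)
        assert final == MAN5
        assert counts[0].sum() == 4  # four trims, Man9 -> Man5

    def test_two_state_conversion_probability(self, rng):
        # single cisterna, single applicable rule: P(converted) = 1 - e^{-kT}
        k, t, n = 1.3, 1.0, 10_000
        p = params_with({"Mgat1": k}, n_cisternae=1, residence_time=t)
        converted = sum(
            simulate_glycan(MAN5, p, rng)[0].agn == 1 for _ in range(n)
        )
        expect = 1 - np.exp(-k * t)
        sigma = np.sqrt(expect * (1 - expect) / n)
        assert abs(converted / n - expect) < 3 * sigma

    def test_unresolved_lock_force_resolves(self, rng):
        # huge Fut8, tiny resolution rate: lock engages and must be
        # force-resolved at the end, yielding fucose
        p = params_with({"Mgat1": 1e6, "Fut8": 1e6}, lock_resolution_rate=1e-9)
        final, _ = simulate_glycan(MAN5, p, rng)
        assert final.fuc == 1
        assert not final.locked


class TestSimulateProfile:
    def test_zero_activity_profile(self, cho_params):
        res = simulate_profile(ZERO, n_glycans=2000, seed=5)
        assert res.profile == {"Man9": 1.0}

    def test_determinism(self, cho_params):
        a = simulate_profile(cho_params, n_glycans=4000, seed=11)
        b = simulate_profile(cho_params, n_glycans=4000, seed=11)
        assert a.profile == b.profile
        np.testing.assert_array_equal(a.firing_counts, b.firing_counts)

    def test_normalization_and_count_conservation(self, cho_params):
        res = simulate_profile(cho_params, n_glycans=3000, seed=2)
        assert abs(sum(res.profile.values()) - 1.0) < 1e-9
        assert res.n_glycans == 3000

    def test_reference_and_compiled_agree(self, cho_params):
        """The python and numba samplers draw from the same distribution."""
        a = simulate_profile(cho_params, n_glycans=4000, seed=3, method="compiled")
        b = simulate_profile(cho_params, n_glycans=4000, seed=3, method="reference")
        assert total_variation(a.profile, b.profile) < 0.04

    def test_toy_chain_matches_matrix_exponential(self):
        # Man1 then Mgat1 only: 6-state chain, one cisterna
        p = params_with({"Man1": 2.0, "Mgat1": 1.0}, n_cisternae=1)
        sim = simulate_profile(p, n_glycans=10_000, seed=17)
        exact = terminal_distribution(p)
        assert total_variation(sim.profile, exact) < 0.02

    def test_full_network_matches_matrix_exponential(self, cho_params):
        sim = simulate_profile(cho_params, n_glycans=10_000, seed=23)
        exact = terminal_distribution(cho_params)
        assert total_variation(sim.profile, exact) < 0.03

    def test_lock_artifact_vanishes_at_fast_resolution(self, cho_params):
        """With instantaneous lock resolution the hidden lock state has no
        effect beyond plain fucosylation."""
        fast = EnzymeParameterSet(
            activity=cho_params.activity.copy(), lock_resolution_rate=1e6
        )
        exact_fast = terminal_distribution(fast)
        sim = simulate_profile(fast, n_glycans=10_000, seed=29)
        assert total_variation(sim.profile, exact_fast) < 0.02

    def test_galt_monotone_in_galactosylated_output(self, cho_params):
        """More GalT activity never reduces expected G1F+G2F."""
        gal_frac = []
        for fold in (0.5, 1.0, 2.0, 4.0):
            fracs = []
            for seed in range(3):
                prof = simulate_profile(
                    cho_params.scaled({"GalT": fold}), n_glycans=5000, seed=100 + seed
                ).profile
                fracs.append(prof.get("G1F", 0) + prof.get("G2F", 0))
            gal_frac.append(np.mean(fracs))
        assert all(b >= a - 0.02 for a, b in zip(gal_frac, gal_frac[1:]))


class TestFluxLocalization:
    def test_single_cisterna_concentration(self):
        p = EnzymeParameterSet.from_enzyme_activities(
            {"Mgat1": 5.0}, localization=np.array([[1, 0, 0, 0]] * 9, dtype=float)
        )
        res = simulate_profile(p, n_glycans=500, seed=7, start=MAN5)
        np.testing.assert_allclose(flux_localization(res, "Mgat1"), [1, 0, 0, 0])

    def test_normalizes_to_one(self, cho_params):
        res = simulate_profile(cho_params, n_glycans=2000, seed=9)
        assert flux_localization(res, "Mgat1").sum() == pytest.approx(1.0)

    def test_zero_flux_warns(self):
        res = simulate_profile(ZERO, n_glycans=100, seed=1)
        with pytest.warns(RuntimeWarning):
            out = flux_localization(res, "GalT")
        assert np.all(out == 0)

    def test_localization_shift_detected(self):
        """Concentrating Mgat1 in a later cisterna moves its flux there."""
        early = np.ones((9, 4))
        late = np.ones((9, 4))
        early[1] = [10, 0.1, 0.1, 0.1]
        late[1] = [0.1, 0.1, 10, 0.1]
        res_e = simulate_profile(
            EnzymeParameterSet(early), n_glycans=4000, seed=5, start=MAN5
        )
        res_l = simulate_profile(
            EnzymeParameterSet(late), n_glycans=4000, seed=5, start=MAN5
        )
        f_e = flux_localization(res_e, "Mgat1")
        f_l = flux_localization(res_l, "Mgat1")
        assert f_e[0] > 0.7
        assert f_l[2] > f_e[2] + 0.3


class TestCompiledNetwork:
    def test_transition_count_matches_rules(self):
        net = compile_network(default_rules())
        # every transition's rule index is a valid enzyme or the resolver
        assert net.trans_rule.min() >= 0
        assert net.trans_rule.max() == 9
        assert len(net.trans_rule) == net.offsets[-1]
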