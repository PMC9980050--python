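"""Microstate enumeration, edge energetics, consistency projection, and
equilibrium observables of the potential-graph model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from znsite import (
    Residue,
    SiteModel,
    enumerate_microstates,
    independent_site_model,
    pairwise_coupled_site_model,
    project_potentials,
)
from znsite.model import (
    LN10,
    BindingEdge,
    ProtonationEdge,
    check_cycle_closure,
    edge_free_energy,
)

from conftest import brute_force_observables, random_small_site


def residues(n):
    return [Residue(f"r{i}") for i in range(n)]


class TestEnumeration:
    @pytest.mark.parametrize(
        "n_res, with_zn, expected_total, expected_unbound",
        [(4, True, 32, 16), (3, True, 16, 8), (0, True, 2, 1), (2, False, 4, 4)],
    )
    def test_state_counts(self, n_res, with_zn, expected_total, expected_unbound):
        states = enumerate_microstates(residues(n_res), has_zn_site=with_zn)
        assert len(states) == expected_total
        assert sum(not s.zn_bound for s in states) == expected_unbound

    def test_canonical_ordering_is_a_bijection(self):
        states = enumerate_microstates(residues(3))
        for k, s in enumerate(states):
            assert s.index == k
            # little-endian proton bits reconstruct the branch-local index
            local = sum(b << i for i, b in enumerate(s.protons))
            assert local == k % 8
            assert s.zn_bound == (k >= 8)
            assert s.n_protons == sum(s.protons)

    def test_unbound_block_comes_first(self):
        states = enumerate_microstates(residues(2))
        assert [s.zn_bound for s in states] == [False] * 4 + [True] * 4

    def test_too_many_residues_raises(self):
        with pytest.raises(ValueError, match="at most"):
            enumerate_microstates(residues(13))

    def test_duplicate_names_raise(self):
        with pytest.raises(ValueError, match="unique"):
            enumerate_microstates([Residue("a"), Residue("a")])


class TestEdgeFreeEnergy:
    def test_protonation_vanishes_at_pka(self):
        e = ProtonationEdge("h", {}, pka=6.5)
        assert edge_free_energy(e, ph=6.5) == 0.0

    def test_protonation_value(self):
        # ln10 * (7.4 - 7.82) for a histidine-like microscopic pKa
        e = ProtonationEdge("h", {}, pka=7.82)
        assert edge_free_energy(e, ph=7.4) == pytest.approx(-0.9670857, abs=1e-6)

    def test_binding_vanishes_at_kd(self):
        e = BindingEdge.from_kd({}, kd_molar=5e-8)
        assert edge_free_energy(e, x_molar=5e-8) == pytest.approx(0.0, abs=1e-12)

    def test_standard_state_binding_energy_from_kd(self):
        # ln(1.6e-8 / 1 M) for a 16 nM site
        e = BindingEdge.from_kd({}, kd_molar=16e-9)
        assert e.dg0 == pytest.approx(math.log(1.6e-8), abs=1e-12)
        assert e.dg0 == pytest.approx(-17.9507, abs=1e-4)

    def test_nonpositive_concentration_rejected(self):
        e = BindingEdge({}, dg0=-10.0)
        with pytest.raises(ValueError, match="> 0"):
            edge_free_energy(e, x_molar=0.0)
        with pytest.raises(ValueError):
            BindingEdge.from_kd({}, kd_molar=-1.0)


class TestPotentialProjection:
    def test_consistent_triangle_exact(self):
        g, resid = project_potentials(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 2.0)])
        assert np.allclose(g, [0.0, 1.0, 2.0], atol=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-12)

    def test_inconsistent_symmetric_cycle_flattens(self):
        # directed 3-cycle of equal edges has no consistent potential;
        # the normal equations put every node at the same potential
        g, resid = project_potentials(3, [(0, 1, 1.0), (1, 2, 1.0), (2, 0, 1.0)])
        assert np.allclose(g, 0.0, atol=1e-12)
        assert resid == pytest.approx(3.0, abs=1e-10)

    def test_reference_shift_preserves_differences(self):
        edges = [(0, 1, 1.3), (1, 2, -0.4), (2, 0, -0.7)]
        g0, _ = project_potentials(3, edges, reference=0)
        g1, _ = project_potentials(3, edges, reference=1)
        d0 = g0[:, None] - g0[None, :]
        d1 = g1[:, None] - g1[None, :]
        assert np.allclose(d0, d1, atol=1e-12)

    def test_disconnected_graph_names_states(self):
        with pytest.raises(ValueError, match="unreachable.*\\[2, 3\\]"):
            project_potentials(4, [(0, 1, 1.0), (2, 3, 1.0)])

    def test_weights_pull_toward_heavier_edge(self):
        # two parallel measurements of the same step: weighted mean wins
        g, _ = project_potentials(
            2, [(0, 1, 1.0), (0, 1, 2.0)], weights=[3.0, 1.0]
        )
        assert g[1] == pytest.approx(1.25, abs=1e-12)


class TestObservables:
    def test_single_residue_half_at_pka(self):
        m = independent_site_model({"a": 7.0})
        p = m.probabilities(7.0, 1e-20)
        assert np.allclose(p, [0.5, 0.5], atol=1e-12)

    def test_two_independent_residues(self):
        m = independent_site_model({"a": 6.0, "b": 8.0})
        p = m.probabilities(7.0, 1e-20)
        # P(both deprotonated) = (10/11) * (1/11)
        assert p[0] == pytest.approx((10 / 11) * (1 / 11), abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        pka=st.floats(0.0, 14.0),
        ph=st.floats(0.0, 14.0),
        dg0=st.floats(-30.0, -5.0),
        logx=st.floats(-15.0, -1.0),
    )
    def test_probabilities_normalized(self, pka, ph, dg0, logx):
        m = independent_site_model({"a": pka}, dg0_bind=dg0)
        p = m.probabilities(ph, 10.0**logx)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)

    def test_bound_fraction_half_at_kd_without_titration(self):
        m = SiteModel([], [BindingEdge({}, dg0=math.log(1e-8))])
        assert m.bound_fraction(7.0, 1e-8) == pytest.approx(0.5, abs=1e-12)

    def test_bound_fraction_limits(self):
        m = independent_site_model({"a": 7.0}, dg0_bind=math.log(1e-8))
        assert m.bound_fraction(7.0, 1e-18) < 1e-6
        assert m.bound_fraction(7.0, 1.0) > 1 - 1e-6

    def test_bound_fraction_monotone_in_concentration(self):
        m = pairwise_coupled_site_model(
            {"a": 7.0, "b": 5.0}, dg0_bind=-18.0, coupling={("a", "b"): 1.5}
        )
        xs = np.geomspace(1e-12, 1e-3, 40)
        bf = m.bound_fractions(np.full(40, 6.5), xs)
        assert np.all(np.diff(bf) >= -1e-12)

    def test_proton_only_model_has_no_bound_fraction(self):
        m = independent_site_model({"a": 7.0})
        with pytest.raises(ValueError, match="no metal-binding edge"):
            m.bound_fraction(7.0, 1e-9)

    def test_residue_observables_henderson_hasselbalch(self):
        m = independent_site_model({"a": 6.0})
        for ph in (4.0, 6.0, 8.0):
            s, _ = m.residue_observables(ph, 1e-20)
            expected = 1.0 / (1.0 + 10.0 ** (6.0 - ph))
            assert s["a"] == pytest.approx(expected, abs=1e-12)

    def test_mean_bound_protons_two_identical_residues(self):
        m = independent_site_model({"a": 8.0, "b": 8.0})
        # each residue protonated with probability 10/11 at pH 7
        assert m.mean_bound_protons(7.0, 1e-20) == pytest.approx(
            2 * 10 / 11, abs=1e-12
        )

    def test_proton_count_identity(self, rng):
        cfg = random_small_site(rng, 3)
        m = pairwise_coupled_site_model(
            cfg["pkas"], cfg["dg0"], cfg["coupling"], cfg["bound_pkas"]
        )
        s, nprot = m.residue_observables(6.2, 1e-7)
        assert nprot == pytest.approx(sum(1 - v for v in s.values()), abs=1e-12)

    def test_saturating_ligand_deprotonates_bound_branch(self):
        # bound branch strongly deprotonation-favoring: at saturating
        # ligand every residue ends up deprotonated
        m = pairwise_coupled_site_model(
            {"a": 7.5, "b": 6.0},
            dg0_bind=-20.0,
            bound_pkas={"a": -2.0, "b": -2.0},
        )
        s, _ = m.residue_observables(5.0, 1e-2)
        assert all(v > 0.999 for v in s.values())

    def test_unknown_residue_rejected(self):
        m = independent_site_model({"a": 7.0}, dg0_bind=-18.0)
        with pytest.raises(ValueError, match="unknown residue"):
            m.implied_pka("zz", {})


class TestApparentKd:
    def test_uncoupled_model_returns_intrinsic_kd(self):
        m = independent_site_model(
            {"a": 7.0}, dg0_bind=math.log(3e-8)
        )  # bound pKa's default to unbound: binding decouples
        assert m.apparent_kd(6.0) == pytest.approx(3e-8, rel=1e-6)
        assert m.apparent_kd(8.5) == pytest.approx(3e-8, rel=1e-6)

    def test_single_competitor_closed_form(self):
        # proton and metal mutually exclusive: half-saturation at
        # K_D * (1 + 10^(pKa - pH))
        m = independent_site_model(
            {"a": 7.0},
            dg0_bind=math.log(10e-9),
            bound_pkas={"a": -30.0},
        )
        assert m.apparent_kd(6.0) == pytest.approx(110e-9, rel=1e-5)

    def test_proton_only_model_rejected(self):
        m = independent_site_model({"a": 7.0})
        with pytest.raises(ValueError, match="no metal-binding edge"):
            m.apparent_kd(7.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_res", [1, 2, 3])
    @pytest.mark.parametrize("case", range(4))
    def test_matches_brute_force(self, n_res, case, rng):
        cfg = random_small_site(
            np.random.default_rng(1000 * n_res + case), n_res
        )
        m = pairwise_coupled_site_model(
            cfg["pkas"], cfg["dg0"], cfg["coupling"], cfg["bound_pkas"]
        )
        for ph, x in [(4.5, 1e-9), (7.0, 1e-7), (9.5, 1e-4)]:
            ref = brute_force_observables(
                cfg["pkas"], ph, x, cfg["dg0"], cfg["coupling"], cfg["bound_pkas"]
            )
            assert np.allclose(
                m.probabilities(ph, x), ref["probabilities"], atol=1e-10
            )
            assert m.bound_fraction(ph, x) == pytest.approx(
                ref["bound_fraction"], abs=1e-10
            )
            s, nprot = m.residue_observables(ph, x)
            for name, val in ref["deprotonation"].items():
                assert s[name] == pytest.approx(val, abs=1e-10)
            assert nprot == pytest.approx(ref["mean_protons"], abs=1e-10)

    def test_detailed_balance_stationary_distribution(self):
        # rates satisfying the edge dG's have the Boltzmann distribution
        # as their stationary state
        m = pairwise_coupled_site_model(
            {"a": 7.0, "b": 5.5}, dg0_bind=-18.0, coupling={("a", "b"): -2.0}
        )
        ph, x = 6.5, 3e-8
        G = m.state_free_energies(ph, x)
        n = m.n_states
        K = np.zeros((n, n))
        for i, j in m._index_pairs:
            K[j, i] = math.exp(-(G[j] - G[i]) / 2)
            K[i, j] = math.exp(-(G[i] - G[j]) / 2)
        np.fill_diagonal(K, -K.sum(axis=0))
        w, v = np.linalg.eig(K)
        stat = np.real(v[:, np.argmin(np.abs(w))])
        stat = stat / stat.sum()
        assert np.allclose(stat, m.probabilities(ph, x), atol=1e-9)


class TestCycleClosure:
    def test_closure_on_fixtures(self):
        from znsite import reference_fixtures

        for model in reference_fixtures().values():
            assert check_cycle_closure(model, atol=1e-10) < 1e-10

    def test_closure_after_noisy_edges(self, rng):
        # perturb edge values inconsistently: projection restores closure
        m = pairwise_coupled_site_model(
            {"a": 7.0, "b": 5.0}, dg0_bind=-18.0, coupling={("a", "b"): 2.0}
        )
        noisy = m.edge_values + rng.normal(0, 0.5, len(m.edges))
        m2 = m.with_edge_values(noisy)
        assert m2.projection_residual > 0
        assert check_cycle_closure(m2, atol=1e-10) < 1e-10
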