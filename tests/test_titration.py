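"""Lambda-series classification, microstate histograms, pKa fits,
coupling energies, and effective pKa extraction."""

import math

import numpy as np
import pytest
from scipy import stats

from znsite import (
    CoupledTitrationCurve,
    HillLangmuirCurve,
    TitrationSeries,
    aggregate_protomer_pka,
    classify_series,
    coupling_energy,
    effective_pkas,
    independent_site_model,
    microstate_histogram,
    pairwise_coupled_site_model,
    site_b_model,
)
from znsite.titration import (
    PH_LADDER_30,
    coupled_titration_nprot,
    deprotonation_curve,
    hill_langmuir,
)


class TestClassify:
    def test_counts_and_fraction(self):
        c = classify_series(np.array([0.95, 0.9, 0.1, 0.85]))
        assert (c.n_deprot, c.n_prot) == (3, 1)
        assert c.s == pytest.approx(0.75)
        assert not c.missing

    def test_all_intermediate_is_missing_not_error(self):
        c = classify_series(np.array([0.5, 0.3, 0.7]))
        assert c.missing and math.isnan(c.s)
        assert (c.n_deprot, c.n_prot) == (0, 0)

    def test_fully_deprotonated(self):
        c = classify_series(np.array([0.85, 0.99, 0.81]))
        assert c.s == 1.0

    def test_band_boundaries_excluded(self):
        c = classify_series(np.array([0.2, 0.8, 0.1, 0.9]))
        assert (c.n_deprot, c.n_prot) == (1, 1)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            classify_series(np.array([0.5]), lo=0.8, hi=0.2)

    def test_widening_excluded_band_only_removes_frames(self):
        lam = np.random.default_rng(5).random(500)
        narrow_band = classify_series(lam, 0.3, 0.7)
        wide_band = classify_series(lam, 0.1, 0.9)
        # a wider excluded band classifies fewer frames but never flips labels
        assert (
            wide_band.n_deprot + wide_band.n_prot
            <= narrow_band.n_deprot + narrow_band.n_prot
        )
        assert wide_band.n_deprot <= narrow_band.n_deprot
        assert wide_band.n_prot <= narrow_band.n_prot
        flipped = (wide_band.labels * narrow_band.labels) < 0
        assert not flipped.any()


class TestHistogram:
    def test_two_residue_example(self):
        lam = np.array([[0.9, 0.1], [0.9, 0.1], [0.1, 0.9]])
        p = microstate_histogram(lam)
        # (deprot, prot) -> index 2; (prot, deprot) -> index 1
        assert p[2] == pytest.approx(2 / 3)
        assert p[1] == pytest.approx(1 / 3)
        assert p[0] == p[3] == 0.0

    def test_always_protonated_marginal(self):
        lam = np.column_stack(
            [np.full(10, 0.05), np.random.default_rng(0).random(10) * 0.09]
        )
        p = microstate_histogram(lam)
        assert p[3] == 1.0

    def test_partial_frames_dropped(self):
        lam = np.array([[0.9, 0.5], [0.9, 0.1]])
        p = microstate_histogram(lam)
        assert p[2] == 1.0

    def test_no_usable_frames_raises(self):
        with pytest.raises(ValueError, match="classifiable"):
            microstate_histogram(np.array([[0.5, 0.9], [0.9, 0.4]]))

    def test_sampling_oracle_chi2(self):
        from znsite import GeneratorSpec, generate_titration_series

        model = pairwise_coupled_site_model(
            {"a": 7.0, "b": 6.0}, coupling={("a", "b"): 1.0}
        )
        sample = generate_titration_series(
            GeneratorSpec(
                model=model,
                seed=42,
                frames_per_ph=10000,
                titration_ladder=(6.5,),
            )
        )
        counts = microstate_histogram(sample.frame_matrix(6.5)) * 10000
        expected = model.unbound_probabilities(6.5) * 10000
        keep = expected > 5
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_marginals_match_per_residue_fractions(self):
        rng = np.random.default_rng(3)
        lam = np.where(rng.random((200, 2)) < 0.4, 0.05, 0.95)
        p = microstate_histogram(lam)
        s0 = classify_series(lam[:, 0]).s
        # marginal deprotonation of residue 0: states with bit0 clear
        assert p[0] + p[2] == pytest.approx(s0, abs=1e-12)


class TestHillLangmuir:
    def test_noiseless_round_trip(self):
        ph = np.array(PH_LADDER_30)
        s = hill_langmuir(ph, pka=7.97, n=1.0)
        fit = HillLangmuirCurve().fit(ph, s)
        assert fit.pka_ == pytest.approx(7.97, abs=1e-6)
        assert fit.hill_ == pytest.approx(1.0, abs=1e-6)
        assert fit.residual_ < 1e-8

    def test_noisy_recovery(self):
        rng = np.random.default_rng(11)
        ph = np.array(PH_LADDER_30)
        s = hill_langmuir(ph, 7.97, 1.0) + rng.normal(0, 0.02, ph.size)
        fit = HillLangmuirCurve().fit(ph, s)
        assert fit.pka_ == pytest.approx(7.97, abs=0.1)

    def test_saturated_curve_unidentifiable(self):
        ph = np.array(PH_LADDER_30)
        with pytest.raises(ValueError, match="unidentifiable"):
            HillLangmuirCurve().fit(ph, np.ones_like(ph))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 4"):
            HillLangmuirCurve().fit([6, 7, 8], [0.2, 0.5, 0.8])

    def test_curve_from_series_skips_missing(self):
        series = [
            TitrationSeries("a", ph, np.full(50, 0.95 if ph > 7 else 0.05))
            for ph in (5.0, 6.0, 8.0, 9.0)
        ] + [TitrationSeries("a", 7.0, np.full(50, 0.5))]
        curve = deprotonation_curve(series)
        assert curve.usable.sum() == 4
        assert math.isnan(curve.s[curve.ph == 7.0][0])


class TestProtomerAggregation:
    @pytest.mark.parametrize(
        "a, b, mean, err",
        [(7.9, 8.1, 8.0, 0.1), (5.0, 5.0, 5.0, 0.0), (7.82, 8.12, 7.97, 0.15)],
    )
    def test_mean_and_error(self, a, b, mean, err):
        got_mean, got_err = aggregate_protomer_pka(a, b)
        assert got_mean == pytest.approx(mean, abs=1e-12)
        assert got_err == pytest.approx(err, abs=1e-12)


class TestCoupledTitration:
    def test_statistical_factor_identity(self):
        # two independent identical sites with microscopic pKa 8:
        # the stepwise model must fit with pK1 - pK2 = 2 log10(2)
        ph = np.linspace(5, 11, 40)
        nprot = 2.0 / (1.0 + 10.0 ** (ph - 8.0))
        fit = CoupledTitrationCurve().fit(ph, nprot)
        assert fit.residual_ < 1e-8
        assert fit.pk1_ == pytest.approx(8 + math.log10(2), abs=1e-6)
        assert fit.pk2_ == pytest.approx(8 - math.log10(2), abs=1e-6)
        assert fit.pk1_ - fit.pk2_ == pytest.approx(2 * math.log10(2), abs=1e-6)

    def test_anticooperative_round_trip(self):
        ph = np.linspace(2, 15, 60)
        nprot = coupled_titration_nprot(ph, 12.4, 5.6)
        fit = CoupledTitrationCurve().fit(ph, nprot)
        assert fit.pk1_ == pytest.approx(12.4, abs=1e-6)
        assert fit.pk2_ == pytest.approx(5.6, abs=1e-6)

    def test_limits(self):
        assert coupled_titration_nprot(0.0, 12.4, 5.6) == pytest.approx(2.0, abs=1e-5)
        assert coupled_titration_nprot(20.0, 12.4, 5.6) == pytest.approx(0.0, abs=1e-5)

    def test_flat_curve_unidentifiable(self):
        ph = np.linspace(6, 8, 10)
        with pytest.raises(ValueError, match="unidentifiable"):
            CoupledTitrationCurve().fit(ph, np.full(10, 1.0))

    def test_out_of_range_rejected(self):
        ph = np.linspace(2, 12, 10)
        with pytest.raises(ValueError, match="\\[0, 2\\]"):
            CoupledTitrationCurve().fit(ph, np.linspace(0, 3, 10))


class TestCouplingEnergy:
    def test_independent_residues_have_zero_coupling(self):
        m = independent_site_model({"a": 7.0, "b": 5.0}, dg0_bind=-18.0)
        assert coupling_energy(m, "a", "b").w == pytest.approx(0.0, abs=1e-10)

    def test_direct_difference_from_pka_table(self):
        table = {("h1", 0): 8.0, ("h1", 1): 7.0}
        assert coupling_energy(table, "h1", "h2").w == pytest.approx(1.0)

    def test_missing_edge_raises(self):
        with pytest.raises(ValueError, match="missing"):
            coupling_energy({("h1", 0): 8.0}, "h1", "h2")

    def test_path_identity_on_consistent_graph(self):
        m = site_b_model()
        w_rs = coupling_energy(m, "H73", "H77").w
        w_sr = coupling_energy(m, "H77", "H73").w
        assert w_rs == pytest.approx(w_sr, abs=1e-10)
        assert w_rs > 0  # anti-cooperative pair

    def test_sign_convention(self):
        anti = pairwise_coupled_site_model(
            {"a": 8.0, "b": 8.0}, coupling={("a", "b"): 1.5}
        )
        coop = pairwise_coupled_site_model(
            {"a": 8.0, "b": 8.0}, coupling={("a", "b"): -1.5}
        )
        assert coupling_energy(anti, "a", "b").w == pytest.approx(1.5, abs=1e-10)
        assert coupling_energy(coop, "a", "b").w == pytest.approx(-1.5, abs=1e-10)

    def test_context_dependence(self):
        m = pairwise_coupled_site_model(
            {"a": 8.0, "b": 8.0, "c": 4.0},
            coupling={("a", "b"): 2.0, ("a", "c"): 1.0},
        )
        w0 = coupling_energy(m, "a", "b", context={"c": 0}).w
        w1 = coupling_energy(m, "a", "b", context={"c": 1}).w
        # pairwise Hamiltonian: a-b coupling independent of c's occupancy
        assert w0 == pytest.approx(2.0, abs=1e-10)
        assert w1 == pytest.approx(2.0, abs=1e-10)


class TestEffectivePka:
    def test_uncoupled_residue_recovers_microscopic_pka(self):
        m = independent_site_model({"a": 6.8}, dg0_bind=-18.0)
        eff = effective_pkas(m)
        assert eff["a"].pka == pytest.approx(6.8, abs=1e-4)
        assert eff["a"].route == "hill"

    def test_cooperative_pair_steep_joint_curve(self):
        # first proton pKa 6, second 9: strongly cooperative pair titrates
        # as one steep transition at the midpoint 7.5 with Hill n near 2
        m = pairwise_coupled_site_model(
            {"a": 6.0, "b": 6.0}, coupling={("a", "b"): -3.0}
        )
        eff = effective_pkas(m, coupled_pairs=[])
        assert eff["a"].pka == pytest.approx(7.5, abs=0.05)
        assert eff["a"].hill == pytest.approx(2.0, abs=0.1)

    def test_anticooperative_pair_falls_back_to_coupled_model(self):
        m = site_b_model()
        eff = effective_pkas(m)
        assert eff["H73"].route == "coupled"
        assert eff["H77"].route == "coupled"
        assert eff["H73"].pka == pytest.approx(12.37, abs=0.05)
        assert eff["H77"].pka == pytest.approx(5.27, abs=0.05)
        # the aspartate fits fine on its own
        assert eff["D70"].route == "hill"
        assert eff["D70"].pka == pytest.approx(1.12, abs=0.1)
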