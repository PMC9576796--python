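"""The two-stage batch simulator: closure, conservation, labels, noise."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

import ndapo as nd
from ndapo.synthetic_data import SimulationError


class TestClosure:
    def test_noiseless_run_closes_exactly(self, noiseless_truth):
        t = noiseless_truth.truth
        assert nd.nitrogen_balance(t) == pytest.approx(1.0, abs=1e-9)
        assert nd.electron_balance(t, "from-propane").ratio == pytest.approx(1.0, abs=1e-9)
        assert nd.electron_balance(t, "from-co2").ratio == pytest.approx(1.0, abs=1e-9)

    def test_partition_recovers_configured_truth(self, noiseless_truth):
        p_n2, p_nh4 = nd.product_partition(noiseless_truth.truth)
        assert p_n2 == pytest.approx(100 * noiseless_truth.phi_true, abs=1e-9)
        assert p_n2 + p_nh4 == pytest.approx(100.0, abs=1e-9)

    def test_stage1_ammonium_negligible(self, noiseless_truth):
        t = noiseless_truth.truth
        seg = nd.segment_stages(t)
        bound = noiseless_truth.params.negligible_nh4_fraction * t.start("no3_umolN")
        assert seg.stage1(t).end("nh4_umolN") <= bound

    def test_stage1_ammonium_bounded_with_small_dnra(self):
        params = nd.SimulationParams(r_dnra_s1=0.2)
        batch = nd.simulate_batch(params, 0)
        t = batch.truth
        seg = nd.segment_stages(t)
        nh4_s1 = seg.stage1(t).end("nh4_umolN")
        assert 0 < nh4_s1 <= params.negligible_nh4_fraction * params.no3_umolN


class TestConservation:
    def test_nitrogen_atoms_constant(self, noiseless_truth):
        t = noiseless_truth.truth
        total = sum(t.column(c) for c in
                    ("no3_umolN", "no2_umolN", "nh4_umolN", "n2_umolN"))
        assert np.max(np.abs(total - total[0])) < 1e-9

    def test_carbon_atoms_constant_with_assimilation(self):
        batch = nd.simulate_batch(nd.SimulationParams(f_assim=0.2), 0)
        t = batch.truth
        carbon = 3 * t.column("propane_umol") + t.column("co2_umol")
        start = carbon[0]
        end = carbon[-1] + batch.assimilated_c_umol
        assert end == pytest.approx(start, abs=1e-9)

    def test_electron_ledger_balances_every_step(self, noiseless_truth):
        t = noiseless_truth.truth
        e_out = 20.0 * (t.start("propane_umol") - t.column("propane_umol"))
        e_in = (5 * t.column("n2_umolN") + 8 * t.column("nh4_umolN")
                + 2 * t.column("no2_umolN"))
        assert np.max(np.abs(e_out - e_in)) < 1e-9

    def test_labelled_nitrogen_conserved(self, noiseless_truth):
        t = noiseless_truth.truth
        f29 = t.column("n2_29_frac")
        f30 = t.column("n2_30_frac")
        n2_mol = t.column("n2_umolN") / 2.0
        heavy_n2 = (f29 + 2 * f30) * n2_mol
        total = (t.column("n15_no3_umol") + t.column("n15_no2_umol")
                 + t.column("n15_nh4_umol") + heavy_n2)
        assert np.max(np.abs(total - total[0])) < 1e-9


class TestIsotopologues:
    def test_increments_follow_binomial_pairing(self, noiseless_truth):
        """Each step's 29N2 increment is 2p(1-p) of the new molecules, with p
        the nitrite heavy fraction at the start of the step."""
        t = noiseless_truth.truth.data
        n2_mol = t["n2_umolN"].to_numpy() / 2.0
        cum29 = t["n2_29_frac"].to_numpy() * n2_mol
        cum30 = t["n2_30_frac"].to_numpy() * n2_mol
        no2 = t["no2_umolN"].to_numpy()
        l_no2 = t["n15_no2_umol"].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(no2 > 0, l_no2 / np.where(no2 > 0, no2, 1.0), 0.0)
        d_mol = np.diff(n2_mol)
        d29 = np.diff(cum29)
        d30 = np.diff(cum30)
        p_prev = p[:-1]
        assert np.allclose(d29, 2 * p_prev * (1 - p_prev) * d_mol, atol=1e-12)
        assert np.allclose(d30, p_prev**2 * d_mol, atol=1e-12)

    def test_end_run_fraction_matches_label_level(self, noiseless_truth):
        """With a ~1% 15N nitrate pool the binomial 29N2 fraction is ~2p."""
        t = noiseless_truth.truth
        f29 = t.end("n2_29_frac")
        p15 = noiseless_truth.params.p15
        assert 0 < f29 <= 2 * p15
        assert f29 == pytest.approx(2 * p15 * (1 - p15), rel=0.05)

    def test_single_atom_bookkeeping_doubles_nothing(self):
        b = nd.simulate_batch(nd.SimulationParams(pairing="single-atom"), 0)
        t = b.truth
        assert t.end("n2_30_frac") == 0.0
        # heavy atoms all land in 29N2: f29 = 2p exactly in atom bookkeeping
        assert t.end("n2_29_frac") == pytest.approx(2 * 0.01, rel=0.05)


class TestLabels:
    def test_complete_oxidation_label_ratio_is_three(self, noiseless_truth):
        t = noiseless_truth.truth
        produced = t.end("c13_co2_umol") - t.start("c13_co2_umol")
        consumed = t.start("c13_propane_umol") - t.end("c13_propane_umol")
        assert nd.label_consumption_ratio(produced, consumed) == pytest.approx(
            3.0, abs=1e-9
        )

    def test_assimilation_reproduces_sub_stoichiometric_ratio(self):
        """f_assim = 0.193 gives 3(1 - 0.193) = 2.421, the observed shortfall."""
        batch = nd.simulate_batch(nd.SimulationParams(f_assim=0.193), 0)
        t = batch.truth
        produced = t.end("c13_co2_umol") - t.start("c13_co2_umol")
        consumed = t.start("c13_propane_umol") - t.end("c13_propane_umol")
        ratio = nd.label_consumption_ratio(produced, consumed)
        assert ratio == pytest.approx(3 * (1 - 0.193), abs=1e-6)
        assert ratio == pytest.approx(2.42, abs=0.005)


class TestDeterminism:
    def test_same_seed_reproduces_bytes(self):
        params = nd.SimulationParams(noise_sigma=0.02)
        a = nd.simulate_batch(params, 7).observed.data
        b = nd.simulate_batch(params, 7).observed.data
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_share_truth(self):
        params = nd.SimulationParams(noise_sigma=0.02)
        a = nd.simulate_batch(params, 1)
        b = nd.simulate_batch(params, 2)
        pd.testing.assert_frame_equal(a.truth.data, b.truth.data)
        assert not a.observed.data.equals(b.observed.data)

    def test_replicate_seeds_derived_from_master(self):
        params = nd.SimulationParams(noise_sigma=0.02, n_replicates=3, seed=11)
        batches, manifest = nd.generate_replicates(params)
        assert manifest["replicate_seeds"] == [11, 12, 13]
        again, _ = nd.generate_replicates(params)
        for x, y in zip(batches, again):
            pd.testing.assert_frame_equal(x.observed.data, y.observed.data)


class TestNoiseStatistics:
    def test_nitrogen_balance_spread_matches_delta_method(self):
        """Empirical replicate SD of the closure ratio within a factor two of
        first-order error propagation (2 var for the nitrate delta, 3 x 2 var
        for the product deltas, at a true ratio of 1)."""
        params = nd.SimulationParams(noise_sigma=0.02, n_replicates=100, seed=7)
        batches, _ = nd.generate_replicates(params)
        values = np.array([nd.nitrogen_balance(b.observed) for b in batches])
        sd_analyte = params.noise_sigma * params.no3_umolN
        predicted = math.sqrt(8) * sd_analyte / params.no3_umolN
        empirical = values.std(ddof=1)
        assert 0.5 * predicted <= empirical <= 2.0 * predicted


class TestValidationAndErrors:
    def test_unreachable_partition_rejected(self):
        # Stage 1 already fixes more N2 than a small phi allows
        params = nd.SimulationParams(r_n2_s1=13.0, phi_n2=0.2)
        with pytest.raises(SimulationError, match="unreachable"):
            nd.simulate_batch(params, 0)

    def test_propane_exhaustion_reported(self):
        with pytest.raises(SimulationError, match="propane"):
            nd.simulate_batch(nd.SimulationParams(propane_umol=10.0), 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"phi_n2": 0.0},
            {"f_assim": 1.0},
            {"noise_sigma": -0.1},
            {"dt": 0.0},
            {"n_replicates": 0},
            {"p15": 1.5},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(SimulationError):
            nd.SimulationParams(**kwargs)
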