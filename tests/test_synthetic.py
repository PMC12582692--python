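import math

import numpy as np
import pytest

from protmr.instruments import harmonize, select_significant
from protmr.mr import ivw
from protmr.synthetic import (simulate_instrument_set, simulate_instruments,
                              simulate_mediation_triplet,
                              simulate_protein_panel, simulate_region_pair)


class TestSimulateInstruments:
    def test_same_seed_reproduces_exactly(self):
        a = simulate_instruments(k=10, theta_true=0.1, seed=42)
        b = simulate_instruments(k=10, theta_true=0.1, seed=42)
        assert a[0] == b[0] and a[1] == b[1]
        np.testing.assert_array_equal(a[2].alpha, b[2].alpha)

    def test_different_seeds_differ(self):
        a, _, _ = simulate_instruments(k=10, seed=1)
        b, _, _ = simulate_instruments(k=10, seed=2)
        assert a != b

    def test_all_exposure_p_genome_wide_significant(self):
        for seed in range(5):
            exp, _, _ = simulate_instruments(k=100, seed=seed)
            assert all(r.pval < 5e-8 for r in exp)

    def test_null_recovery(self):
        s, _ = simulate_instrument_set(k=50, theta_true=0.0, se_y=0.002, seed=0)
        r = ivw(s)
        assert abs(r.beta) < 3 * r.se

    def test_records_and_set_paths_agree(self):
        exp, out, _ = simulate_instruments(k=8, theta_true=0.05, seed=9)
        s, _ = simulate_instrument_set(k=8, theta_true=0.05, seed=9)
        np.testing.assert_allclose([r.beta for r in exp], s.beta_x)
        np.testing.assert_allclose([r.beta for r in out], s.beta_y)

    def test_harmonization_preserves_all_instruments(self):
        exp, out, _ = simulate_instruments(k=25, theta_true=0.1, seed=3)
        s = harmonize(select_significant(exp), out)
        assert s.n_snp == 25

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            simulate_instruments(k=0)

    def test_mean_ivw_estimate_unbiased(self):
        """Generative consistency: the mean IVW estimate over 200 seeds
        stays within 2 SEs of its mean from the generating effect."""
        ests = []
        for seed in range(200):
            s, _ = simulate_instrument_set(k=50, theta_true=0.2,
                                           se_y=0.002, seed=seed)
            ests.append(ivw(s, model="fixed").beta)
        sem = np.std(ests) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.2) < 2 * sem

    def test_outcome_effects_near_unity_odds_ratios(self):
        """At the default outcome scale, simulated outcome ORs stay within
        ~1 +- 0.005 of unity, matching a rare binary trait at biobank n."""
        _, out, _ = simulate_instruments(k=50, theta_true=0.002, seed=5)
        ors = np.exp([r.beta for r in out])
        assert np.all(np.abs(ors - 1.0) < 0.005)


class TestSimulateRegionPair:
    def test_determinism(self):
        a = simulate_region_pair(L=10, n1=500, n2=500, seed=7)
        b = simulate_region_pair(L=10, n1=500, n2=500, seed=7)
        assert a[0] == b[0] and a[1] == b[1]

    def test_ld_matrix_is_ar1(self):
        _, _, ld, _ = simulate_region_pair(L=5, rho=0.8, n1=200, n2=200, seed=0)
        assert math.isclose(ld.r[0, 4], 0.8**4, rel_tol=1e-12)

    def test_zero_rho_gives_identity_ld_and_null_z(self):
        r1, _, ld, truth = simulate_region_pair(
            L=20, rho=0.0, scenario="null", n1=20_000, n2=2000, seed=1)
        np.testing.assert_allclose(ld.r, np.eye(20))
        zs = np.array([r.beta / r.se for r in r1])
        assert np.all(np.abs(zs) < 5)  # no causal SNP, no signal

    def test_shared_scenario_has_common_causal(self):
        _, _, _, truth = simulate_region_pair(scenario="shared", n1=200,
                                              n2=200, seed=3)
        ids = truth.causal_snp_ids
        assert ids["trait1"] == ids["trait2"] is not None

    def test_distinct_scenario_has_different_causals(self):
        _, _, _, truth = simulate_region_pair(scenario="distinct", n1=200,
                                              n2=200, seed=3)
        ids = truth.causal_snp_ids
        assert ids["trait1"] != ids["trait2"]

    def test_causal_snp_is_top_association(self):
        r1, _, _, truth = simulate_region_pair(scenario="shared", seed=2)
        top = min(r1, key=lambda r: r.pval)
        # top hit is the causal SNP or an immediate LD neighbour
        causal_pos = next(r.pos for r in r1 if r.snp_id == truth.causal_snp_ids["trait1"])
        assert abs(top.pos - causal_pos) <= 2000

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_region_pair(L=1)
        with pytest.raises(ValueError):
            simulate_region_pair(rho=1.0)
        with pytest.raises(ValueError):
            simulate_region_pair(scenario="both_ways")


class TestSimulateMediationTriplet:
    def test_determinism(self):
        a = simulate_mediation_triplet(seed=11)
        b = simulate_mediation_triplet(seed=11)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_disjoint_instrument_sets(self):
        _, _, _, truth = simulate_mediation_triplet(k_x=5, k_m=7, seed=0)
        xs = set(truth.causal_snp_ids["exposure_instruments"])
        ms = set(truth.causal_snp_ids["mediator_instruments"])
        assert not xs & ms
        assert len(xs) == 5 and len(ms) == 7

    def test_total_effect_arithmetic(self):
        _, _, _, truth = simulate_mediation_triplet(
            beta_xm=0.2, beta_my=0.3, theta_direct=0.1, seed=0)
        assert math.isclose(truth.theta_true, 0.1 + 0.06)

    def test_instruments_significant_in_own_gwas(self):
        gx, gm, _, truth = simulate_mediation_triplet(k_x=20, k_m=20, seed=4)
        px = {r.snp_id: r.pval for r in gx}
        pm = {r.snp_id: r.pval for r in gm}
        assert all(px[s] < 5e-8 for s in truth.causal_snp_ids["exposure_instruments"])
        assert all(pm[s] < 5e-8 for s in truth.causal_snp_ids["mediator_instruments"])

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            simulate_mediation_triplet(k_x=1)


class TestSimulateProteinPanel:
    def test_structure_and_truth(self):
        exps, outcome, ld, truth = simulate_protein_panel(
            n_proteins=4, causal_proteins={"P02": 0.003}, k=5, seed=0)
        assert set(exps) == {"P01", "P02", "P03", "P04"}
        assert len(outcome) == 4 * 5
        assert truth.theta_true["P02"] == 0.003 and truth.theta_true["P01"] == 0.0

    def test_unknown_causal_name_rejected(self):
        with pytest.raises(ValueError):
            simulate_protein_panel(n_proteins=2, causal_proteins={"P09": 0.1})
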