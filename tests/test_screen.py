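"""Discovery-screen kernels against brute-force oracles, plus cohort runs."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonecall.counts import ALLELE_INDEX, Pileup, SiteCounts
from clonecall.io import manifest_for_simulation
from clonecall.screen import (
    ScreenConfig,
    bh_fdr,
    binomial_site_test,
    contamination_filter,
    estimate_error_rate,
    fisher_one_sided_greater,
    run_screen,
    somatic_fisher_test,
    strand_bias_filter,
)
from clonecall.simulate import SimulationConfig, simulate_pileup_cohort

from oracles import bh_stepup_manual, binom_tail_exact, fisher_greater_exact


def uniform_pileup(sample_id, L, depth, ref_idx=0, mismatches=()):
    """Flat pileup of `depth` ref observations per site, plus explicit
    (pos, allele, strand, count) mismatch injections replacing ref reads."""
    ref = np.full(L, ref_idx, dtype=np.int8)
    counts = np.zeros((L, 4, 2), dtype=np.int64)
    counts[:, ref_idx, 0] = depth // 2
    counts[:, ref_idx, 1] = depth - depth // 2
    for pos, allele, strand, n in mismatches:
        a = ALLELE_INDEX[allele]
        s = {"+": 0, "-": 1}[strand]
        counts[pos, a, s] += n
        counts[pos, ref_idx, s] -= n
    return Pileup(sample_id=sample_id, ref=ref, counts=counts)


class TestErrorModel:
    def test_simple_ratio(self):
        # 10 mismatches in 100,000 observations -> e_hat = 1e-4
        pu = uniform_pileup("s", 1000, 100,
                            mismatches=[(i, "T", "+", 1) for i in range(7)]
                            + [(900, "G", "-", 3)])
        em = estimate_error_rate({"s": pu}, floor=0.0)
        assert em.e_hat == pytest.approx(1e-4)
        assert em.n_bases == 100_000
        assert em.excluded_sites == 0

    def test_zero_mismatch_floor(self):
        pu = uniform_pileup("s", 100, 50)
        assert estimate_error_rate({"s": pu}, floor=0.0).e_hat == 0.0
        assert estimate_error_rate({"s": pu}).e_hat == 1e-6

    def test_germline_sites_excluded(self):
        # a het site (AF 0.5) must not inflate the error estimate
        pu = uniform_pileup("s", 100, 100, mismatches=[(0, "T", "+", 50)])
        em = estimate_error_rate({"s": pu}, germline_af_threshold=0.05,
                                 floor=0.0)
        assert em.excluded_sites == 1
        assert em.e_hat == 0.0

    def test_all_sites_excluded_errors(self):
        pu = uniform_pileup("s", 2, 100, mismatches=[(0, "T", "+", 50),
                                                     (1, "T", "+", 50)])
        with pytest.raises(ValueError, match="excluded"):
            estimate_error_rate({"s": pu})

    def test_simulation_calibration(self):
        e = 1e-4
        cfg = SimulationConfig(n_patients=1, subpopulations=("CD8+", "CD4+"),
                               target_region_length=5000, depth_mean=300,
                               germline_het_rate=0.0, error_rate=e, seed=21)
        pileups, _ = simulate_pileup_cohort(cfg)
        em = estimate_error_rate(pileups)
        sd = np.sqrt(e / em.n_bases)
        assert abs(em.e_hat - e) < 3 * sd


class TestBinomialKernel:
    def test_zero_alt_is_one(self):
        assert binomial_site_test(0, 1000, 1e-4, 4_000_000) == 1.0

    def test_tail_sum_oracle_with_bonferroni(self):
        # k=5 of n=1000 at e_alt = 1e-4/3, corrected by 4e6 tests
        e_alt = Fraction(1, 30000)
        oracle = float(binom_tail_exact(5, 1000, e_alt)) * 4_000_000
        got = binomial_site_test(5, 1000, 1 / 30000, 4_000_000)
        assert got == pytest.approx(min(1.0, oracle), rel=1e-10)

    def test_monotone_decreasing_in_k(self):
        n = 500
        ps = [binomial_site_test(k, n, 1e-3, 2000) for k in range(0, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_site_test(11, 10, 1e-4, 4)

    @pytest.mark.parametrize("k,n,p", [
        (3, 100, 0.001), (2, 50, 0.3), (40, 400, 0.05), (1, 7, 0.5),
    ])
    def test_raw_tail_matches_exact_enumeration(self, k, n, p):
        oracle = float(binom_tail_exact(k, n, Fraction(p).limit_denominator(10**9)))
        assert binomial_site_test(k, n, p, 1) == pytest.approx(oracle, rel=1e-10)


class TestFisherKernel:
    def test_equal_null_proportions(self):
        t = SiteCounts("t", 0, "A", np.array([[500, 500], [0, 0], [0, 0], [0, 0]]))
        c = SiteCounts("c", 0, "A", np.array([[1500, 1500], [0, 0], [0, 0], [0, 0]]))
        assert somatic_fisher_test(t, c, "T") == 1.0

    def test_hypergeometric_tail_oracle(self):
        # 10 alt / 990 ref vs 0 alt / 3000 ref
        got = fisher_one_sided_greater(10, 1000, 0, 3000)
        oracle = float(fisher_greater_exact(10, 1000, 0, 3000))
        assert got == pytest.approx(oracle, rel=1e-10)

    def test_one_sidedness(self):
        enriched = fisher_one_sided_greater(10, 1000, 2, 3000)
        swapped = fisher_one_sided_greater(2, 3000, 10, 1000)
        assert swapped > enriched

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            at, dt = rng.integers(0, 30), rng.integers(50, 400)
            ac, dc = rng.integers(0, 30), rng.integers(50, 400)
            at, ac = min(at, dt), min(ac, dc)
            _, p_ref = stats.fisher_exact(
                [[at, dt - at], [ac, dc - ac]], alternative="greater")
            assert fisher_one_sided_greater(at, dt, ac, dc) == \
                pytest.approx(p_ref, rel=1e-9)

    def test_zero_depth_warns_and_returns_one(self):
        t = SiteCounts("t", 0, "A", np.zeros((4, 2), int))
        c = SiteCounts("c", 0, "A", np.array([[10, 10], [0, 0], [0, 0], [0, 0]]))
        with pytest.warns(UserWarning):
            assert somatic_fisher_test(t, c, "T") == 1.0


class TestStrandBias:
    def site(self, alt_p, alt_m, ref_p=500, ref_m=500):
        counts = np.zeros((4, 2), int)
        counts[ALLELE_INDEX["A"]] = [ref_p, ref_m]
        counts[ALLELE_INDEX["T"]] = [alt_p, alt_m]
        return SiteCounts("s", 0, "A", counts)

    def test_balanced_passes(self):
        assert strand_bias_filter(self.site(5, 5), "T")

    def test_one_sided_evidence_fails(self):
        assert not strand_bias_filter(self.site(10, 0), "T",
                                      min_per_strand=1)

    def test_imbalance_decision_matches_exact_test(self):
        # alt 8+/2- vs ref 500/500: decision from the two-sided exact test
        s = self.site(8, 2)
        _, p = stats.fisher_exact([[8, 2], [500, 500]],
                                  alternative="two-sided")
        assert strand_bias_filter(s, "T", max_imbalance_p=0.001) == (p >= 0.001)


class TestContamination:
    def test_other_patient_het_fails(self):
        other = uniform_pileup("o", 10, 100, mismatches=[(3, "T", "+", 50)])
        assert not contamination_filter(3, "T", [other])

    def test_clean_other_patients_pass(self):
        other = uniform_pileup("o", 10, 100)
        assert contamination_filter(3, "T", [other])

    def test_low_af_other_patient_passes(self):
        other = uniform_pileup("o", 10, 100, mismatches=[(3, "T", "+", 1)])
        assert contamination_filter(3, "T", [other],
                                    germline_af_threshold=0.05)


class TestBH:
    def test_single_small_p(self):
        q, acc = bh_fdr([0.01])
        assert q[0] == pytest.approx(0.01)
        assert acc[0]

    def test_stepup_hand_example(self):
        # 0.04 > 3/4 * 0.05, so only the first two are accepted
        q, acc = bh_fdr([0.001, 0.02, 0.04, 0.9], q_cutoff=0.05)
        assert list(acc) == [True, True, False, False]

    def test_all_ones_rejected(self):
        _, acc = bh_fdr([1.0, 1.0, 1.0])
        assert not acc.any()

    def test_empty(self):
        q, acc = bh_fdr([])
        assert len(q) == 0 and len(acc) == 0

    def test_matches_manual_stepup(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            q, acc = bh_fdr(p, 0.05)
            q_m, acc_m = bh_stepup_manual(p, 0.05)
            np.testing.assert_allclose(q, q_m, rtol=1e-12)
            assert (acc == acc_m).all()


def cohort(clones=(), seed=0, n_patients=2, L=2000, depth=1000):
    cfg = SimulationConfig(
        n_patients=n_patients, subpopulations=("CD4+", "CD8+", "CD19+"),
        target_region_length=L, depth_mean=depth, clone_spec=clones,
        seed=seed)
    pileups, truth = simulate_pileup_cohort(cfg)
    return pileups, truth, manifest_for_simulation(cfg)


class TestRunScreen:
    def test_planted_clone_detected_in_its_subpopulation(self):
        pileups, truth, manifest = cohort([("CD8+", 0.02, 1)], seed=3)
        out = run_screen(pileups, manifest)
        clones = truth[~truth.is_germline]
        acc = out[out.accepted]
        for rec in clones.itertuples():
            hit = acc[(acc.sample_id == rec.sample_id) &
                      (acc.position == rec.position) &
                      (acc.alt_base == rec.alt_base)]
            assert len(hit) == 1

    def test_null_cohort_rarely_accepts(self):
        pileups, _, manifest = cohort(seed=5)
        out = run_screen(pileups, manifest)
        assert out["accepted"].sum() == 0

    def test_germline_like_signal_not_accepted(self):
        # same alt at the same AF in every subpopulation: no contrast
        pileups, _, manifest = cohort(seed=6, n_patients=1, L=500, depth=800)
        for pu in pileups.values():
            a = ALLELE_INDEX["T"] if pu.ref[250] != ALLELE_INDEX["T"] \
                else ALLELE_INDEX["C"]
            take = pu.counts[250, pu.ref[250], :] // 10
            pu.counts[250, a, :] += take
            pu.counts[250, pu.ref[250], :] -= take
        out = run_screen(pileups, manifest)
        at_site = out[(out.position == 250) & out.accepted]
        assert len(at_site) == 0

    def test_manifest_pileup_mismatch_errors(self):
        pileups, _, manifest = cohort(seed=7, n_patients=1, L=300, depth=100)
        manifest = manifest.iloc[:-1]
        with pytest.raises(ValueError, match="disagree"):
            run_screen(pileups, manifest)

    def test_single_sample_patient_skipped(self, caplog):
        pileups, _, manifest = cohort(seed=8, n_patients=1, L=300, depth=100)
        keep = manifest.iloc[:1]
        pileups = {keep.sample_id.iloc[0]: pileups[keep.sample_id.iloc[0]]}
        out = run_screen(pileups, keep)
        assert out.empty

    def test_af_recovery_within_binomial_error(self):
        pileups, truth, manifest = cohort([("CD8+", 0.03, 2)], seed=9)
        out = run_screen(pileups, manifest)
        acc = out[out.accepted]
        merged = acc.merge(
            truth[~truth.is_germline],
            left_on=["sample_id", "position", "alt_base"],
            right_on=["sample_id", "position", "alt_base"])
        assert len(merged) >= 3
        for row in merged.itertuples():
            sd = np.sqrt(row.true_af * (1 - row.true_af) / row.depth)
            assert abs(row.af_target - row.true_af) < 3 * sd

    def test_detection_monotone_in_af_and_depth(self):
        """Detection probability does not decrease with clone AF or depth
        (coarse grid, pooled over replicate cohorts)."""
        afs = [0.005, 0.02, 0.05]
        depths = [250, 1000]
        rate = {}
        for af in afs:
            for depth in depths:
                hits = 0
                n = 6
                for s in range(n):
                    pileups, truth, manifest = cohort(
                        [("CD8+", af, 1)], seed=100 + s, n_patients=1,
                        L=800, depth=depth)
                    out = run_screen(pileups, manifest)
                    rec = truth[~truth.is_germline].iloc[0]
                    acc = out[out.accepted]
                    hits += int(((acc.sample_id == rec.sample_id) &
                                 (acc.position == rec.position)).any())
                rate[(af, depth)] = hits / n
        for depth in depths:
            seq = [rate[(af, depth)] for af in afs]
            assert all(a <= b + 1e-9 for a, b in zip(seq, seq[1:]))
        for af in afs:
            assert rate[(af, 250)] <= rate[(af, 1000)] + 1e-9
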