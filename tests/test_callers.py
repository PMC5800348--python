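"""Depth callers: reference aggregation, dispersion fit, HMM decoding against
exhaustive path enumeration, and the z-score caller."""

import numpy as np
import pytest
from scipy import stats

import panelcnv as p
from panelcnv.callers import (CallerError, CallerParams, _transition_log,
                              bb_logpmf, call_bb_hmm, call_zscore,
                              fit_dispersion, hmm_emissions, select_reference,
                              viterbi)

from ._oracles import best_path_brute_force, loglik_of_path_brute_force


class TestSelectReference:
    def test_exact_copies_all_selected(self, toy_panel):
        rng = np.random.default_rng(0)
        test = rng.poisson(800, len(toy_panel)).astype(np.int64)
        pool = p.CountsMatrix(toy_panel, [f"c{i}" for i in range(5)],
                              np.tile(test[:, None], (1, 5)))
        chosen, agg, solitary = select_reference(test, pool)
        assert sorted(chosen) == [f"c{i}" for i in range(5)]
        assert np.array_equal(agg, test * 5)
        assert not solitary

    def test_test_sample_in_pool_rejected(self, flat_counts):
        test = flat_counts.counts[:, 0]
        with pytest.raises(CallerError, match="own reference pool"):
            select_reference(test, flat_counts, test_id="c00")

    def test_solitary_candidate_flagged(self, toy_panel):
        rng = np.random.default_rng(1)
        test = rng.poisson(500, len(toy_panel)).astype(np.int64)
        pool = p.CountsMatrix(toy_panel, ["only"],
                              rng.poisson(500, (len(toy_panel), 1)).astype(np.int64))
        chosen, agg, solitary = select_reference(test, pool)
        assert chosen == ["only"] and solitary

    def test_ranking_prefers_correlated_candidates(self, toy_panel):
        rng = np.random.default_rng(2)
        profile = rng.uniform(100, 2000, len(toy_panel))
        test = rng.poisson(profile).astype(np.int64)
        scaled = rng.poisson(profile * 2).astype(np.int64)      # corr ~1
        noisy = rng.poisson(profile * rng.uniform(0.5, 1.5, len(toy_panel))).astype(np.int64)
        anti = rng.poisson(profile[::-1]).astype(np.int64)      # uncorrelated profile
        pool = p.CountsMatrix(toy_panel, ["scaled", "noisy", "anti"],
                              np.column_stack([scaled, noisy, anti]))
        chosen, _, _ = select_reference(test, pool)
        # brute-force correlation sort on normalized coverage
        norm = p.normalize_coverage(pool)
        tn = 1e6 * test / test.sum()
        corr = [np.corrcoef(tn, norm[:, i])[0, 1] for i in range(3)]
        expect_order = [pool.sample_ids[i] for i in np.argsort(corr)[::-1]]
        assert chosen == expect_order[: len(chosen)]
        assert chosen[0] == "scaled" and "anti" not in chosen

    def test_empty_pool_rejected(self, toy_panel):
        pool = p.CountsMatrix(toy_panel, [], np.zeros((len(toy_panel), 0), int))
        with pytest.raises(CallerError, match="empty"):
            select_reference(np.ones(len(toy_panel), int), pool)


class TestDispersionFit:
    def test_binomial_data_recovers_zero(self):
        rng = np.random.default_rng(3)
        n = rng.integers(2000, 20_000, size=1000)
        x = rng.binomial(n, 0.1)
        phi = fit_dispersion(x, n - x)
        assert phi < 1e-3

    def test_beta_binomial_parameter_recovery(self):
        rng = np.random.default_rng(4)
        phi_true = 0.02
        a = 0.1 * (1 / phi_true - 1)
        b = 0.9 * (1 / phi_true - 1)
        n = rng.integers(2000, 20_000, size=1000)
        x = rng.binomial(n, rng.beta(a, b, size=1000))
        phi = fit_dispersion(x, n - x)
        assert abs(phi / phi_true - 1) < 0.30

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(CallerError):
            fit_dispersion(np.ones(5, int), np.ones(6, int))

    def test_all_zero_input_rejected(self):
        with pytest.raises(CallerError, match="degenerate"):
            fit_dispersion(np.zeros(10, int), np.zeros(10, int))


class TestEmission:
    def test_phi_zero_equals_binomial_closed_form(self):
        """Beta-binomial emission degenerates to the exact binomial at phi=0."""
        x = np.arange(0, 50)
        n = np.full(50, 120)
        for prob in (0.03, 0.5, 0.91):
            assert np.allclose(bb_logpmf(x, n, prob, 0.0),
                               stats.binom.logpmf(x, n, prob), atol=1e-9, rtol=0)

    def test_single_exon_phi_zero_reduces_to_binomial_lr(self):
        """One-exon panel, phi=0: the call confidence is the binomial
        log10 likelihood ratio plus the transition prior, to 1e-9."""
        panel = p.make_panel("one", 1, 1)
        params = CallerParams()
        test, ref = np.array([250]), np.array([4750])
        p0 = 0.1  # null expectation supplied externally: one exon cannot self-calibrate
        calls = call_bb_hmm(test, ref, panel, params, phi=0.0, p0=p0, sample_id="s")
        assert len(calls) == 1 and calls[0].type == "del"
        odds = p0 / (1 - p0)
        p1 = 0.5 * odds / (0.5 * odds + 1)
        lr = (stats.binom.logpmf(250, 5000, p1) - stats.binom.logpmf(250, 5000, p0)
              + np.log(params.transition_prob) - np.log(1 - 2 * params.transition_prob))
        assert calls[0].confidence == pytest.approx(lr / np.log(10), abs=1e-9)


def _toy_emissions(counts_test, counts_ref):
    return hmm_emissions(np.asarray(counts_test), np.asarray(counts_ref), phi=0.0)


class TestBbHmm:
    def test_proportional_test_yields_no_calls(self, toy_panel):
        lam = np.linspace(200, 2000, len(toy_panel))
        test = lam.astype(np.int64)
        ref = (lam * 10).astype(np.int64)
        assert call_bb_hmm(test, ref, toy_panel, phi=0.0) == []

    def test_six_exon_deletion_matches_exhaustive_enumeration(self):
        panel = p.make_panel("six", 6, 1)
        params = CallerParams()
        ref = np.full(6, 5000)
        test = np.array([500, 500, 250, 250, 500, 500])
        calls = call_bb_hmm(test, ref, panel, params, phi=0.0, sample_id="s")
        assert len(calls) == 1
        call = calls[0]
        assert (call.type, call.exon_start, call.exon_end) == ("del", 2, 4)
        log_emis, _ = _toy_emissions(test, ref)
        log_pi, log_T = _transition_log(params)
        best, _ = best_path_brute_force(log_emis, log_pi, log_T)
        assert best.tolist() == [1, 1, 0, 0, 1, 1]
        assert viterbi(log_emis, log_pi, log_T).tolist() == best.tolist()

    def test_duplication_confidence_matches_oracle_likelihood_ratio(self):
        panel = p.make_panel("six", 6, 1)
        params = CallerParams()
        ref = np.full(6, 5000)
        test = np.array([500, 500, 500, 500, 750, 500])
        calls = call_bb_hmm(test, ref, panel, params, phi=0.0, sample_id="s")
        assert len(calls) == 1 and calls[0].type == "dup"
        assert (calls[0].exon_start, calls[0].exon_end) == (4, 5)
        log_emis, _ = _toy_emissions(test, ref)
        log_pi, log_T = _transition_log(params)
        decoded = np.array([1, 1, 1, 1, 2, 1])
        normal = np.ones(6, dtype=int)
        expected = (loglik_of_path_brute_force(decoded, log_emis, log_pi, log_T)
                    - loglik_of_path_brute_force(normal, log_emis, log_pi, log_T)
                    ) / np.log(10)
        assert calls[0].confidence == pytest.approx(expected, abs=1e-6)

    def test_viterbi_equals_enumeration_on_random_instances(self):
        """Random emission matrices, panels of 2..8 exons."""
        rng = np.random.default_rng(12)
        log_pi, log_T = _transition_log(CallerParams(transition_prob=0.05,
                                                     exit_prob=0.4))
        for _ in range(100):
            n = int(rng.integers(2, 9))
            log_emis = rng.normal(0, 3, size=(n, 3))
            ours = viterbi(log_emis, log_pi, log_T)
            best, best_ll = best_path_brute_force(log_emis, log_pi, log_T)
            got_ll = loglik_of_path_brute_force(ours, log_emis, log_pi, log_T)
            assert got_ll == pytest.approx(best_ll, abs=1e-9)

    def test_calls_do_not_cross_chromosomes(self):
        # two genes on different chromosomes, adjacent in panel order
        targets = (p.ExonTarget("chr1", 100, 200, "A", "NM_A", 1),
                   p.ExonTarget("chr1", 300, 400, "A", "NM_A", 2),
                   p.ExonTarget("chr1", 500, 600, "A", "NM_A", 3),
                   p.ExonTarget("chr2", 100, 200, "B", "NM_B", 1),
                   p.ExonTarget("chr2", 300, 400, "B", "NM_B", 2),
                   p.ExonTarget("chr2", 500, 600, "B", "NM_B", 3))
        panel = p.PanelDesign("x", targets)
        ref = np.full(6, 5000)
        test = np.array([500, 250, 500, 500, 250, 500])
        calls = call_bb_hmm(test, ref, panel, phi=0.0)
        assert len(calls) == 2
        assert {(c.chrom, c.exon_start, c.exon_end) for c in calls} == \
            {("chr1", 1, 2), ("chr2", 4, 5)}

    def test_pool_permutation_does_not_change_output(self, toy_panel):
        rng = np.random.default_rng(6)
        lam = rng.uniform(300, 2500, len(toy_panel))
        cols = rng.poisson(lam[:, None] * rng.uniform(0.8, 1.2, 12)).astype(np.int64)
        test = rng.poisson(lam).astype(np.int64)
        test[5:7] = rng.poisson(lam[5:7] * 0.5)
        ids = [f"r{i}" for i in range(12)]
        pool = p.CountsMatrix(toy_panel, ids, cols)
        perm = rng.permutation(12)
        pool_shuffled = p.CountsMatrix(toy_panel, [ids[i] for i in perm], cols[:, perm])
        out = []
        for pl in (pool, pool_shuffled):
            chosen, agg, _ = select_reference(test, pl)
            out.append((sorted(chosen),
                        call_bb_hmm(test, agg, toy_panel, sample_id="t")))
        assert out[0] == out[1]


class TestZScoreCaller:
    def _pool(self, panel, n, rng, lam):
        cols = rng.poisson(lam[:, None] * np.ones(n)).astype(np.int64)
        return p.CountsMatrix(panel, [f"k{i}" for i in range(n)], cols)

    def test_null_sample_rarely_called(self, toy_panel):
        rng = np.random.default_rng(8)
        lam = np.full(len(toy_panel), 1000.0)
        pool = self._pool(toy_panel, 20, rng, lam)
        fp = sum(bool(call_zscore(rng.poisson(lam).astype(np.int64), pool, toy_panel))
                 for _ in range(50))
        assert fp <= 2  # ratio gate at 0.75/1.25 dominates the z tail mass

    def test_spiked_het_deletion_recovered_with_half_ratio(self, toy_panel):
        rng = np.random.default_rng(9)
        lam = np.full(len(toy_panel), 1000.0)
        pool = self._pool(toy_panel, 20, rng, lam)
        test = rng.poisson(lam).astype(np.int64)
        test[12:14] = rng.poisson(lam[12:14] * 0.5)
        calls = call_zscore(test, pool, toy_panel, sample_id="s")
        assert len(calls) == 1
        assert calls[0].type == "del"
        assert calls[0].exon_start <= 12 and calls[0].exon_end >= 14
        assert calls[0].ratio == pytest.approx(0.5, abs=0.1)

    def test_degenerate_zero_sd_guard(self, toy_panel):
        n = len(toy_panel)
        cols = np.full((n, 6), 400, dtype=np.int64)
        pool = p.CountsMatrix(toy_panel, [f"k{i}" for i in range(6)], cols)
        test = np.full(n, 400, dtype=np.int64)
        assert call_zscore(test, pool, toy_panel) == []

    def test_small_pool_rejected(self, toy_panel):
        cols = np.full((len(toy_panel), 4), 400, dtype=np.int64)
        pool = p.CountsMatrix(toy_panel, list("abcd"), cols)
        with pytest.raises(CallerError, match="control pool"):
            call_zscore(np.full(len(toy_panel), 400), pool, toy_panel)
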