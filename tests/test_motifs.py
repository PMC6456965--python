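"""PWM scanning with exact p-values, enrichment, TF filter, stepwise OLS."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epiland as ep
from epiland.motifs import MotifError, reverse_complement
from conftest import sharp_motif


class TestMemeFormat:
    def test_write_read_round_trip(self, tmp_path):
        spec = ep.MotifSpec()
        models = [m.pwm(np.asarray(spec.background)) for m in spec.motifs]
        path = tmp_path / "motifs.meme"
        ep.write_meme(models, path)
        back = ep.read_meme(path)
        assert [m.motif_id for m in back] == [m.motif_id for m in models]
        assert [m.tf_gene for m in back] == [m.tf_gene for m in models]
        for a, b in zip(models, back):
            # writer rounds to 6 decimals; reader guards zeros with 1e-4
            assert np.allclose(a.matrix, b.matrix, atol=5e-4)
            assert np.allclose(a.background, b.background, atol=1e-6)

    def test_rows_sum_to_one_and_consensus(self):
        m = sharp_motif("ACGTAC")
        assert np.allclose(m.matrix.sum(axis=1), 1.0, atol=1e-6)
        assert m.consensus() == "ACGTAC"

    def test_short_motif_rejected(self):
        with pytest.raises(MotifError):
            ep.MotifModel("x", None, np.full((3, 4), 0.25))

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.meme"
        p.write_text("MEME version 4\n")
        with pytest.raises(MotifError):
            ep.read_meme(p)


class TestScoreDistribution:
    @pytest.mark.parametrize("L,seed", [(4, 0), (5, 1), (6, 2)])
    def test_dp_equals_brute_force_enumeration(self, L, seed):
        # oracle: enumerate all 4^L words under the background
        rng = np.random.default_rng(seed)
        mat = rng.dirichlet([1.0] * 4, size=L)
        bg = rng.dirichlet([2.0] * 4)
        m = ep.MotifModel("t", None, mat, background=bg, pseudocount=0.01)
        g = 1e-6
        dist = ep.pwm_score_distribution(m, granularity=g)
        colbins = np.round(m.log_odds() / g).astype(np.int64)
        brute: dict[int, float] = {}
        for w in itertools.product(range(4), repeat=L):
            k = int(sum(colbins[i, b] for i, b in enumerate(w)))
            p = float(np.prod([bg[b] for b in w]))
            brute[k] = brute.get(k, 0.0) + p
        dp = {int(round(s / g)): p for s, p in zip(dist.scores, dist.probs)}
        assert set(dp) == set(brute)
        for k, v in brute.items():
            assert dp[k] == pytest.approx(v, abs=1e-9)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_tail_p_extremes(self):
        m = sharp_motif("ACGT")
        dist = ep.pwm_score_distribution(m, granularity=1e-5)
        assert dist.tail_p(dist.scores[0]) == pytest.approx(1.0, abs=1e-12)
        assert dist.tail_p(dist.scores[-1] + 1.0) == 0.0

    def test_threshold_attained_p(self):
        m = sharp_motif("ACGTACGT")
        dist = ep.pwm_score_distribution(m, granularity=1e-5)
        thr, attained = dist.threshold_for_p(1e-3)
        assert attained <= 1e-3
        assert dist.tail_p(thr) == pytest.approx(attained, rel=1e-9)

    def test_too_coarse_granularity_rejected(self):
        m = sharp_motif("ACGTACGT")
        with pytest.raises(MotifError, match="finer"):
            ep.pwm_score_distribution(m, granularity=0.4)


class TestScan:
    def test_consensus_found_once_forward(self):
        m = sharp_motif("TGACCTTG")
        seq = "A" * 30 + "TGACCTTG" + "C" * 30
        hits = ep.pwm_scan(seq, m, p_threshold=1e-4)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].start == 30
        assert fwd[0].p <= 1e-4

    def test_threshold_below_minimum_gives_no_hits(self):
        m = sharp_motif("ACGTAC")
        dist = ep.pwm_score_distribution(m, granularity=1e-5)
        p_min = dist.probs[-1]  # exact p of the best score
        hits = ep.pwm_scan("ACGTAC" * 20, m, p_threshold=p_min / 10)
        assert hits == []

    def test_sequence_shorter_than_motif(self):
        m = sharp_motif("ACGTACGT")
        assert ep.pwm_scan("ACG", m, 1e-3) == []

    def test_windows_with_n_skipped(self):
        m = sharp_motif("TGACCTTG")
        seq = "TGACNTTG" + "A" * 20 + "TGACCTTG"
        hits = ep.pwm_scan(seq, m, p_threshold=1e-4)
        assert all(h.start == 28 for h in hits if h.strand == "+")

    def test_null_hit_rate_matches_exact_p(self):
        # Monte Carlo oracle: on random background sequence the per-window
        # hit probability equals the attained p; total hits over many
        # sequences stay inside exact binomial 99.9% bounds
        m = sharp_motif("TGACCTTG", dominant=0.85)
        dist = ep.pwm_score_distribution(m, granularity=1e-3)
        _, attained = dist.threshold_for_p(1e-3)
        rng = np.random.default_rng(0)
        n_seq, seq_len = 60, 1001
        L = m.length
        n_windows = 2 * (seq_len - L + 1) * n_seq
        total = 0
        for _ in range(n_seq):
            seq = "".join(rng.choice(list("ACGT"), size=seq_len))
            total += len(ep.pwm_scan(seq, m, p_threshold=1e-3, dist=dist))
        lo = stats.binom.ppf(5e-4, n_windows, attained)
        hi = stats.binom.ppf(1 - 5e-4, n_windows, attained)
        assert lo <= total <= hi


class TestCountMotifs:
    def test_two_planted_sites(self):
        m = sharp_motif("TGACCTTG")
        seq = "A" * 10 + "TGACCTTG" + "C" * 10 + "TGACCTTG" + "G" * 10
        counts = ep.count_motifs({"g1": seq}, None, [m], p_threshold=1e-4)
        assert counts.loc["g1", m.motif_id] == 2

    def test_palindrome_counted_on_both_strands(self):
        pal = "TGACGTCA"  # reverse complement of itself
        assert reverse_complement(pal) == pal
        m = sharp_motif(pal)
        seq = "A" * 20 + pal + "C" * 20
        counts = ep.count_motifs({"g1": seq}, None, [m], p_threshold=1e-4)
        assert counts.loc["g1", m.motif_id] == 2

    def test_strand_symmetry(self):
        rng = np.random.default_rng(4)
        motifs = [sharp_motif("TGACCTTG"), sharp_motif("GCGTGGGCG")]
        seqs = {
            f"g{i}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(6)
        }
        fwd = ep.count_motifs(seqs, None, motifs, p_threshold=1e-3)
        rc = {g: reverse_complement(s) for g, s in seqs.items()}
        rev = ep.count_motifs(rc, None, motifs, p_threshold=1e-3)
        assert fwd.equals(rev)

    def test_empty_motif_list(self):
        counts = ep.count_motifs({"g1": "ACGT" * 20}, None, [], p_threshold=1e-3)
        assert counts.shape == (1, 0)

    def test_missing_sequence_listed(self):
        w = [ep.PromoterWindow(gene="gX", chrom="chr9", start=0, end=1001)]
        with pytest.raises(MotifError, match="gX"):
            ep.count_motifs(w, {"other": "ACGT"}, [sharp_motif("ACGTAC")])


class TestWindows:
    def test_tss_centered_windows_both_strands(self):
        bed = pd.DataFrame(
            [
                ["chr2L", 5000, 7000, "gPlus", 0, "+"],
                ["chr2L", 5000, 7000, "gMinus", 0, "-"],
            ],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        wins = ep.tss_windows(bed)
        plus, minus = wins
        assert (plus.start, plus.end) == (4500, 5501)
        assert (minus.start, minus.end) == (6499, 7500)
        assert plus.end - plus.start == 1001

    def test_clipping_at_contig_edge_flagged(self):
        bed = pd.DataFrame(
            [["chrX", 100, 400, "gEdge", 0, "+"]],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
        (w,) = ep.tss_windows(bed)
        assert w.start == 0 and w.clipped


class TestEnrichment:
    def _counts(self, carriers_test, carriers_ctrl, n=10):
        genes = [f"t{i}" for i in range(n)] + [f"c{i}" for i in range(n)]
        vals = [1] * carriers_test + [0] * (n - carriers_test)
        vals += [1] * carriers_ctrl + [0] * (n - carriers_ctrl)
        return genes[:n], genes, pd.DataFrame({"m": vals}, index=genes)

    def test_hand_hypergeometric_tail(self):
        # 8/10 carriers in test vs 2/10 in control: upper tail of
        # Hypergeom(pop 20, successes 10, draws 10) at >= 8, enumerated
        cluster, universe, counts = self._counts(8, 2)
        res = ep.enrich_cluster_motifs(cluster, universe, counts, seed=0)
        from math import comb

        expect = sum(comb(10, i) * comb(10, 10 - i) for i in (8, 9, 10)) / comb(20, 10)
        assert res[0].raw_p == pytest.approx(expect, rel=1e-12)

    def test_equal_prevalence_not_enriched(self):
        cluster, universe, counts = self._counts(5, 5)
        res = ep.enrich_cluster_motifs(cluster, universe, counts, seed=0)
        assert res[0].raw_p >= 0.5 and not res[0].enriched

    def test_threshold_is_strict(self):
        r = ep.motifs.EnrichmentResult(
            cluster=1, motif_id="m", test_genes_with_site=1,
            control_genes_with_site=0, test_total_sites=1, control_total_sites=0,
            n_test=1, n_control=1, raw_p=1e-9, adjusted_p=1e-9,
        )
        assert not r.enriched  # adjusted p = 1e-9 misses the 1e-10 cutoff
        r2 = ep.motifs.EnrichmentResult(
            cluster=1, motif_id="m", test_genes_with_site=1,
            control_genes_with_site=0, test_total_sites=1, control_total_sites=0,
            n_test=1, n_control=1, raw_p=1e-11, adjusted_p=1e-11,
        )
        assert r2.enriched

    def test_super_uniform_under_permutation(self):
        # random cluster labels: enrichment p should not be anti-conservative
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(200)]
        counts = pd.DataFrame(
            {"m1": rng.poisson(0.8, 200), "m2": rng.poisson(1.5, 200)}, index=genes
        )
        hits = 0
        n_perm = 400
        for i in range(n_perm):
            cluster = list(rng.choice(genes, size=60, replace=False))
            res = ep.enrich_cluster_motifs(cluster, genes, counts, seed=1000 + i)
            hits += sum(r.raw_p < 0.05 for r in res)
        assert hits / (2 * n_perm) < 0.07

    def test_cluster_equals_universe_rejected(self):
        genes = ["a", "b"]
        counts = pd.DataFrame({"m": [1, 0]}, index=genes)
        with pytest.raises(MotifError):
            ep.enrich_cluster_motifs(genes, genes, counts, seed=0)

    def test_adjusted_at_least_raw(self):
        cluster, universe, counts = self._counts(7, 3)
        counts["m2"] = 0
        counts.loc[cluster, "m2"] = 1
        res = ep.enrich_cluster_motifs(cluster, universe, counts, seed=0)
        for r in res:
            assert r.adjusted_p >= r.raw_p


class TestFilterTfs:
    def _fc(self, mapping):
        gh = pd.Series({g: v for g, (v, _) in mapping.items()})
        sh = pd.Series({g: v2 for g, (_, v2) in mapping.items()})
        return ep.fold_changes(gh, sh, pseudocount=1e-9)

    def test_filter_rules(self):
        motifs = [
            sharp_motif("TGACCTTG"),  # tf_gene "tf" placeholder, replaced below
        ]
        m_up = ep.MotifModel("m_up", "cbt", motifs[0].matrix)
        m_low = ep.MotifModel("m_low", "slow", motifs[0].matrix)
        m_out = ep.MotifModel("m_out", "ghost", motifs[0].matrix)
        m_un = ep.MotifModel("m_un", None, motifs[0].matrix)
        fc = self._fc({"cbt": (1.94, 1.0), "slow": (1.2, 1.0), "ghost": (3.0, 1.0)})
        short = ep.filter_tfs(
            [m_up, m_low, m_out, m_un], expressed_genes=["cbt", "slow"], fc=fc
        )
        assert short.tf_genes == ["cbt"]  # 94% change, expressed
        assert "m_low" in short.dropped_low_change  # 20% change
        assert "m_out" in short.dropped_not_expressed
        assert short.unmapped == ["m_un"]

    def test_motifs_collapse_to_tf(self):
        base = sharp_motif("TGACCTTG").matrix
        m1 = ep.MotifModel("m1", "Hr38", base)
        m2 = ep.MotifModel("m2", "Hr38", base)
        fc = self._fc({"Hr38": (2.0, 1.0)})
        short = ep.filter_tfs([m1, m2], ["Hr38"], fc)
        assert short.kept == {"Hr38": ["m1", "m2"]}


class TestStepwise:
    def test_noiseless_recovery_exact(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.poisson(2.0, size=(50, 2)).astype(float), columns=["x1", "x2"]
        )
        y = 2.0 * X["x1"] - 3.0 * X["x2"]
        res = ep.stepwise_fit(y, X, group_name="noiseless")
        coefs = dict(zip(res.retained["predictor"], res.retained["coef"]))
        assert coefs["x1"] == pytest.approx(2.0, abs=1e-8)
        assert coefs["x2"] == pytest.approx(-3.0, abs=1e-8)
        assert res.r == pytest.approx(1.0, abs=1e-8)
        signs = dict(zip(res.retained["predictor"], res.retained["sign"]))
        assert signs == {"x1": "+", "x2": "-"}

    def test_null_type_i_retention_near_alpha(self):
        # per-predictor retention under the null tracks alpha; a large
        # majority of runs drop everything (backward selection keeps the
        # minimum of ~5 p-values, so "all removed" stays below 1 - alpha)
        rng = np.random.default_rng(1)
        n_trials, retained_total, all_removed = 200, 0, 0
        for _ in range(n_trials):
            X = pd.DataFrame(rng.poisson(1.2, size=(100, 5)),
                             columns=list("abcde"))
            y = pd.Series(rng.normal(size=100))
            est = ep.StepwiseLinearRegression().fit(X, y)
            retained_total += len(est.retained_)
            all_removed += len(est.retained_) == 0
        per_predictor = retained_total / (n_trials * 5)
        assert 0.02 <= per_predictor <= 0.08
        assert all_removed / n_trials >= 0.70

    def test_planted_signs_recovered(self):
        spec = ep.MotifSpec()
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            counts, log_fc = ep.gen_motif_counts(spec, 300, seed=seed)
            res = ep.stepwise_fit(log_fc, counts)
            signs = dict(zip(res.retained["predictor"], res.retained["sign"]))
            want = {m.motif_id: ("+" if m.coefficient > 0 else "-")
                    for m in spec.motifs}
            hits += all(signs.get(k, "").strip("()") == v for k, v in want.items())
        assert hits / n_seeds >= 0.95

    def test_marginal_band_annotation(self):
        # with drop_alpha=0.10 a predictor with 0.05 <= p < 0.10 is kept
        # and rendered with a parenthesised sign
        rng = np.random.default_rng(12)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
            y = 1.0 * X["a"] + 0.22 * X["b"] + rng.normal(size=60)
            est = ep.StepwiseLinearRegression(alpha=0.05, drop_alpha=0.10).fit(X, y)
            if "b" in est.retained_ and 0.05 <= dict(
                zip(est.retained_, est.pvalues_)
            )["b"] < 0.10:
                assert est.signs_["b"] == "(+)"
                break
        else:  # pragma: no cover
            pytest.fail("no marginal case produced in 50 seeds")

    def test_collinear_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=40)})
        X["b"] = 2.0 * X["a"]
        y = X["a"] + rng.normal(0, 0.1, size=40)
        with pytest.warns(UserWarning, match="collinear"):
            est = ep.StepwiseLinearRegression().fit(X, y)
        assert est.dropped_collinear_ == ["b"]
        assert est.retained_ == ["a"]

    def test_r2_monotone_under_elimination(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        y = X["a"] * 0.8 + rng.normal(size=80)
        import statsmodels.api as sm

        full = sm.OLS(y, sm.add_constant(X)).fit()
        est = ep.StepwiseLinearRegression().fit(X, y)
        assert est.r_ ** 2 <= full.rsquared + 1e-12
        if est.retained_:
            final = sm.OLS(y, sm.add_constant(X[est.retained_])).fit()
            assert est.r_ == pytest.approx(np.sqrt(final.rsquared), abs=1e-12)

    def test_too_few_observations_rejected(self):
        X = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            ep.StepwiseLinearRegression().fit(X, np.ones(5))

    def test_aic_mode_runs(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(size=60)
        est = ep.StepwiseLinearRegression(criterion="aic").fit(X, y)
        assert "a" in est.retained_
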