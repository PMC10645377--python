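"""Signature scoring: ssGSEA oracle agreement, z-scaling, phenotype
quadrants, the correlation screen and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from b7h3adc.expression import ExpressionMatrix, Scale
from b7h3adc.signatures import (GeneSet, SignatureScores, call_phenotype,
                                correlate_with_response, group_compare,
                                score_signatures, ssgsea_score, z_transform)


def expr_matrix(arr, genes=None, samples=None, scale=Scale.LOG2_CPM):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(values=pd.DataFrame(arr, index=genes,
                                                columns=samples), scale=scale)


def ssgsea_oracle(values, gene_names, set_genes, alpha):
    """Direct summation of the weighted running-sum formula for one
    sample, written independently of the implementation (explicit loop,
    dict-based average ranks)."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    # average ranks for ties, 1-based
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    in_set = [g in set_genes for g in gene_names]
    # walk from highest expression down
    walk = sorted(range(n), key=lambda i: -ranks[i])
    denom_in = sum(abs(ranks[i]) ** alpha for i in walk if in_set[i])
    n_out = sum(1 for f in in_set if not f)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for i in walk:
        if in_set[i]:
            cum_in += abs(ranks[i]) ** alpha / denom_in
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


class TestSsgseaScore:
    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            n_genes, n_samples = 10, 6
            vals = rng.normal(size=(n_genes, n_samples))
            if trial % 3 == 0:  # exercise tie handling
                vals = np.round(vals, 1)
            genes = [f"g{i}" for i in range(n_genes)]
            set_genes = set(rng.choice(genes, size=3, replace=False))
            m = expr_matrix(vals, genes=genes)
            gs = GeneSet("toy", frozenset(set_genes))
            scores = ssgsea_score(m, gs, alpha=0.25, normalize=False)
            expected = [ssgsea_oracle(vals[:, j].tolist(), genes, set_genes,
                                      0.25) for j in range(n_samples)]
            assert np.allclose(scores.to_numpy(), expected, atol=1e-12)

    def test_top_ranked_set_attains_cohort_maximum(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(20, 5))
        genes = [f"g{i}" for i in range(20)]
        set_genes = frozenset(genes[:4])
        vals[:4, 2] = vals.max() + np.arange(4, 0, -1)  # top-4 in sample 2
        scores = ssgsea_score(expr_matrix(vals, genes=genes),
                              GeneSet("top", set_genes))
        assert scores.idxmax() == "s2"

    def test_rank_invariance_under_exp(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(15, 4))
        gs = GeneSet("s", frozenset(["g1", "g5", "g9"]))
        a = ssgsea_score(expr_matrix(vals), gs)
        b = ssgsea_score(expr_matrix(np.exp(vals)), gs)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_too_few_present_genes_rejected_with_name(self):
        m = expr_matrix(np.ones((5, 2)) * np.arange(5)[:, None])
        with pytest.raises(ValueError, match="absent_set"):
            ssgsea_score(m, GeneSet("absent_set", frozenset(["x1", "x2"])))

    def test_set_covering_all_genes_rejected(self):
        m = expr_matrix(np.arange(10).reshape(5, 2))
        gs = GeneSet("all", frozenset(f"g{i}" for i in range(5)))
        with pytest.raises(ValueError, match="complement"):
            ssgsea_score(m, gs)

    def test_cohort_range_normalization(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(30, 8))
        gs = GeneSet("s", frozenset(["g0", "g3", "g7", "g11"]))
        raw = ssgsea_score(expr_matrix(vals), gs, normalize=False)
        norm = ssgsea_score(expr_matrix(vals), gs, normalize=True)
        rng_ = raw.max() - raw.min()
        assert np.allclose(norm.to_numpy(), raw.to_numpy() / rng_)


class TestZTransform:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(4)
        raw = pd.DataFrame(rng.normal(size=(3, 12)),
                           index=["a", "b", "c"])
        z = z_transform(SignatureScores(raw_scores=raw)).z_scores
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_two_samples_give_plus_minus_invroot2(self):
        raw = pd.DataFrame([[1.0, 3.0]], index=["sig"])
        z = z_transform(SignatureScores(raw_scores=raw)).z_scores
        assert np.allclose(sorted(z.loc["sig"]), [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_rank_order_preserved(self):
        raw = pd.DataFrame([[5.0, 1.0, 3.0, 2.0]], index=["sig"])
        z = z_transform(SignatureScores(raw_scores=raw)).z_scores
        assert (np.argsort(z.loc["sig"].to_numpy())
                == np.argsort(raw.loc["sig"].to_numpy())).all()

    def test_zero_variance_signature_named(self):
        raw = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                           index=["flat_sig", "ok"])
        with pytest.raises(ValueError, match="flat_sig"):
            z_transform(SignatureScores(raw_scores=raw))


class TestCallPhenotype:
    @pytest.mark.parametrize("ar,ne,expected", [
        (2.0, -2.0, "ARPC"),
        (-2.0, 2.0, "SCNPC"),
        (-2.0, -2.0, "DNPC"),
        (2.0, 2.0, "amphicrine"),
        (0.0, 0.0, "DNPC"),  # cutoffs are strict: 0 is not positive
    ])
    def test_quadrants(self, ar, ne, expected):
        assert call_phenotype(ar, ne) == expected

    def test_configurable_cutoffs(self):
        assert call_phenotype(0.5, -1.0, ar_cutoff=1.0) == "DNPC"


class TestCorrelateWithResponse:
    def _scores(self, mat, samples):
        raw = pd.DataFrame(mat, columns=samples)
        raw.index = [f"sig{i}" for i in range(raw.shape[0])]
        return SignatureScores(raw_scores=raw)

    def test_perfect_negative_monotone_gives_minus_one(self):
        samples = [f"m{i}" for i in range(8)]
        nauc = pd.Series(np.linspace(0.2, 1.0, 8), index=samples)
        scores = self._scores([-nauc.to_numpy(), np.random.default_rng(0)
                               .normal(size=8)], samples)
        out = correlate_with_response(nauc, z_transform(scores))
        row = out[out["signature"] == "sig0"].iloc[0]
        assert row["coefficient"] == pytest.approx(-1.0)

    def test_bh_adjustment_matches_hand_computation(self):
        # p = (.01,.02,.03,.04) over 4 tests -> BH all 0.04
        p = np.array([0.01, 0.02, 0.03, 0.04])
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(p, method="fdr_bh")[1]
        # hand BH on sorted p: adj_i = min_{j >= i} p_j * n / (j+1)
        hand = [min(p[j] * 4 / (j + 1) for j in range(i, 4)) for i in range(4)]
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(adj, hand)

    def test_constant_signature_reported_but_excluded_from_fdr(self):
        samples = [f"m{i}" for i in range(6)]
        nauc = pd.Series(np.linspace(0.2, 1.0, 6), index=samples)
        rng = np.random.default_rng(1)
        raw = pd.DataFrame([np.ones(6), rng.normal(size=6)],
                           index=["const", "ok"], columns=samples)
        out = correlate_with_response(nauc, SignatureScores(raw_scores=raw))
        const_row = out[out["signature"] == "const"].iloc[0]
        assert np.isnan(const_row["coefficient"])
        assert np.isnan(const_row["fdr"])

    def test_null_calibration_of_fdr_positive_fraction(self):
        # permuted scores: fraction of signatures at FDR <= 0.05 should
        # average below 0.05 across seeds
        n_models, n_sigs = 20, 100
        samples = [f"m{i}" for i in range(n_models)]
        fracs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            nauc = pd.Series(rng.uniform(0.2, 1.0, n_models), index=samples)
            raw = pd.DataFrame(rng.normal(size=(n_sigs, n_models)),
                               columns=samples)
            raw.index = [f"sig{i}" for i in range(n_sigs)]
            out = correlate_with_response(nauc,
                                          SignatureScores(raw_scores=raw))
            fracs.append(out["significant"].mean())
        assert np.mean(fracs) < 0.05

    def test_too_few_shared_models_rejected(self):
        nauc = pd.Series([0.5, 0.6], index=["m0", "m1"])
        raw = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 2)),
                           columns=["m0", "m1"], index=["a", "b"])
        with pytest.raises(ValueError, match="4 models"):
            correlate_with_response(nauc, SignatureScores(raw_scores=raw))


class TestGroupCompare:
    def test_exact_rank_sum_p_for_extreme_3v3(self):
        values = pd.Series([1, 2, 3, 10, 11, 12], dtype=float)
        groups = pd.Series(["a", "a", "a", "b", "b", "b"])
        out = group_compare(values, groups)
        # most extreme of C(6,3)=20 arrangements, two-sided: p = 2/20
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        values = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        out = group_compare(values, groups)
        assert out["p_holm"].iloc[0] == 1.0

    def test_holm_matches_hand_computation_three_groups(self):
        rng = np.random.default_rng(2)
        values = pd.Series(np.concatenate([
            rng.normal(0, 1, 5), rng.normal(3, 1, 5), rng.normal(0.5, 1, 5)]))
        groups = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        out = group_compare(values, groups).sort_values("p").reset_index(drop=True)
        p = out["p"].to_numpy()
        # hand Holm on ascending p: adj_i = max_{j <= i} min((n-j) p_j, 1)
        hand = np.maximum.accumulate(np.minimum((3 - np.arange(3)) * p, 1.0))
        assert np.allclose(out["p_holm"].to_numpy(), hand)

    def test_small_group_excluded_with_warning(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 9.0])
        groups = pd.Series(["a", "a", "a", "b", "b", "c"])
        with pytest.warns(UserWarning, match="c"):
            out = group_compare(values, groups)
        assert set(out["group1"]) | set(out["group2"]) == {"a", "b"}
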