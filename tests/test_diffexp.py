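"""Normalization, dispersion estimation, the Wald test and BH adjustment
against hand-computed and simulation oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sigdepth as sd
from sigdepth.diffexp import ALPHA_FLOOR


def _matrix(values, groups=None):
    arr = np.asarray(values)
    n = arr.shape[1]
    groups = groups or ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return sd.CountMatrix(
        gene_ids=[f"g{i}" for i in range(arr.shape[0])],
        sample_ids=[f"s{j}" for j in range(n)],
        counts=arr,
        groups=groups,
    )


class TestRleSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _matrix(np.tile([[5], [9], [2]], (1, 4)))
        np.testing.assert_allclose(sd.rle_size_factors(cm), np.ones(4))

    def test_hand_example_median_of_ratios(self):
        # geometric means (2.83, 11.3, 5.66); every ratio in column 1 is
        # 1/sqrt(2) and in column 2 sqrt(2); geometric mean already 1
        cm = _matrix([[2, 4], [8, 16], [4, 8]], groups=["A", "B"])
        s = sd.rle_size_factors(cm)
        np.testing.assert_allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=(50, 4)) + 1
        s0 = sd.rle_size_factors(_matrix(base))
        scaled = base.copy()
        scaled[:, 2] *= 5
        s1 = sd.rle_size_factors(_matrix(scaled))
        np.testing.assert_allclose(
            (s1[2] / s1[0]) / (s0[2] / s0[0]), 5.0, rtol=1e-9
        )

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        cm = _matrix(rng.poisson(50, size=(100, 6)) + 1)
        s = sd.rle_size_factors(cm)
        assert abs(np.exp(np.mean(np.log(s))) - 1.0) < 1e-6

    def test_no_reference_gene_is_normalization_error(self):
        cm = _matrix([[0, 5, 5, 5], [5, 0, 5, 5]])
        with pytest.raises(sd.NormalizationError):
            sd.rle_size_factors(cm)


class TestEstimateDispersions:
    def test_poisson_gene_near_floor(self):
        rng = np.random.default_rng(3)
        cm = _matrix(rng.poisson(500, size=(300, 200)))
        alpha = sd.estimate_dispersions(cm, np.ones(200))
        # Poisson: var = mean, so MoM alpha scatters around 0 and truncates
        assert np.median(alpha) < 0.01

    def test_nb_mom_consistency_large_n(self):
        rng = np.random.default_rng(4)
        true_alpha, mu, n = 0.2, 200.0, 200
        r = 1 / true_alpha
        counts = rng.negative_binomial(r, r / (r + mu), size=(200, 2 * n))
        cm = _matrix(counts)
        alpha = sd.estimate_dispersions(cm, np.ones(2 * n))
        assert abs(alpha.mean() - true_alpha) < 0.05

    def test_constant_gene_gets_floor(self):
        cm = _matrix(np.vstack([np.full(6, 40), np.full(6, 7)]))
        alpha = sd.estimate_dispersions(cm, np.ones(6))
        np.testing.assert_allclose(alpha, ALPHA_FLOOR)

    def test_requires_two_samples_per_group(self):
        cm = _matrix([[1, 2], [3, 4]], groups=["A", "B"])
        with pytest.raises(sd.ContrastError):
            sd.estimate_dispersions(cm, np.ones(2))


class TestWaldTest:
    def test_both_group_means_zero_convention(self):
        counts = np.array([[0, 0, 0, 0], [10, 11, 9, 12]])
        cm = _matrix(counts)
        de = sd.wald_de_test(cm, np.ones(4), np.full(2, 0.1))
        assert de.p_value[0] == 1.0 and de.lfc[0] == 0.0

    def test_planted_sign_recovery(self):
        # lfc = +2 planted genes: the sign is recovered essentially always
        hits = total = 0
        for seed in range(3):
            cfg = sd.SimConfig(seed=seed)
            cm, truth = sd.generate_counts(cfg)
            de = sd.run_de(cm)
            lfc = dict(zip(de.gene_ids, de.lfc))
            strong = {
                g: b for g, b in truth.de_genes.items()
                if cm.counts[cm.gene_ids.index(g)].mean() > 5
            }
            hits += sum(np.sign(lfc[g]) == np.sign(b) for g, b in strong.items())
            total += len(strong)
        assert hits / total > 0.95

    def test_padj_dominates_p(self, default_study):
        _, counts, _, _ = default_study
        de = sd.run_de(counts)
        assert np.all(de.padj >= de.p_value - 1e-12)


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            sd.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_value_identity(self):
        np.testing.assert_allclose(sd.bh_adjust(np.array([0.04])), [0.04])

    def test_all_ones_boundary(self):
        np.testing.assert_allclose(sd.bh_adjust(np.ones(5)), np.ones(5))

    def test_domain(self):
        with pytest.raises(sd.DomainError):
            sd.bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(sd.DomainError):
            sd.bh_adjust(np.array([0.5, 1.2]))

    @staticmethod
    def brute_force(p):
        # padj_i = min over thresholds t in {p_j : p_j >= p_i} of
        # min(1, m * t / #{j : p_j <= t}) — the step-up definition evaluated
        # literally, O(m^2)
        p = np.asarray(p)
        m = p.size
        out = np.empty(m)
        for i in range(m):
            cands = [
                min(1.0, m * t / (p <= t).sum()) for t in p[p >= p[i]]
            ]
            out[i] = min(cands)
        return out

    @given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1, max_size=30))
    def test_matches_brute_force_definition(self, p_list):
        p = np.asarray(p_list)
        np.testing.assert_allclose(sd.bh_adjust(p), self.brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 200))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(sd.bh_adjust(p), expected, atol=1e-12)


class TestBuildSignature:
    def _de(self, p, lfc):
        p = np.asarray(p, dtype=float)
        lfc = np.asarray(lfc, dtype=float)
        n = p.size
        return sd.DEResult(
            gene_ids=[f"g{i:03d}" for i in range(n)],
            base_mean=np.full(n, 10.0),
            lfc=lfc,
            se=np.ones(n),
            p_value=p,
            padj=p,  # already "adjusted" for these unit tests
            size_factors=np.ones(4),
            dispersions=np.full(n, 0.1),
        )

    def test_cap_keeps_smallest_pvalues(self):
        n = 300
        p = np.linspace(1e-6, 1e-3, n)
        de = self._de(p, np.full(n, 2.0))
        sig = sd.build_signature(de, sd.SignatureFilter(max_per_direction=100))
        assert len(sig.up) == 100 and len(sig.down) == 0
        retained_p = sorted(p[:100])
        assert max(de.p_value[[de.gene_ids.index(g) for g in sig.up]]) <= retained_p[-1]

    def test_tie_break_prefers_larger_lfc(self):
        de = self._de([1e-4, 1e-4], [1.5, 3.0])
        sig = sd.build_signature(de, sd.SignatureFilter(max_per_direction=1))
        assert sig.up == {"g001"}

    def test_direction_split_and_thresholds(self):
        de = self._de([1e-4, 1e-4, 0.5, 1e-4], [2.0, -2.0, 3.0, 0.5])
        sig = sd.build_signature(de, sd.SignatureFilter())
        assert sig.up == {"g000"} and sig.down == {"g001"}

    def test_empty_signature_flagged_not_raised(self):
        de = self._de([0.9, 0.8], [0.1, -0.1])
        sig = sd.build_signature(de, sd.SignatureFilter())
        assert sig.is_empty

    def test_deg_count_monotone_in_thresholds(self, default_study):
        _, counts, _, _ = default_study
        de = sd.run_de(counts)

        def n_deg(alpha, lfc_min):
            return int(((de.padj <= alpha) & (np.abs(de.lfc) >= lfc_min)).sum())

        for a1, a2 in [(0.01, 0.05), (0.05, 0.1)]:
            assert n_deg(a1, 1.0) <= n_deg(a2, 1.0)
        for l1, l2 in [(2.0, 1.0), (1.0, 0.5)]:
            assert n_deg(0.05, l1) <= n_deg(0.05, l2)
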