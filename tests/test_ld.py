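"""Haplotype-frequency EM, r-squared, pair significance and LOESS decay."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wheatpopgen.io import MISSING
from wheatpopgen.ld import (critical_r2_per_genome, fit_ld_decay,
                            haplotype_freqs_em, ld_r2, ld_scan,
                            ld_significance, round_haplotype_counts,
                            summarize_ld)

from .conftest import make_matrix, small_map


class TestHaplotypeEM:
    def test_homozygous_covarying_panel(self):
        a = np.array([0, 0, 2, 2, 0, 2], dtype=np.int8)
        f = haplotype_freqs_em(a, a)
        np.testing.assert_allclose(f, [0.5, 0, 0, 0.5], atol=1e-12)

    def test_no_double_hets_equals_direct_count(self, rng):
        # random panel avoiding the (1,1) genotype: phase is certain
        for _ in range(10):
            a = rng.choice([0, 1, 2], size=30).astype(np.int8)
            b = rng.choice([0, 2], size=30).astype(np.int8)
            if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                continue
            f = haplotype_freqs_em(a, b)
            # brute-force haplotype count: genotype pairs resolve uniquely
            counts = np.zeros(4)
            for ga, gb in zip(a, b):
                for copy in range(2):
                    ha = (1 if copy < ga else 0) if ga != 1 else copy
                    hb = (1 if copy < gb else 0) if gb != 1 else copy
                    counts[2 * ha + hb] += 1
            # the unique-phase resolution above pairs het copies in order,
            # which matches EM only when at most one locus is het per sample
            np.testing.assert_allclose(f, counts / counts.sum(), atol=1e-9)

    def test_double_het_only_input_converges_to_independence(self):
        a = np.ones(10, dtype=np.int8)
        f = haplotype_freqs_em(a, a)
        D, r2 = ld_r2(f)
        assert D == pytest.approx(0.0, abs=1e-9)

    def test_monomorphic_pair_rejected(self):
        a = np.zeros(10, dtype=np.int8)
        b = np.array([0, 2] * 5, dtype=np.int8)
        with pytest.raises(ValueError, match="monomorphic"):
            haplotype_freqs_em(a, b)


class TestR2:
    def test_complete_coupling(self):
        D, r2 = ld_r2([0.5, 0, 0, 0.5])
        assert r2 == pytest.approx(1.0)

    def test_independence(self):
        D, r2 = ld_r2([0.25, 0.25, 0.25, 0.25])
        assert D == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        D, r2 = ld_r2([0.4, 0.1, 0.1, 0.4])
        assert D == pytest.approx(0.15)
        assert r2 == pytest.approx(0.36)

    def test_matches_squared_pearson_on_phased_panels(self, rng):
        # fully homozygous panels: each sample is one haplotype, phase known
        for _ in range(20):
            h1 = rng.choice([0, 1], size=40)
            h2 = np.where(rng.random(40) < 0.7, h1, rng.choice([0, 1], size=40))
            if h1.std() == 0 or h2.std() == 0:
                continue
            f = haplotype_freqs_em((2 * h1).astype(np.int8),
                                   (2 * h2).astype(np.int8))
            _, r2 = ld_r2(f)
            expected = np.corrcoef(h1, h2)[0, 1] ** 2
            assert r2 == pytest.approx(expected, abs=1e-9)


class TestSignificance:
    def test_perfect_association_is_extreme(self):
        p = ld_significance(np.array([[10, 0], [0, 10]]))
        # exact hypergeometric tail: 2 / C(20,10)
        assert p == pytest.approx(2 / 184756, rel=1e-6)
        assert p < 1e-4

    def test_balanced_table_is_null(self):
        assert ld_significance(np.array([[5, 5], [5, 5]])) == pytest.approx(1.0)

    def test_chi_square_branch_agrees_with_fisher(self):
        t = np.array([[60, 40], [45, 55]])
        p_chi = ld_significance(t)  # all cells >= 5: chi-square branch
        p_fisher = stats.fisher_exact(t)[1]
        assert np.log10(p_chi) == pytest.approx(np.log10(p_fisher), abs=0.5)

    def test_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            ld_significance(np.array([[1.5, 2.5], [3.0, 3.0]]))

    def test_largest_remainder_rounding(self):
        out = round_haplotype_counts(np.array([0.3, 0.3, 0.2, 0.2]), 10)
        assert out.sum() == 10
        np.testing.assert_array_equal(out, [3, 3, 2, 2])
        out = round_haplotype_counts(np.array([0.26, 0.26, 0.26, 0.22]), 10)
        assert out.sum() == 10


class TestScan:
    def test_window_excludes_distant_pairs(self):
        gmap = small_map(["1A"], per_chrom=2, spacing=60.0)  # 0 and 60 cM
        doses = np.array([[0, 0], [2, 2], [0, 2], [2, 0]], dtype=np.int8)
        table, _ = ld_scan(make_matrix(doses), gmap, window_cM=50.0)
        assert table.empty

    def test_duplicated_marker_is_perfect_ld(self):
        gmap = small_map(["1A"], per_chrom=2, spacing=1.0)
        col = np.array([0, 0, 2, 2, 0, 2] * 2, dtype=np.int8)
        table, _ = ld_scan(make_matrix(np.column_stack([col, col])), gmap)
        assert len(table) == 1
        assert table["r2"].iloc[0] == pytest.approx(1.0)
        assert table["p_value"].iloc[0] < 0.01

    def test_unlinked_mean_r2_near_reciprocal_n(self):
        from wheatpopgen.simulate import PanelSpec, generate_panel
        spec = PanelSpec(n_samples=80, n_loci=45, K=1, F=0.0, alpha=1.0,
                         selfing_rate=1.0, missing_rate=0.0,
                         chromosomes=("1A",), chromosome_length_cM=40.0,
                         seed=11)
        gm, gmap, _ = generate_panel(spec)
        table, _ = ld_scan(gm, gmap, window_cM=50.0, compute_p=False)
        r2 = table["r2"].to_numpy()
        se = r2.std(ddof=1) / np.sqrt(len(r2))
        assert abs(r2.mean() - 1 / spec.n_samples) < 3 * se + 0.005

    def test_critical_r2_pools_pairs_within_genome(self):
        table = pd.DataFrame({
            "chromosome": ["1A"] * 10 + ["2A"] * 30 + ["1B"] * 5,
            "r2": [0.1] * 10 + [0.3] * 30 + [0.9] * 5,
        })
        crit = critical_r2_per_genome(table)
        assert crit["A"] == pytest.approx((10 * 0.1 + 30 * 0.3) / 40)
        assert crit["B"] == pytest.approx(0.9)


class TestDecayFit:
    @staticmethod
    def _table(d, r2):
        return pd.DataFrame({
            "chromosome": "1A", "distance_cM": d, "r2": r2,
            "p_value": np.full(len(d), 0.5),
        })

    def test_exponential_decay_crosses_at_unit_distance(self, rng):
        d = np.linspace(0.01, 5, 400)
        table = self._table(d, np.exp(-d))
        fit = fit_ld_decay(table, "1A", critical_r2=np.exp(-1.0))
        assert fit.decay_cM == pytest.approx(1.0, abs=1.0)
        assert abs(fit.decay_cM_raw - 1.0) < 0.5

    def test_flat_below_critical_is_zero(self):
        d = np.linspace(0, 10, 50)
        fit = fit_ld_decay(self._table(d, np.full(50, 0.05)), "1A", 0.2)
        assert fit.decay_cM == 0.0

    def test_never_crossing_is_censored(self):
        d = np.linspace(0, 10, 50)
        fit = fit_ld_decay(self._table(d, np.full(50, 0.9)), "1A", 0.2)
        assert fit.censored
        assert np.isnan(fit.decay_cM)

    def test_monotone_input_has_unique_crossing(self):
        d = np.linspace(0, 8, 300)
        r2 = 1.0 / (1.0 + d)
        fit = fit_ld_decay(self._table(d, r2), "1A", 0.5)
        below = fit.fitted <= 0.5
        # once below, stays below (curve monotone): crossing unique
        first = int(np.argmax(below))
        assert below[first:].all()
        # bisection-style check of the crossing location: 1/(1+d)=0.5 at d=1
        assert fit.decay_cM == pytest.approx(1.0, abs=1.0)

    def test_too_few_pairs_undefined(self):
        d = np.linspace(0, 5, 10)
        fit = fit_ld_decay(self._table(d, np.exp(-d)), "1A", 0.3)
        assert np.isnan(fit.decay_cM)
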