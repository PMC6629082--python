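"""Marker filtering, polymorphism partition and decay thinning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatpopgen.io import MISSING
from wheatpopgen.qc import (compute_locus_stats, filter_markers,
                            partition_polymorphism, thin_by_decay)

from .conftest import make_matrix, small_map


class TestLocusStats:
    def test_hand_counted_maf(self):
        # {AA x6, AB x2, BB x2}: p_B = (2*2 + 2)/20 = 0.3
        doses = np.array([[0] * 6 + [1] * 2 + [2] * 2]).T
        _, maf = compute_locus_stats(make_matrix(doses))
        assert maf[0] == pytest.approx(0.3)

    def test_monomorphic_and_missing_rates(self):
        doses = np.zeros((10, 2), dtype=np.int8)
        doses[:4, 1] = MISSING
        missing_rate, maf = compute_locus_stats(make_matrix(doses))
        assert maf[0] == 0.0
        assert missing_rate[1] == pytest.approx(0.4)

    def test_all_missing_locus_is_nan_not_zero(self):
        doses = np.zeros((4, 2), dtype=np.int8)
        doses[:, 1] = MISSING
        _, maf = compute_locus_stats(make_matrix(doses))
        assert np.isnan(maf[1])


class TestFilterMarkers:
    def test_boundary_semantics(self):
        # maf exactly 0.05 (1 B-copy in 10 haploid-equivalents of 10 inbreds)
        n = 10
        exact = np.zeros(n, dtype=np.int8)
        exact[0] = 1  # p = 1/20 = 0.05
        low = np.zeros(n, dtype=np.int8)  # monomorphic: maf 0 < 0.05
        missing = np.zeros(n, dtype=np.int8)
        missing[:3] = MISSING  # 30% > 25%
        keep = np.tile([0, 2], n // 2).astype(np.int8)  # p = 0.5
        doses = np.column_stack([exact, low, missing, keep])
        filtered, report = filter_markers(make_matrix(doses))
        assert report.n_removed_missing == 1
        assert report.n_removed_maf == 1
        assert filtered.locus_ids == ["m0", "m3"]

    def test_published_marker_arithmetic(self, filter_panel):
        filtered, report = filter_markers(filter_panel)
        assert (report.n_input, report.n_removed_missing,
                report.n_removed_maf, report.n_retained) == (11196, 8, 730, 10458)
        assert filtered.n_loci == 10458

    def test_idempotent(self, filter_panel):
        filtered, _ = filter_markers(filter_panel)
        again, report2 = filter_markers(filtered)
        assert report2.n_retained == filtered.n_loci
        assert report2.n_removed_missing == report2.n_removed_maf == 0

    @settings(max_examples=25, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.05, 0.6),
        st.floats(0.01, 0.4),
    )
    def test_counting_identity_random(self, seed, max_missing, min_maf):
        rng = np.random.default_rng(seed)
        doses = rng.choice([0, 1, 2, MISSING], size=(15, 60),
                           p=[0.4, 0.1, 0.35, 0.15]).astype(np.int8)
        gm = make_matrix(doses)
        try:
            _, rep = filter_markers(gm, max_missing, min_maf)
        except ValueError:
            return  # empty retained set is a legal refusal
        assert rep.n_input == (rep.n_removed_missing + rep.n_removed_maf
                               + rep.n_retained)


class TestPartition:
    def test_published_partition(self, partition_panel):
        gm, labels = partition_panel
        part = partition_polymorphism(gm, labels)
        assert part.n_total_union == 11074
        assert part.n_common == 10090
        assert (part.n_only_group1, part.n_only_group2) == (368, 616)

    def test_fixed_alternative_alleles_in_neither(self):
        doses = np.array([[0], [0], [2], [2]], dtype=np.int8)
        part = partition_polymorphism(make_matrix(doses),
                                      np.array(["a", "a", "b", "b"]))
        assert part.n_total_union == 0

    def test_identities_match_per_locus_scan(self, rng):
        doses = rng.choice([0, 1, 2, MISSING], size=(12, 50),
                           p=[0.35, 0.1, 0.35, 0.2]).astype(np.int8)
        labels = np.array(["x"] * 6 + ["y"] * 6, dtype=object)
        part = partition_polymorphism(make_matrix(doses), labels)

        def poly(col):
            vals = col[col != MISSING]
            has_a = np.any(vals < 2)
            has_b = np.any(vals > 0)
            return has_a and has_b

        in1 = np.array([poly(doses[:6, j]) for j in range(50)])
        in2 = np.array([poly(doses[6:, j]) for j in range(50)])
        assert part.n_common == int((in1 & in2).sum())
        assert part.n_only_group1 == int((in1 & ~in2).sum())
        assert part.n_only_group2 == int((~in1 & in2).sum())
        assert part.n_total_union == part.n_common + part.n_only_group1 + part.n_only_group2

    def test_small_group_rejected(self):
        doses = np.zeros((3, 4), dtype=np.int8)
        with pytest.raises(ValueError, match="fewer than 2"):
            partition_polymorphism(make_matrix(doses),
                                   np.array(["a", "a", "b"]))


class TestThinning:
    def test_greedy_spacing(self):
        gmap = small_map(["1A"], per_chrom=5, spacing=1.0)  # 0,1,2,3,4 cM
        gm = make_matrix(np.zeros((2, 5), dtype=np.int8))
        kept = thin_by_decay(gm, gmap, {"1A": 2.0})
        assert kept == ["m0", "m2", "m4"]

    def test_zero_decay_keeps_all(self):
        gmap = small_map(["1A", "2B"], per_chrom=4)
        gm = make_matrix(np.zeros((2, 8), dtype=np.int8))
        assert len(thin_by_decay(gm, gmap, 0.0)) == 8

    def test_retained_pairs_respect_spacing(self, rng):
        import pandas as pd
        from wheatpopgen.io import GeneticMap
        rows = []
        for j in range(60):
            rows.append({"locus_id": f"m{j}",
                         "chromosome": rng.choice(["1A", "5B", "7D"]),
                         "position_cM": float(rng.uniform(0, 80))})
        gmap = GeneticMap(pd.DataFrame(rows))
        gm = make_matrix(np.zeros((2, 60), dtype=np.int8))
        decay = {"1A": 3.0, "5B": 7.5, "7D": 0.5}
        kept = thin_by_decay(gm, gmap, decay)
        pos = gmap.positions()
        chrom = gmap.chromosome_of()
        for c in decay:
            ps = sorted(pos[l] for l in kept if chrom[l] == c)
            assert all(b - a >= decay[c] for a, b in zip(ps, ps[1:]))
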