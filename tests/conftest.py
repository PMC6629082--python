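"""Shared fixtures: tiny hand-made panels and engineered marker-accounting
panels whose filter/partition arithmetic is known by construction."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wheatpopgen.io import MISSING, GeneticMap, GenotypeMatrix


def make_matrix(doses, era=None) -> GenotypeMatrix:
    doses = np.asarray(doses, dtype=np.int8)
    n, L = doses.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        locus_ids=[f"m{j}" for j in range(L)],
        doses=doses,
        era_labels=None if era is None else np.asarray(era, dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_panel(rng):
    """20 x 50 panel with all call states and some missingness."""
    doses = rng.choice([0, 1, 2, MISSING], size=(20, 50),
                       p=[0.45, 0.1, 0.4, 0.05]).astype(np.int8)
    return make_matrix(doses)


def small_map(chromosomes, per_chrom, spacing=1.0) -> GeneticMap:
    rows = []
    j = 0
    for chrom in chromosomes:
        for i in range(per_chrom):
            rows.append({"locus_id": f"m{j}", "chromosome": chrom,
                         "position_cM": i * spacing})
            j += 1
    return GeneticMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# engineered panels reproducing the published marker accounting
# ---------------------------------------------------------------------------

def engineered_filter_panel() -> GenotypeMatrix:
    """40-sample panel of 11196 loci: 8 fail the >25% missingness rule,
    730 fail the MAF<5% rule, 10458 pass both."""
    n = 40
    n_missfail, n_maffail, n_pass = 8, 730, 10458
    cols = []
    # >25% missing: 12/40 = 30% missing, remaining calls polymorphic
    col = np.zeros(n, dtype=np.int8)
    col[:12] = MISSING
    col[12:26] = 2
    cols += [col] * n_missfail
    # MAF below 5%: one B allele among 40 inbred lines -> p = 1/80 = 0.0125
    col = np.zeros(n, dtype=np.int8)
    col[0] = 1
    cols += [col] * n_maffail
    # passing: balanced, maf 0.5, no missing
    col = np.zeros(n, dtype=np.int8)
    col[: n // 2] = 2
    cols += [col] * n_pass
    doses = np.tile(np.array(cols, dtype=np.int8).T, 1)
    return make_matrix(doses)


def engineered_partition_panel() -> tuple[GenotypeMatrix, np.ndarray]:
    """Two groups of 4 samples over 11196 loci: 10090 polymorphic in both,
    368 only in group 1, 616 only in group 2, 122 in neither."""
    blocks = {
        "both": (10090, [0, 2, 0, 2], [0, 2, 0, 2]),
        "only1": (368, [0, 2, 0, 2], [2, 2, 2, 2]),
        "only2": (616, [0, 0, 0, 0], [0, 2, 0, 2]),
        # fixed for alternative alleles: polymorphic in neither group
        "neither": (122, [0, 0, 0, 0], [2, 2, 2, 2]),
    }
    cols = []
    for count, g1, g2 in blocks.values():
        cols += [np.array(g1 + g2, dtype=np.int8)] * count
    doses = np.array(cols, dtype=np.int8).T
    labels = np.array(["g1"] * 4 + ["g2"] * 4, dtype=object)
    return make_matrix(doses), labels


@pytest.fixture(scope="session")
def filter_panel():
    return engineered_filter_panel()


@pytest.fixture(scope="session")
def partition_panel():
    return engineered_partition_panel()
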