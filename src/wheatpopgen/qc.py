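"""Marker quality control: missingness/MAF filters, polymorphism partition
between germplasm groups, and LD-decay-spaced marker thinning.

Filter boundary semantics follow the usual reporting convention for diversity
panels: a marker is dropped when its missing fraction is strictly greater
than the threshold, or its minor-allele frequency strictly lower than the
threshold (a locus at MAF exactly 0.05 is retained).  Removal precedence is
missingness first, then MAF, so the two removal counts and the retained
count always sum to the input count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import MISSING, GeneticMap, GenotypeMatrix

logger = logging.getLogger("wheatpopgen")


@dataclass
class FilterReport:
    """Marker-accounting summary of one filtering pass."""

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_retained: int
    missing_rate: np.ndarray  # per input locus
    maf: np.ndarray           # per input locus; NaN where undefined

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_missing + self.n_removed_maf + self.n_retained:
            raise ValueError("filter counts do not sum to n_input")


@dataclass
class PolymorphismPartition:
    """How polymorphic loci distribute over two germplasm groups."""

    n_total_union: int
    n_common: int
    n_only_group1: int
    n_only_group2: int

    def __post_init__(self) -> None:
        if self.n_total_union != self.n_common + self.n_only_group1 + self.n_only_group2:
            raise ValueError("partition counts do not sum to union")


def compute_locus_stats(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (missing_rate, minor allele frequency).

    MAF is allele-count based over non-missing calls: with B-dose d summed
    over samples, p_B = sum(d) / (2 * n_nonmissing) and MAF = min(p_B, 1-p_B).
    Loci with no non-missing call get MAF = NaN (undefined, never silently 0).
    """
    d = gm.doses
    miss = d == MISSING
    n_nonmiss = (~miss).sum(axis=0)
    missing_rate = miss.sum(axis=0) / gm.n_samples
    dose_sum = np.where(miss, 0, d).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_nonmiss > 0, dose_sum / (2.0 * n_nonmiss), np.nan)
    maf = np.minimum(p, 1.0 - p)
    n_undef = int((n_nonmiss == 0).sum())
    if n_undef:
        logger.warning("%d loci have no non-missing calls; MAF undefined", n_undef)
    return missing_rate, maf


def filter_markers(
    gm: GenotypeMatrix, max_missing: float = 0.25, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop markers with missingness > *max_missing* or MAF < *min_maf*."""
    if not (0 < max_missing < 1 and 0 < min_maf < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    missing_rate, maf = compute_locus_stats(gm)
    fail_miss = missing_rate > max_missing
    # all-missing loci (NaN MAF) already fail the missingness rule
    fail_maf = ~fail_miss & (np.isnan(maf) | (maf < min_maf))
    keep = ~fail_miss & ~fail_maf
    if not keep.any():
        raise ValueError("no markers retained by the filters")
    report = FilterReport(
        n_input=gm.n_loci,
        n_removed_missing=int(fail_miss.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
        missing_rate=missing_rate,
        maf=maf,
    )
    return gm.subset_loci(keep), report


def _polymorphic_mask(doses: np.ndarray) -> np.ndarray:
    """Loci with >=2 distinct alleles observed among non-missing calls."""
    miss = doses == MISSING
    has_a = np.logical_and(~miss, doses < 2).any(axis=0)   # allele A present
    has_b = np.logical_and(~miss, doses > 0).any(axis=0)   # allele B present
    return has_a & has_b


def partition_polymorphism(
    gm: GenotypeMatrix, group_labels: np.ndarray
) -> PolymorphismPartition:
    """Count loci polymorphic in both, only the first, or only the second group.

    *group_labels* holds exactly two distinct labels; group order follows the
    sorted label order.  A locus enters the union only if it is polymorphic
    within at least one group (fixed-for-alternative-alleles loci are
    polymorphic in neither and excluded).
    """
    labels = np.asarray(group_labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    masks = []
    for g in uniq:
        sel = labels == g
        if sel.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        masks.append(_polymorphic_mask(gm.doses[sel]))
    in1, in2 = masks
    return PolymorphismPartition(
        n_total_union=int((in1 | in2).sum()),
        n_common=int((in1 & in2).sum()),
        n_only_group1=int((in1 & ~in2).sum()),
        n_only_group2=int((~in1 & in2).sum()),
    )


def thin_by_decay(
    gm: GenotypeMatrix, gmap: GeneticMap, decay_cM: dict[str, float] | float
) -> list[str]:
    """Greedy left-to-right marker thinning at LD-decay spacing.

    Scans each chromosome in map order and keeps a marker only if it lies at
    least ``decay_cM[chromosome]`` centimorgans beyond the last kept marker,
    so retained neighbours are outside the chromosome's significant-LD range.
    A scalar *decay_cM* applies to every chromosome.  Markers without a map
    position are excluded (logged).  Returns retained locus ids in map order.
    """
    panel = set(gm.locus_ids)
    unmapped = panel - set(gmap.locus_ids)
    if unmapped:
        logger.warning("thinning: %d panel loci have no map position", len(unmapped))
    retained: list[str] = []
    for chrom in gmap.chromosomes():
        dec = decay_cM if np.isscalar(decay_cM) else decay_cM.get(chrom)
        if dec is None:
            raise ValueError(f"no decay distance for chromosome {chrom}")
        if dec < 0:
            raise ValueError(f"negative decay distance for {chrom}")
        last = -np.inf
        sub = gmap.loci_on(chrom)
        for locus, pos in zip(sub["locus_id"], sub["position_cM"]):
            if locus not in panel:
                continue
            if pos - last >= dec:
                retained.append(locus)
                last = pos
    return retained
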