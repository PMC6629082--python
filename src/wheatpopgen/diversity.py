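"""Nei diversity statistics, Botstein PIC, and gene flow.

For a biallelic locus with allele frequency p (q = 1 - p):

* gene diversity (expected heterozygosity)  H = 1 - p^2 - q^2 = 2pq
* polymorphic information content           PIC = 1 - (p^2 + q^2) - 2 p^2 q^2

With the panel split into subpopulations, total diversity H_T is computed
from the mean subpopulation frequency p-bar, H_S is the mean within-group
diversity, and the partition follows Nei:

    D_ST = H_T - H_S        G_ST = D_ST / H_T       Nm = 0.5 (1 - G_ST) / G_ST

H_T and H_S are averaged over loci first and the ratios formed from the
means, which is how a single table row per grouping is obtained.  The
frequency mean over groups is unweighted by default (Nei's convention for
comparing populations of unequal size); pass ``weights`` to weight by group
size instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GeneticMap, GenotypeMatrix

logger = logging.getLogger("wheatpopgen")

#: biallelic PIC attains its maximum 0.375 at p = 0.5
PIC_MAX_BIALLELIC = 0.375


@dataclass
class DiversityPartition:
    """Nei partition of gene diversity for one grouping of samples."""

    n_samples: int
    n_loci: int
    H_T: float
    H_S: float
    D_ST: float
    G_ST: float
    Nm: float  # NaN when G_ST <= 0 (no differentiation: gene flow undefined)


def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return p


def pic_locus(p):
    """Botstein polymorphic information content of a biallelic locus.

    Algebraically 1 - (p^2 + q^2) - 2 p^2 q^2 = 2pq (1 - pq); the factored
    form avoids catastrophic cancellation near monomorphism.
    """
    p = _check_p(p)
    pq = p * (1.0 - p)
    return 2.0 * pq * (1.0 - pq)


def gene_diversity_locus(p):
    """Nei gene diversity H = 2pq of a biallelic locus."""
    p = _check_p(p)
    return 2.0 * p * (1.0 - p)


def gene_flow(G_ST: float) -> float:
    """Effective-migrant estimate Nm = 0.5 (1 - G_ST) / G_ST.

    Undefined (NaN) for G_ST <= 0; strictly decreasing on (0, 1].
    """
    if G_ST <= 0:
        return float("nan")
    return 0.5 * (1.0 - G_ST) / G_ST


def allele_frequencies(gm: GenotypeMatrix, sample_mask=None) -> np.ndarray:
    """Per-locus B-allele frequency over non-missing calls (NaN if none)."""
    d = gm.doses if sample_mask is None else gm.doses[np.asarray(sample_mask)]
    miss = d == MISSING
    n = (~miss).sum(axis=0)
    s = np.where(miss, 0, d).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, s / (2.0 * n), np.nan)


def partition_from_means(H_T: float, H_S: float, n_samples: int = 0,
                         n_loci: int = 0) -> DiversityPartition:
    """Complete the Nei partition from already-averaged H_T and H_S."""
    if H_S > H_T + 1e-12:
        raise ValueError("H_S cannot exceed H_T")
    D_ST = H_T - H_S
    G_ST = D_ST / H_T if H_T > 0 else 0.0
    return DiversityPartition(n_samples, n_loci, H_T, H_S, D_ST, G_ST,
                              gene_flow(G_ST))


def diversity_partition(
    gm: GenotypeMatrix,
    group_labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> DiversityPartition:
    """Nei diversity partition of a panel over >=2 subpopulations.

    *group_labels* assigns each sample to a subpopulation; samples labelled
    ``None``/NaN are excluded (e.g. admixed accessions left out of a
    structured-genotypes analysis).  Loci with an undefined frequency in any
    group are excluded (logged).  *weights* optionally weights groups by
    e.g. sample size when averaging frequencies and within-group H.
    """
    labels = np.asarray(group_labels, dtype=object)
    use = np.array([l is not None and l == l for l in labels])
    groups = sorted({l for l in labels[use]})
    if len(groups) < 2:
        raise ValueError("need at least 2 subpopulations")
    freqs, sizes = [], []
    for g in groups:
        sel = use & (labels == g)
        if sel.sum() < 2:
            raise ValueError(f"subpopulation {g!r} has fewer than 2 samples")
        freqs.append(allele_frequencies(gm, sel))
        sizes.append(int(sel.sum()))
    P = np.vstack(freqs)                      # (K, L)
    defined = ~np.isnan(P).any(axis=0)
    if not defined.all():
        logger.info("diversity partition: %d loci dropped (undefined in a group)",
                    int((~defined).sum()))
    if not defined.any():
        raise ValueError("no locus has a defined frequency in every group")
    P = P[:, defined]
    if weights is None:
        w = np.full(len(groups), 1.0 / len(groups))
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    p_bar = w @ P
    H_T = float(np.mean(gene_diversity_locus(p_bar)))
    H_S = float(np.mean(w @ gene_diversity_locus(P)))
    part = partition_from_means(H_T, H_S, n_samples=int(use.sum()),
                                n_loci=int(defined.sum()))
    if part.G_ST <= 0:
        logger.warning("G_ST <= 0: gene flow undefined for this grouping")
    return part


def summarize_by_region(
    gm: GenotypeMatrix, gmap: GeneticMap, digits: int | None = None
) -> pd.DataFrame:
    """Marker count, mean H_T and mean PIC per chromosome, genome and total.

    Diversity here treats the supplied panel as one undivided population
    (frequencies pooled over all samples).  Chromosomes with no analysed
    markers are omitted (logged).  Monomorphic loci, if present, contribute
    zeros; all-missing loci are excluded.
    """
    p = allele_frequencies(gm)
    chrom_of = gmap.chromosome_of()
    rows = []
    per_chrom: dict[str, list[int]] = {}
    for j, locus in enumerate(gm.locus_ids):
        c = chrom_of.get(locus)
        if c is None:
            continue
        if not np.isnan(p[j]):
            per_chrom.setdefault(c, []).append(j)
    for chrom in gmap.chromosomes():
        idx = per_chrom.get(chrom)
        if not idx:
            logger.info("summary: chromosome %s has no analysed markers", chrom)
            continue
        pj = p[idx]
        rows.append({
            "region": chrom, "level": "chromosome", "genome": chrom[-1],
            "N": len(idx),
            "H_T": float(np.mean(gene_diversity_locus(pj))),
            "PIC": float(np.mean(pic_locus(pj))),
        })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no mapped, analysable markers")
    gen_rows = []
    for genome, sub in df.groupby("genome"):
        n = int(sub["N"].sum())
        gen_rows.append({
            "region": f"Genome {genome}", "level": "genome", "genome": genome,
            "N": n,
            "H_T": float((sub["H_T"] * sub["N"]).sum() / n),
            "PIC": float((sub["PIC"] * sub["N"]).sum() / n),
        })
    n_tot = int(df["N"].sum())
    total = {
        "region": "Total", "level": "total", "genome": "-",
        "N": n_tot,
        "H_T": float((df["H_T"] * df["N"]).sum() / n_tot),
        "PIC": float((df["PIC"] * df["N"]).sum() / n_tot),
    }
    out = pd.concat([df, pd.DataFrame(gen_rows), pd.DataFrame([total])],
                    ignore_index=True)
    if digits is not None:
        out[["H_T", "PIC"]] = out[["H_T", "PIC"]].round(digits)
    return out
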