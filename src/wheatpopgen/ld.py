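"""Intra-chromosomal linkage disequilibrium: r-squared, significance, and
LOESS-based decay distance.

Genotypes are unphased, so two-locus haplotype frequencies are estimated by
EM over the double-heterozygote phase ambiguity; for fully homozygous
(inbred) panels the EM reduces to direct haplotype counting.  LD is
summarised as r^2 = D^2 / (pA qA pB qB), pair significance is tested on the
2x2 haplotype count table (Fisher exact, chi-square when all cells are
large), and per chromosome a LOESS curve of r^2 against genetic distance is
intersected with a critical r^2 — the mean r^2 of the chromosome's genome —
to yield the decay distance in centimorgans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import MISSING, GeneticMap, GenotypeMatrix

logger = logging.getLogger("wheatpopgen")

#: defaults mirroring the analysis conventions for wheat chip panels
DEFAULT_WINDOW_CM = 50.0
DEFAULT_ALPHA = 0.001
DEFAULT_LOESS_SPAN = 0.5
DECAY_GRID_STEP_CM = 0.1
MIN_PAIRS_FOR_DECAY = 20


# ---------------------------------------------------------------------------
# haplotype frequencies and r^2
# ---------------------------------------------------------------------------

def haplotype_freqs_em(
    doses_a: np.ndarray, doses_b: np.ndarray,
    max_iter: int = 100, tol: float = 1e-8,
) -> np.ndarray:
    """EM estimate of the four haplotype frequencies (f00, f01, f10, f11).

    Index order: allele-B dose at locus a, then at locus b.  Only samples
    non-missing at both loci are used; either locus monomorphic in that
    complete-case subset makes r^2 undefined and raises ``ValueError``.
    """
    a = np.asarray(doses_a)
    b = np.asarray(doses_b)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 samples complete at both loci")
    a, b = a[ok].astype(np.int64), b[ok].astype(np.int64)
    # monomorphic = only one allele observed (all AA, or all BB)
    if a.max() == 0 or a.min() == 2 or b.max() == 0 or b.min() == 2:
        raise ValueError("locus monomorphic in the complete-case subset")
    n = np.bincount(3 * a + b, minlength=9).reshape(3, 3)
    # phase-determined haplotype copies
    c = np.array([
        2 * n[0, 0] + n[0, 1] + n[1, 0],   # 00
        2 * n[0, 2] + n[0, 1] + n[1, 2],   # 01
        2 * n[2, 0] + n[2, 1] + n[1, 0],   # 10
        2 * n[2, 2] + n[2, 1] + n[1, 2],   # 11
    ], dtype=float)
    ndh = int(n[1, 1])                      # double heterozygotes: ambiguous
    total = float(c.sum() + 2 * ndh)
    if ndh == 0:
        return c / total
    f = (c + ndh * np.array([0.5, 0.5, 0.5, 0.5])) / total
    for _ in range(max_iter):
        coup = f[0] * f[3]
        rep = f[1] * f[2]
        w = 0.5 if coup + rep == 0 else coup / (coup + rep)
        f_new = (c + ndh * np.array([w, 1 - w, 1 - w, w])) / total
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return f


def ld_r2(hapfreqs: np.ndarray) -> tuple[float, float]:
    """(D, r^2) from haplotype frequencies (f00, f01, f10, f11)."""
    f00, f01, f10, f11 = np.asarray(hapfreqs, dtype=float)
    pA = f10 + f11
    pB = f01 + f11
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise ValueError("marginal allele frequency 0 or 1: r^2 undefined")
    D = f11 - pA * pB
    return float(D), float(D * D / denom)


def round_haplotype_counts(freqs: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rounding of expected haplotype counts to integers."""
    e = np.asarray(freqs, dtype=float) * total
    base = np.floor(e).astype(np.int64)
    short = int(total - base.sum())
    if short > 0:
        # deterministic: largest fractional part first, ties by index
        order = np.lexsort((np.arange(4), -(e - base)))
        base[order[:short]] += 1
    return base


def ld_significance(counts: np.ndarray) -> float:
    """Two-sided p-value for association in a 2x2 haplotype count table.

    Fisher's exact test; for well-filled tables (all cells >= 5) the
    chi-square approximation is used, which is indistinguishable at that
    size and much cheaper.
    """
    t = np.asarray(counts)
    if t.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("haplotype counts must be integers")
        t = np.round(t).astype(np.int64)
    if t.sum() < 2:
        raise ValueError("need at least 2 haplotypes")
    if (t >= 5).all():
        row = t.sum(axis=1, keepdims=True)
        col = t.sum(axis=0, keepdims=True)
        e = row * col / t.sum()
        chi2 = float(((t - e) ** 2 / e).sum())
        return max(float(stats.chi2.sf(chi2, df=1)), np.finfo(float).tiny)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# genome-wide scan
# ---------------------------------------------------------------------------

def inbreeding_coefficient(gm: GenotypeMatrix) -> float:
    """Panel-wide Wright F_IS = 1 - mean(H_obs) / mean(H_exp) over loci.

    Selfing crops carry far fewer heterozygotes than Hardy-Weinberg
    predicts; F_IS near 1 means each sample contributes essentially one
    independent gamete, not two.
    """
    d = gm.doses
    miss = d == MISSING
    n = (~miss).sum(axis=0)
    ok = n > 0
    het = np.where(miss, 0, d == 1).sum(axis=0)[ok] / n[ok]
    s = np.where(miss, 0, d).sum(axis=0, dtype=np.int64)[ok]
    p = s / (2.0 * n[ok])
    h_exp = 2 * p * (1 - p)
    if h_exp.mean() == 0:
        return 0.0
    return float(np.clip(1.0 - het.mean() / h_exp.mean(), 0.0, 1.0))


def ld_scan(
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    window_cM: float = DEFAULT_WINDOW_CM,
    alpha: float = DEFAULT_ALPHA,
    compute_p: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate all intra-chromosomal pairs within *window_cM*.

    Returns ``(ld_table, summary)``: the pair table with columns
    ``locus_a, locus_b, chromosome, distance_cM, r2, p_value`` and a
    per-chromosome summary with ``n_pairs, mean_r2, pct_significant``.
    Pairs whose r^2 is undefined (a locus monomorphic among complete cases)
    are skipped and counted in the log.  Chromosomes with fewer than two
    mapped markers are skipped.

    Significance is tested on *effective* gamete counts
    ``n_eff = 2 n / (1 + F_IS)``: in an inbred panel the two allele copies
    of a sample are near-duplicates, and testing on the raw 2n copies would
    inflate the type-I rate roughly twofold.
    """
    f_is = inbreeding_coefficient(gm) if compute_p else 0.0
    dose_col = {l: gm.doses[:, j] for j, l in enumerate(gm.locus_ids)}
    rows: list[tuple] = []
    n_skipped = 0
    for chrom in gmap.chromosomes():
        sub = gmap.loci_on(chrom)
        loci = [l for l in sub["locus_id"] if l in dose_col]
        pos = {l: p for l, p in zip(sub["locus_id"], sub["position_cM"])}
        if len(loci) < 2:
            continue
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                la, lb = loci[i], loci[j]
                dist = abs(pos[lb] - pos[la])
                if dist > window_cM:
                    continue
                try:
                    f = haplotype_freqs_em(dose_col[la], dose_col[lb])
                    _, r2 = ld_r2(f)
                except ValueError:
                    n_skipped += 1
                    continue
                if compute_p:
                    ok = (dose_col[la] != MISSING) & (dose_col[lb] != MISSING)
                    n_eff = max(2, round(2 * int(ok.sum()) / (1.0 + f_is)))
                    counts = round_haplotype_counts(f, n_eff)
                    p = ld_significance(counts.reshape(2, 2))
                else:
                    p = np.nan
                rows.append((la, lb, chrom, dist, r2, p))
    if n_skipped:
        logger.info("LD scan: %d pairs skipped (r^2 undefined)", n_skipped)
    table = pd.DataFrame(
        rows, columns=["locus_a", "locus_b", "chromosome",
                       "distance_cM", "r2", "p_value"],
    )
    summary = summarize_ld(table, alpha)
    return table, summary


def summarize_ld(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    rows = []
    for chrom, sub in table.groupby("chromosome"):
        rows.append({
            "chromosome": chrom,
            "n_pairs": len(sub),
            "mean_r2": float(sub["r2"].mean()),
            "pct_significant": float(100.0 * (sub["p_value"] < alpha).mean()),
        })
    return pd.DataFrame(rows)


def critical_r2_per_genome(table: pd.DataFrame) -> dict[str, float]:
    """Mean r^2 over all evaluated pairs per genome (chromosome suffix)."""
    if table.empty:
        return {}
    genome = table["chromosome"].str[-1]
    return {g: float(sub["r2"].mean()) for g, sub in table.groupby(genome)}


# ---------------------------------------------------------------------------
# LOESS decay
# ---------------------------------------------------------------------------

@dataclass
class LDDecayFit:
    """LOESS decay fit for one chromosome."""

    chromosome: str
    critical_r2: float
    decay_cM: float          # whole-cM report; NaN when undefined/censored
    decay_cM_raw: float      # grid crossing before rounding; NaN likewise
    censored: bool           # curve never falls below critical in range
    n_pairs: int
    pct_significant: float
    grid: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)


def fit_ld_decay(
    table: pd.DataFrame,
    chromosome: str,
    critical_r2: float,
    span: float = DEFAULT_LOESS_SPAN,
    alpha: float = DEFAULT_ALPHA,
) -> LDDecayFit:
    """LOESS (degree 1, tricube) of r^2 on distance; decay at the critical line.

    The fitted curve is evaluated on a 0.1 cM grid; the decay distance is the
    smallest grid distance at which the curve is <= *critical_r2* (0 if it
    starts below, censored if it never crosses within the observed range).
    Reported decay is rounded to whole centimorgans.
    """
    sub = table[table["chromosome"] == chromosome]
    n_pairs = len(sub)
    pct_sig = float(100.0 * (sub["p_value"] < alpha).mean()) if n_pairs else np.nan
    if n_pairs < MIN_PAIRS_FOR_DECAY:
        logger.warning("decay %s: only %d pairs, decay undefined",
                       chromosome, n_pairs)
        return LDDecayFit(chromosome, critical_r2, np.nan, np.nan, False,
                          n_pairs, pct_sig, np.array([]), np.array([]))
    d = sub["distance_cM"].to_numpy(float)
    r2 = sub["r2"].to_numpy(float)
    if np.ptp(d) == 0:
        raise ValueError(f"decay {chromosome}: all pair distances equal")
    grid = np.arange(0.0, d.max() + DECAY_GRID_STEP_CM, DECAY_GRID_STEP_CM)
    fitted = lowess(r2, d, frac=span, it=0, xvals=grid)
    below = fitted <= critical_r2
    if not below.any():
        return LDDecayFit(chromosome, critical_r2, np.nan, np.nan, True,
                          n_pairs, pct_sig, grid, fitted)
    raw = float(grid[int(np.argmax(below))])
    return LDDecayFit(chromosome, critical_r2, float(round(raw)), raw, False,
                      n_pairs, pct_sig, grid, fitted)


def decay_table(fits: list[LDDecayFit]) -> pd.DataFrame:
    """Per-chromosome decay summary mirroring a diversity-panel LD table."""
    return pd.DataFrame([
        {
            "chromosome": f.chromosome,
            "n_pairs": f.n_pairs,
            "critical_r2": f.critical_r2,
            "decay_cM": f.decay_cM,
            "censored": f.censored,
            "pct_significant": f.pct_significant,
        }
        for f in fits
    ])
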