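"""Synthetic structured SNP panels with full ground truth.

The generator targets the statistical structure that the diversity,
structure and LD analyses assume for an inbred wheat panel, not wheat
biology itself:

* K latent subpopulations whose allele frequencies diverge from a shared
  ancestral frequency under the Balding–Nichols F-model,
* per-sample admixture proportions Q ~ Dirichlet(alpha),
* near-complete homozygosity via a selfing rate (the second allele copy
  duplicates the first with that probability),
* i.i.d. missing calls and a minor-allele-frequency spectrum with a sub-5%
  tail (ancestral frequencies uniform on (0.05, 0.95) plus drift),
* optionally, along-chromosome LD from a finite founder-haplotype pool with
  recombination-style founder switching.

Everything is deterministic given the seed, and the true Q, subpopulation
frequencies and realized per-locus differentiation are returned alongside
the panel for parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MISSING, WHEAT_CHROMOSOMES, GeneticMap, GenotypeMatrix

logger = logging.getLogger("wheatpopgen")


@dataclass
class PanelSpec:
    """Study-condition parameters for one synthetic panel."""

    n_samples: int = 200
    n_loci: int = 1000
    K: int = 3
    F: float | tuple = 0.15            # divergence per subpopulation
    alpha: float = 0.2                 # admixture concentration
    selfing_rate: float = 0.98
    missing_rate: float = 0.05
    chromosomes: tuple = WHEAT_CHROMOSOMES
    chromosome_length_cM: float = 160.0
    n_founder_haplotypes: int = 8      # linked mode
    recomb_rate_per_cM: float = 0.05   # linked mode: founder-switch rate c
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("selfing_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.missing_rate > 0.25:
            raise ValueError("missing_rate above 0.25 is outside the emulated panel")
        fs = np.atleast_1d(np.asarray(self.F, float))
        if np.any((fs < 0) | (fs >= 1)):
            raise ValueError("F must lie in [0, 1)")
        if self.n_loci < 1 or self.n_samples < 2 or self.K < 1:
            raise ValueError("need n_samples >= 2, n_loci >= 1, K >= 1")

    def f_per_pop(self) -> np.ndarray:
        fs = np.atleast_1d(np.asarray(self.F, float))
        if fs.size == 1:
            return np.repeat(fs, self.K)
        if fs.size != self.K:
            raise ValueError("F must be scalar or length K")
        return fs


@dataclass
class PanelTruth:
    """Ground truth accompanying a generated panel."""

    Q: np.ndarray = field(repr=False)            # (n, K)
    P: np.ndarray = field(repr=False)            # (K, L) subpop allele-B freqs
    fst_per_locus: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)       # 'SPk' at q>0.5 else None

    def realized_gst(self) -> float:
        """G_ST implied by the subpopulation frequencies (loci averaged)."""
        p_bar = self.P.mean(axis=0)
        h_t = 2 * p_bar * (1 - p_bar)
        h_s = (2 * self.P * (1 - self.P)).mean(axis=0)
        mt, ms = float(h_t.mean()), float(h_s.mean())
        return (mt - ms) / mt if mt > 0 else 0.0


def _make_map(spec: PanelSpec, rng: np.random.Generator) -> GeneticMap:
    chroms = list(spec.chromosomes)
    base, extra = divmod(spec.n_loci, len(chroms))
    counts = [base + (1 if i < extra else 0) for i in range(len(chroms))]
    rows = []
    j = 0
    for chrom, c in zip(chroms, counts):
        pos = np.sort(rng.uniform(0.0, spec.chromosome_length_cM, size=c))
        for p in pos:
            rows.append({"locus_id": f"mk{j:05d}", "chromosome": chrom,
                         "position_cM": float(p)})
            j += 1
    return GeneticMap(pd.DataFrame(rows))


def _draw_frequencies(spec: PanelSpec, rng: np.random.Generator):
    L = spec.n_loci
    p0 = rng.uniform(0.05, 0.95, size=L)
    P = np.empty((spec.K, L))
    for k, f in enumerate(spec.f_per_pop()):
        if f == 0:
            P[k] = p0
        else:
            a = p0 * (1 - f) / f
            b = (1 - p0) * (1 - f) / f
            P[k] = rng.beta(a, b)
    return p0, P


def _truth(spec: PanelSpec, Q: np.ndarray, P: np.ndarray) -> PanelTruth:
    p_bar = P.mean(axis=0)
    h_t = 2 * p_bar * (1 - p_bar)
    h_s = (2 * P * (1 - P)).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / h_t, 0.0)
    best = Q.argmax(axis=1)
    q_best = Q[np.arange(len(Q)), best]
    labels = np.array([f"SP{b + 1}" if q > 0.5 else None
                       for b, q in zip(best, q_best)], dtype=object)
    return PanelTruth(Q=Q, P=P, fst_per_locus=fst, labels=labels)


def _finalize(spec: PanelSpec, rng: np.random.Generator, gamete1, gamete2,
              gmap: GeneticMap, era: str | None):
    doses = (gamete1 + gamete2).astype(np.int8)
    mask = rng.random(doses.shape) < spec.missing_rate
    doses[mask] = MISSING
    n = spec.n_samples
    gm = GenotypeMatrix(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        locus_ids=gmap.locus_ids,
        doses=doses,
        era_labels=None if era is None else np.array([era] * n, dtype=object),
        alleles=[("A", "B")] * spec.n_loci,
    )
    return gm


def generate_panel(
    spec: PanelSpec, era: str | None = None
) -> tuple[GenotypeMatrix, GeneticMap, PanelTruth]:
    """Unlinked structured panel under the F-model with Dirichlet admixture."""
    rng = np.random.default_rng(spec.seed)
    gmap = _make_map(spec, rng)
    _, P = _draw_frequencies(spec, rng)
    Q = rng.dirichlet(np.full(spec.K, spec.alpha), size=spec.n_samples)
    # per-copy mixture frequency; loci are unlinked so copies are Bernoulli
    M = Q @ P
    g1 = (rng.random(M.shape) < M).astype(np.int8)
    g2_indep = (rng.random(M.shape) < M).astype(np.int8)
    dup = rng.random(M.shape) < spec.selfing_rate
    g2 = np.where(dup, g1, g2_indep)
    gm = _finalize(spec, rng, g1, g2, gmap, era)
    # note: map loci and genotype loci share ids but map order may differ
    return gm, gmap, _truth(spec, Q, P)


def generate_linked_panel(
    spec: PanelSpec, era: str | None = None
) -> tuple[GenotypeMatrix, GeneticMap, PanelTruth]:
    """Structured panel with along-chromosome LD from founder mosaics.

    Each subpopulation holds ``n_founder_haplotypes`` founder haplotypes
    drawn from its F-model frequencies; a gamete walks each chromosome as a
    founder mosaic, switching to a random founder between adjacent markers
    with probability 1 - exp(-c * delta_cM).  Larger c means faster LD decay.
    """
    if spec.n_founder_haplotypes < 2:
        raise ValueError("need at least 2 founder haplotypes")
    rng = np.random.default_rng(spec.seed)
    gmap = _make_map(spec, rng)  # locus ids are assigned in map order
    _, P = _draw_frequencies(spec, rng)
    Q = rng.dirichlet(np.full(spec.K, spec.alpha), size=spec.n_samples)
    H = spec.n_founder_haplotypes
    founders = (rng.random((spec.K, H, spec.n_loci))
                < P[:, None, :]).astype(np.int8)
    # switch probability between consecutive markers, 1.0 at chromosome start
    tbl = gmap.table
    pos = tbl["position_cM"].to_numpy()
    chrom = tbl["chromosome"].to_numpy()
    delta = np.empty(spec.n_loci)
    delta[0] = np.inf
    delta[1:] = pos[1:] - pos[:-1]
    delta[np.flatnonzero(chrom[1:] != chrom[:-1]) + 1] = np.inf
    p_switch = 1.0 - np.exp(-spec.recomb_rate_per_cM * delta)

    def one_gamete(i: int) -> np.ndarray:
        k = rng.choice(spec.K, p=Q[i])
        new_seg = rng.random(spec.n_loci) < p_switch
        new_seg[0] = True
        seg_id = np.cumsum(new_seg) - 1
        seg_founder = rng.integers(0, H, size=seg_id[-1] + 1)
        return founders[k, seg_founder[seg_id], np.arange(spec.n_loci)]

    g1 = np.empty((spec.n_samples, spec.n_loci), dtype=np.int8)
    g2 = np.empty_like(g1)
    for i in range(spec.n_samples):
        g1[i] = one_gamete(i)
        if rng.random() < spec.selfing_rate:
            g2[i] = g1[i]
        else:
            g2[i] = one_gamete(i)
    gm = _finalize(spec, rng, g1, g2, gmap, era)
    return gm, gmap, _truth(spec, Q, P)


# ---------------------------------------------------------------------------
# presets: a landrace-like and a modern-cultivar-like panel
# ---------------------------------------------------------------------------

PRESETS: dict[str, PanelSpec] = {
    # three geographic subpopulations, heavy admixture, moderate divergence
    "landrace-like": PanelSpec(n_samples=170, n_loci=2000, K=3, F=0.12,
                               alpha=0.25, selfing_rate=0.98,
                               missing_rate=0.05, seed=0),
    # three breeding-programme pools, stronger divergence, less admixture
    "modern-like": PanelSpec(n_samples=184, n_loci=2000, K=3, F=0.17,
                             alpha=0.1, selfing_rate=0.98,
                             missing_rate=0.05, seed=0),
}


def generate_era_panel(
    landrace_spec: PanelSpec | None = None,
    modern_spec: PanelSpec | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, GeneticMap, dict[str, PanelTruth]]:
    """A two-era panel (landraces + modern cultivars) on one shared map.

    Both eras share the marker set and ancestral frequencies but have their
    own subpopulation structure, mimicking a germplasm collection assembled
    from historical and elite material.
    """
    ls = landrace_spec or PRESETS["landrace-like"]
    ms = modern_spec or PRESETS["modern-like"]
    if ms.n_loci != ls.n_loci:
        raise ValueError("era specs must share n_loci")
    ls = replace(ls, seed=seed)
    ms = replace(ms, seed=seed + 1, chromosomes=ls.chromosomes,
                 chromosome_length_cM=ls.chromosome_length_cM)
    gm_l, gmap, truth_l = generate_panel(ls, era="landrace")
    rng = np.random.default_rng(ms.seed)
    _, P_m = _draw_frequencies(ms, rng)
    Q_m = rng.dirichlet(np.full(ms.K, ms.alpha), size=ms.n_samples)
    M = Q_m @ P_m
    g1 = (rng.random(M.shape) < M).astype(np.int8)
    g2 = np.where(rng.random(M.shape) < ms.selfing_rate, g1,
                  (rng.random(M.shape) < M).astype(np.int8))
    gm_m = _finalize(ms, rng, g1, g2, gmap, era="modern")
    gm_m.sample_ids = [f"M{i:04d}" for i in range(ms.n_samples)]
    truth_m = _truth(ms, Q_m, P_m)
    combined = GenotypeMatrix(
        sample_ids=gm_l.sample_ids + gm_m.sample_ids,
        locus_ids=gm_l.locus_ids,
        doses=np.vstack([gm_l.doses, gm_m.doses]),
        era_labels=np.concatenate([gm_l.era_labels, gm_m.era_labels]),
        alleles=gm_l.alleles,
    )
    return combined, gmap, {"landrace": truth_l, "modern": truth_m}
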