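"""Bayesian admixture clustering, Evanno Delta-K, and membership assignment.

The model is the classic admixture model for unlinked biallelic loci with
independent allele frequencies: each sample i carries admixture proportions
Q_i ~ Dirichlet(alpha, ..., alpha); each of the two allele copies at a locus
picks an ancestral population z from Q_i and then an allele from that
population's frequency P_{l,z}, itself given a Beta(lambda, lambda) prior
(lambda = 1).  Inference is by Gibbs sampling over (Z, P, Q) with a
Metropolis step for the shared alpha (uniform prior on (0, alpha_max),
Gaussian proposal).  The model-choice statistic reported per run is the
standard deviance-style estimator

    lnP(data) = mean(L) - var(L) / 2

over the post-burn-in trace of the complete log-likelihood L = ln P(X|P,Q).
The number of subpopulations is then chosen by the Evanno statistic
Delta-K = mean|L''(K)| / sd(L(K)) across replicate runs.

The Gibbs sweep is compiled with numba; runs are deterministic given the
seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .io import GenotypeMatrix

logger = logging.getLogger("wheatpopgen")

DEFAULT_BURN_IN = 10_000
DEFAULT_ITERATIONS = 100_000
DEFAULT_LAMBDA = 1.0
DEFAULT_ALPHA0 = 1.0
DEFAULT_ALPHA_PROP_SD = 0.025
DEFAULT_ALPHA_MAX = 10.0
STRONG_Q = 0.7
MODERATE_Q = 0.5


@dataclass
class StructureRun:
    """One MCMC run at a fixed K."""

    K: int
    seed: int
    burn_in: int
    iterations: int
    lnP_data: float
    Q: np.ndarray = field(repr=False)            # (n_samples, K) posterior mean
    P: np.ndarray = field(repr=False)            # (n_loci, K) posterior mean (allele B)
    lnp_trace: np.ndarray = field(repr=False)
    alpha_trace: np.ndarray = field(repr=False)
    alpha_acceptance: float = float("nan")


@dataclass
class EvannoResult:
    """Evanno table over K and the Delta-K-selected best K (None if flat)."""

    table: pd.DataFrame = field(repr=False)
    best_K: int | None = None


_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _next_uniform(state):
    """xorshift64* uniform in [0, 1); cheap generator for the origin draws."""
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state ^= state >> np.uint64(27)
    bits = (state * np.uint64(2685821657736338717)) >> np.uint64(11)
    return np.float64(bits) * _INV_2_53, state


@njit(cache=True, fastmath=True)
def _gibbs(doses, K, burn_in, n_iter, seed, lam, alpha0, alpha_prop_sd, alpha_max):
    np.random.seed(seed)
    rs = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    rs |= np.uint64(1)
    n, L = doses.shape
    P = np.random.random((L, K))            # Beta(1,1) init
    Q = np.full((n, K), 1.0 / K)
    alpha = alpha0
    total = burn_in + n_iter
    Q_sum = np.zeros((n, K))
    P_sum = np.zeros((L, K))
    lnp_trace = np.empty(n_iter)
    alpha_trace = np.empty(total)
    w1 = np.empty(K)
    w0 = np.empty(K)
    n_acc = 0
    n_rec = 0
    if K == 1:
        # degenerate model: origins are certain, only P is sampled
        s1 = np.zeros(L)
        s0 = np.zeros(L)
        for i in range(n):
            for l in range(L):
                g = doses[i, l]
                if g < 0:
                    continue
                s1[l] += g
                s0[l] += 2 - g
        for sweep in range(total):
            lnp = 0.0
            for l in range(L):
                g1 = np.random.gamma(lam + s1[l], 1.0)
                g2 = np.random.gamma(lam + s0[l], 1.0)
                p = g1 / (g1 + g2)
                if p < 1e-12:
                    p = 1e-12
                elif p > 1.0 - 1e-12:
                    p = 1.0 - 1e-12
                P[l, 0] = p
                if sweep >= burn_in:
                    lnp += s1[l] * math.log(p) + s0[l] * math.log(1.0 - p)
            alpha_trace[sweep] = alpha
            if sweep >= burn_in:
                Q_sum += Q
                P_sum += P
                lnp_trace[n_rec] = lnp
                n_rec += 1
        return (Q_sum / n_iter, P_sum / n_iter, lnp_trace, alpha_trace, 0.0)
    for sweep in range(total):
        record = sweep >= burn_in
        n_ik = np.zeros((n, K))
        c1 = np.full((L, K), lam)           # Beta posterior pseudo-counts
        c0 = np.full((L, K), lam)
        lnp = 0.0
        prod = 1.0                          # running likelihood product;
                                            # log-flushed near underflow
        for i in range(n):
            for l in range(L):
                g = doses[i, l]
                if g < 0:
                    continue
                # homozygotes: both copies carry the same allele and are iid
                # given (Q, P); their origin pair is drawn with one uniform
                # over the K(K+1)/2 unordered outcomes.  Hets need both
                # weight vectors and one draw per allele class.
                if g != 1:
                    t1 = 0.0
                    if g == 2:
                        for k in range(K):
                            w1[k] = Q[i, k] * P[l, k]
                            t1 += w1[k]
                    else:
                        for k in range(K):
                            w1[k] = Q[i, k] * (1.0 - P[l, k])
                            t1 += w1[k]
                    u, rs = _next_uniform(rs)
                    u *= t1 * t1
                    acc = 0.0
                    ka = K - 1
                    kb = K - 1
                    done = False
                    for a in range(K):
                        if done:
                            break
                        acc += w1[a] * w1[a]
                        if u <= acc:
                            ka = a
                            kb = a
                            break
                        for b in range(a + 1, K):
                            acc += 2.0 * w1[a] * w1[b]
                            if u <= acc:
                                ka = a
                                kb = b
                                done = True
                                break
                    n_ik[i, ka] += 1.0
                    n_ik[i, kb] += 1.0
                    if g == 2:
                        c1[l, ka] += 1.0
                        c1[l, kb] += 1.0
                    else:
                        c0[l, ka] += 1.0
                        c0[l, kb] += 1.0
                    if record:
                        prod *= t1 * t1
                        if prod < 1e-280:
                            lnp += math.log(prod)
                            prod = 1.0
                else:
                    t1 = 0.0
                    t0 = 0.0
                    for k in range(K):
                        w1[k] = Q[i, k] * P[l, k]
                        t1 += w1[k]
                        w0[k] = Q[i, k] * (1.0 - P[l, k])
                        t0 += w0[k]
                    u, rs = _next_uniform(rs)
                    u *= t1
                    acc = 0.0
                    k_hit = K - 1
                    for k in range(K):
                        acc += w1[k]
                        if u <= acc:
                            k_hit = k
                            break
                    n_ik[i, k_hit] += 1.0
                    c1[l, k_hit] += 1.0
                    u, rs = _next_uniform(rs)
                    u *= t0
                    acc = 0.0
                    k_hit = K - 1
                    for k in range(K):
                        acc += w0[k]
                        if u <= acc:
                            k_hit = k
                            break
                    n_ik[i, k_hit] += 1.0
                    c0[l, k_hit] += 1.0
                    if record:
                        prod *= t1 * t0
                        if prod < 1e-280:
                            lnp += math.log(prod)
                            prod = 1.0
        # P | Z  ~ Beta(lam + #B, lam + #A) per locus and population
        for l in range(L):
            for k in range(K):
                g1 = np.random.gamma(c1[l, k], 1.0)
                g2 = np.random.gamma(c0[l, k], 1.0)
                tot = g1 + g2
                if tot <= 0.0:
                    P[l, k] = 0.5
                else:
                    P[l, k] = g1 / tot
                if P[l, k] < 1e-12:
                    P[l, k] = 1e-12
                elif P[l, k] > 1.0 - 1e-12:
                    P[l, k] = 1.0 - 1e-12
        # Q | Z ~ Dirichlet(alpha + n_ik) per sample
        sum_log_q = 0.0
        for i in range(n):
            s = 0.0
            for k in range(K):
                v = np.random.gamma(alpha + n_ik[i, k], 1.0)
                if v < 1e-300:
                    v = 1e-300
                Q[i, k] = v
                s += v
            for k in range(K):
                Q[i, k] /= s
                sum_log_q += math.log(Q[i, k])
        # alpha | Q by Metropolis with uniform prior on (0, alpha_max)
        if K > 1:
            a_new = alpha + alpha_prop_sd * np.random.standard_normal()
            if 0.0 < a_new < alpha_max:
                logr = n * (math.lgamma(K * a_new) - K * math.lgamma(a_new)
                            - math.lgamma(K * alpha) + K * math.lgamma(alpha))
                logr += (a_new - alpha) * sum_log_q
                if logr >= 0.0 or math.log(np.random.random()) < logr:
                    alpha = a_new
                    n_acc += 1
        alpha_trace[sweep] = alpha
        if record:
            Q_sum += Q
            P_sum += P
            lnp_trace[n_rec] = lnp + math.log(prod)
            n_rec += 1
    return (Q_sum / n_iter, P_sum / n_iter, lnp_trace, alpha_trace,
            n_acc / total)


def run_admixture_mcmc(
    gm: GenotypeMatrix,
    K: int,
    burn_in: int = DEFAULT_BURN_IN,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    lam: float = DEFAULT_LAMBDA,
    alpha0: float = DEFAULT_ALPHA0,
    alpha_prop_sd: float = DEFAULT_ALPHA_PROP_SD,
    alpha_max: float = DEFAULT_ALPHA_MAX,
) -> StructureRun:
    """Gibbs-sample the admixture model at a fixed number of populations K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_samples:
        raise ValueError(f"K={K} exceeds the {gm.n_samples} samples")
    if burn_in < 1 or iterations < 2:
        raise ValueError("need burn_in >= 1 and iterations >= 2")
    Q, P, lnp, a_trace, acc = _gibbs(
        np.ascontiguousarray(gm.doses), K, int(burn_in), int(iterations),
        int(seed) % (2**31 - 1), float(lam), float(alpha0),
        float(alpha_prop_sd), float(alpha_max),
    )
    if K > 1 and acc < 0.01:
        logger.warning("K=%d seed=%d: alpha acceptance %.2f%% (<1%%)",
                       K, seed, 100 * acc)
    lnP_data = float(np.mean(lnp) - np.var(lnp) / 2.0)
    return StructureRun(K=K, seed=int(seed), burn_in=int(burn_in),
                        iterations=int(iterations), lnP_data=lnP_data,
                        Q=Q, P=P, lnp_trace=lnp, alpha_trace=a_trace,
                        alpha_acceptance=float(acc))


def replicate_seed(master_seed: int, K: int, rep: int) -> int:
    """Deterministic per-run seed: master + 1000 K + rep (kept below 2^31)."""
    return (int(master_seed) + 1000 * K + rep) % (2**31 - 1)


def run_k_grid(
    gm: GenotypeMatrix,
    k_values,
    n_reps: int = 7,
    burn_in: int = DEFAULT_BURN_IN,
    iterations: int = DEFAULT_ITERATIONS,
    master_seed: int = 0,
    **kwargs,
) -> dict[int, list[StructureRun]]:
    """Replicate runs over a K grid (K = 1..10 x 7 runs in the full design)."""
    runs: dict[int, list[StructureRun]] = {}
    for K in k_values:
        runs[K] = [
            run_admixture_mcmc(gm, K, burn_in, iterations,
                               seed=replicate_seed(master_seed, K, r), **kwargs)
            for r in range(n_reps)
        ]
        logger.info("K=%d: mean lnP = %.1f",
                    K, np.mean([r.lnP_data for r in runs[K]]))
    return runs


# ---------------------------------------------------------------------------
# Evanno Delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(lnp_by_k: dict[int, list[float]]) -> EvannoResult:
    """Evanno statistics from replicate lnP(data) values per K.

    Requires at least 3 consecutive K values with >= 2 replicates each.
    Delta-K = mean|L''(K)| / sd(L(K)) is defined for interior K only;
    a zero replicate sd leaves Delta-K undefined at that K (excluded from
    the argmax with a warning).
    """
    ks = sorted(lnp_by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(lnp_by_k[k]) < 2:
            raise ValueError(f"K={k}: need >= 2 replicates")
    mean_l = {k: float(np.mean(lnp_by_k[k])) for k in ks}
    sd_l = {k: float(np.std(lnp_by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        l1 = mean_l[k] - mean_l[k - 1] if k - 1 in mean_l else np.nan
        if k - 1 in mean_l and k + 1 in mean_l:
            l2 = abs((mean_l[k + 1] - mean_l[k]) - l1)
            if sd_l[k] == 0:
                logger.warning("Evanno: sd(L)=0 at K=%d, Delta-K undefined", k)
                dk = np.nan
            else:
                dk = l2 / sd_l[k]
        else:
            l2, dk = np.nan, np.nan
        rows.append({"K": k, "mean_L": mean_l[k], "sd_L": sd_l[k],
                     "L_prime": l1, "abs_L_doubleprime": l2, "delta_K": dk})
    table = pd.DataFrame(rows)
    dk = table["delta_K"]
    if dk.notna().any() and np.nanmax(dk.to_numpy()) > 0:
        best = int(table.loc[dk.idxmax(), "K"])
    else:
        logger.warning("Evanno: Delta-K flat or undefined everywhere; no best K")
        best = None
    return EvannoResult(table=table, best_K=best)


# ---------------------------------------------------------------------------
# membership and run aggregation
# ---------------------------------------------------------------------------

def assign_membership(
    Q: np.ndarray,
    sample_ids=None,
    strong: float = STRONG_Q,
    moderate: float = MODERATE_Q,
) -> pd.DataFrame:
    """Classify samples by their best admixture coefficient.

    ``strong`` membership means q_best strictly > 0.7, ``moderate`` means
    0.5 < q_best <= 0.7, anything else is ``admixed`` (q_best exactly 0.5 is
    admixed: the inequalities are strict).
    """
    Q = np.asarray(Q, dtype=float)
    best = Q.argmax(axis=1)
    q_best = Q[np.arange(len(Q)), best]
    cls = np.where(q_best > strong, "strong",
                   np.where(q_best > moderate, "moderate", "admixed"))
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(len(Q))]
    return pd.DataFrame({
        "sample_id": ids,
        "subpopulation": [f"SP{b + 1}" for b in best],
        "q_best": q_best,
        "membership": cls,
    })


def align_q_columns(Q: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute Q's columns to best match *reference* (greedy max correlation).

    Label switching between runs is resolved by repeatedly pairing the
    as-yet-unmatched reference/run column pair with the highest Pearson
    correlation; exact ties break deterministically on column index.
    """
    Q = np.asarray(Q, float)
    R = np.asarray(reference, float)
    K = Q.shape[1]
    if K == 1:
        return Q.copy()
    # correlation; constant columns get 0 correlation
    def corr(a, b):
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    C = np.array([[corr(R[:, i], Q[:, j]) for j in range(K)] for i in range(K)])
    perm = np.full(K, -1)
    used_r, used_q = set(), set()
    order = sorted(
        ((i, j) for i in range(K) for j in range(K)),
        key=lambda ij: (-C[ij], ij[0], ij[1]),
    )
    for i, j in order:
        if i in used_r or j in used_q:
            continue
        perm[i] = j
        used_r.add(i)
        used_q.add(j)
    return Q[:, perm]


def aggregate_runs(runs: list[StructureRun] | list[np.ndarray]) -> np.ndarray:
    """Label-aligned mean Q over replicate runs at the same K."""
    qs = [r.Q if isinstance(r, StructureRun) else np.asarray(r, float)
          for r in runs]
    if not qs:
        raise ValueError("no runs to aggregate")
    if len({q.shape for q in qs}) != 1:
        raise ValueError("runs disagree on shape (same K required)")
    ref = qs[0]
    aligned = [ref] + [align_q_columns(q, ref) for q in qs[1:]]
    return np.mean(aligned, axis=0)
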