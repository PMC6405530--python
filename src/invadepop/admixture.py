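"""Admixture-model clustering by Gibbs sampling.

Each individual's two gene copies per locus originate independently from
one of K clusters; cluster k carries an allele frequency p_kl per locus
and individual i an ancestry vector q_i on the K-simplex (Dirichlet(alpha)
prior, uniform Beta(1,1) prior on frequencies).  The collapsed latent
variables Z (per-copy cluster origins) make all conditional updates
conjugate except the Dirichlet concentration alpha, which moves by
random-walk Metropolis on a uniform (0, 10] prior.

Model-order selection uses the second-order rate of change of the model
evidence across K (the Evanno delta-K statistic); replicate runs are
aligned by optimally matching cluster columns against a reference run, and
individuals/populations are called assigned or admixed with the
credible-interval overlap rule: an individual is significantly assigned to
its top cluster only when that cluster's interval does not overlap any
other cluster's interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix, metadata_for

__all__ = [
    "RunSummary",
    "KSelection",
    "gibbs_admixture",
    "evanno_deltaK",
    "align_runs",
    "average_runs",
    "assign_individuals",
    "assign_populations",
]

_EPS = 1e-12


@dataclass
class RunSummary:
    """Posterior summaries of one MCMC replicate at fixed K."""

    K: int
    replicate: int
    mean_lnPD: float
    Q_mean: np.ndarray  # (N, K)
    Q_low: np.ndarray  # (N, K) equal-tailed credible-interval bounds
    Q_high: np.ndarray
    individual_ids: list[str]
    ci_level: float
    loglik_trace: np.ndarray = field(repr=False, default=None)
    alpha_trace: np.ndarray = field(repr=False, default=None)
    alpha_converged: bool = True


@dataclass
class KSelection:
    table: pd.DataFrame  # columns K, mean_lnPD, sd_lnPD, deltaK
    chosen_K: int


def _sample_multinomial_counts(n, weights, rng):
    """Multinomial counts with per-cell n (..., ) and probs (..., K).

    Uses the conditional-binomial chain so the draw vectorizes over any
    leading shape.
    """
    K = weights.shape[-1]
    counts = np.zeros(n.shape + (K,), dtype=np.int64)
    rem = n.astype(np.int64).copy()
    tail = weights.sum(axis=-1)
    for k in range(K - 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            pk = np.where(tail > 0, weights[..., k] / tail, 0.0)
        pk = np.clip(pk, 0.0, 1.0)
        draw = rng.binomial(rem, pk)
        counts[..., k] = draw
        rem -= draw
        tail = tail - weights[..., k]
    counts[..., K - 1] = rem
    return counts


def _log_dirichlet_sym(q, alpha):
    K = q.shape[1]
    return (
        gammaln(K * alpha) - K * gammaln(alpha)
    ) * q.shape[0] + (alpha - 1) * np.log(np.clip(q, _EPS, None)).sum()


def gibbs_admixture(
    genotypes: GenotypeMatrix,
    K: int,
    burn_in: int = 2000,
    iters: int = 5000,
    thin: int = 5,
    seed: int | None = None,
    infer_alpha: bool = True,
    alpha_init: float = 1.0,
    ci: float = 0.90,
    replicate: int = 0,
) -> RunSummary:
    """Run one Gibbs-sampling replicate of the admixture model.

    Missing calls contribute no gene copies (no likelihood term).  The
    model evidence is estimated as mean(loglik) - var(loglik)/2 over the
    retained samples; alpha is flagged non-converged when its trace spans
    more than 0.2 over the second half of sampling.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    rng = np.random.default_rng(seed)
    calls = genotypes.calls
    N, L = calls.shape
    missing = calls == MISSING
    alt_n = np.where(missing, 0, calls).astype(np.int64)
    ref_n = np.where(missing, 0, 2 - calls).astype(np.int64)

    P = rng.uniform(0.1, 0.9, size=(K, L))
    Q = rng.dirichlet(np.ones(K), size=N)
    alpha = float(alpha_init)
    alpha_step = 0.05

    n_keep = iters // thin
    q_samples = np.empty((n_keep, N, K))
    logliks = np.empty(n_keep)
    alphas = np.empty(n_keep)
    kept = 0

    for it in range(burn_in + iters):
        # Z | P, Q : per-copy cluster origins, summarised as counts
        w_alt = Q[:, None, :] * P.T[None, :, :]  # (N, L, K)
        w_ref = Q[:, None, :] * (1 - P.T)[None, :, :]
        z_alt = _sample_multinomial_counts(alt_n, w_alt, rng)
        z_ref = _sample_multinomial_counts(ref_n, w_ref, rng)

        # P | Z : Beta posterior with uniform prior
        alt_k = z_alt.sum(axis=0).T  # (K, L)
        ref_k = z_ref.sum(axis=0).T
        P = rng.beta(1 + alt_k, 1 + ref_k)

        # Q | Z, alpha : Dirichlet posterior
        m = (z_alt + z_ref).sum(axis=1)  # (N, K)
        gam = rng.gamma(alpha + m, 1.0)
        gam = np.clip(gam, _EPS, None)
        Q = gam / gam.sum(axis=1, keepdims=True)

        # alpha | Q : random-walk Metropolis, uniform prior on (0, 10]
        if infer_alpha and K > 1:
            prop = alpha + rng.normal(0, alpha_step)
            if 0 < prop <= 10:
                delta = _log_dirichlet_sym(Q, prop) - _log_dirichlet_sym(Q, alpha)
                if np.log(rng.uniform()) < delta:
                    alpha = prop

        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            pi = np.clip(Q @ P, _EPS, 1 - _EPS)
            ll = np.where(
                missing,
                0.0,
                np.where(calls == 1, np.log(2.0), 0.0)
                + alt_n * np.log(pi)
                + ref_n * np.log(1 - pi),
            ).sum()
            q_samples[kept] = Q
            logliks[kept] = ll
            alphas[kept] = alpha
            kept += 1

    q_samples = q_samples[:kept]
    logliks = logliks[:kept]
    alphas = alphas[:kept]
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    q_low, q_high = np.quantile(q_samples, [lo, hi], axis=0)
    half = alphas[len(alphas) // 2 :]
    converged = bool(half.size == 0 or np.ptp(half) <= 0.2)
    mean_lnPD = float(logliks.mean() - logliks.var() / 2)
    return RunSummary(
        K=K,
        replicate=replicate,
        mean_lnPD=mean_lnPD,
        Q_mean=q_samples.mean(axis=0),
        Q_low=q_low,
        Q_high=q_high,
        individual_ids=list(genotypes.individual_ids),
        ci_level=ci,
        loglik_trace=logliks,
        alpha_trace=alphas,
        alpha_converged=converged,
    )


def evanno_deltaK(run_summaries: list[RunSummary]) -> KSelection:
    """Evanno delta-K model-order selection from replicate evidence values.

    delta K(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)), with L(K) the mean
    evidence across replicates.  Undefined at the boundary K values and
    where the between-replicate sd is zero (reported as NaN).
    """
    by_k: dict[int, list[float]] = {}
    for rs in run_summaries:
        by_k.setdefault(rs.K, []).append(rs.mean_lnPD)
    ks = sorted(by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("delta K needs >= 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("delta K needs >= 2 replicates per K")
    mean = np.array([np.mean(by_k[k]) for k in ks])
    sd = np.array([np.std(by_k[k], ddof=1) for k in ks])
    delta = np.full(len(ks), np.nan)
    for j in range(1, len(ks) - 1):
        second = abs(mean[j + 1] - 2 * mean[j] + mean[j - 1])
        delta[j] = second / sd[j] if sd[j] > 0 else np.nan
    table = pd.DataFrame(
        {"K": ks, "mean_lnPD": mean, "sd_lnPD": sd, "deltaK": delta}
    )
    if np.isnan(delta[1:-1]).all():
        chosen = ks[0]
    else:
        chosen = ks[int(np.nanargmax(delta))]
    return KSelection(table=table, chosen_K=int(chosen))


def _permute(rs: RunSummary, perm: np.ndarray) -> RunSummary:
    return RunSummary(
        K=rs.K,
        replicate=rs.replicate,
        mean_lnPD=rs.mean_lnPD,
        Q_mean=rs.Q_mean[:, perm],
        Q_low=rs.Q_low[:, perm],
        Q_high=rs.Q_high[:, perm],
        individual_ids=rs.individual_ids,
        ci_level=rs.ci_level,
        loglik_trace=rs.loglik_trace,
        alpha_trace=rs.alpha_trace,
        alpha_converged=rs.alpha_converged,
    )


def align_runs(
    run_summaries: list[RunSummary], reference: int = 0
) -> list[RunSummary]:
    """Resolve label switching by matching cluster columns to a reference run.

    For each run the column permutation minimising the total L1 distance
    sum_ik |q_ik - q_ik_ref| is found by solving the equivalent linear
    assignment problem exactly (optimal for any K).
    """
    ref = run_summaries[reference]
    if any(rs.K != ref.K or rs.individual_ids != ref.individual_ids for rs in run_summaries):
        raise ValueError("all runs must share K and individuals")
    aligned = []
    for rs in run_summaries:
        cost = np.abs(
            rs.Q_mean[:, :, None] - ref.Q_mean[:, None, :]
        ).sum(axis=0)  # cost[j, k]: run column j placed at reference column k
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(rs.K, dtype=int)
        perm[cols] = rows
        aligned.append(_permute(rs, perm))
    return aligned


def alignment_cost(run: RunSummary, ref: RunSummary) -> float:
    """Minimal total L1 column-matching cost between two runs (diagnostic)."""
    cost = np.abs(run.Q_mean[:, :, None] - ref.Q_mean[:, None, :]).sum(axis=0)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


def exhaustive_alignment_cost(run: RunSummary, ref: RunSummary) -> float:
    """Brute-force minimum over all K! column permutations (small K only)."""
    best = np.inf
    for perm in itertools.permutations(range(run.K)):
        c = np.abs(run.Q_mean[:, perm] - ref.Q_mean).sum()
        best = min(best, c)
    return float(best)


def average_runs(aligned: list[RunSummary]) -> RunSummary:
    """Element-wise average of aligned replicate summaries."""
    ref = aligned[0]
    return RunSummary(
        K=ref.K,
        replicate=-1,
        mean_lnPD=float(np.mean([rs.mean_lnPD for rs in aligned])),
        Q_mean=np.mean([rs.Q_mean for rs in aligned], axis=0),
        Q_low=np.mean([rs.Q_low for rs in aligned], axis=0),
        Q_high=np.mean([rs.Q_high for rs in aligned], axis=0),
        individual_ids=ref.individual_ids,
        ci_level=ref.ci_level,
        alpha_converged=all(rs.alpha_converged for rs in aligned),
    )


ADMIXED = "admixed"


def assign_individuals(summary: RunSummary) -> pd.DataFrame:
    """Call each individual assigned-to-cluster or admixed.

    The top cluster by posterior mean is called only when its credible
    interval overlaps no other cluster's interval; ties in the argmax are
    conservatively called admixed.
    """
    calls = []
    for i, ind in enumerate(summary.individual_ids):
        q = summary.Q_mean[i]
        top = int(np.argmax(q))
        tied = np.flatnonzero(q == q[top])
        if tied.size > 1:
            calls.append(ADMIXED)
            continue
        lo_t, hi_t = summary.Q_low[i, top], summary.Q_high[i, top]
        overlap = False
        for k in range(summary.K):
            if k == top:
                continue
            if not (lo_t > summary.Q_high[i, k] or hi_t < summary.Q_low[i, k]):
                overlap = True
                break
        calls.append(ADMIXED if overlap else f"cluster_{top + 1}")
    return pd.DataFrame(
        {"individual_id": summary.individual_ids, "call": calls}
    )


def assign_populations(
    individual_calls: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Population-level calls from individual calls.

    A population is assigned to the cluster holding the largest proportion
    of significantly assigned individuals; on a tie, or when all
    individuals are admixed, the population is called admixed.
    """
    merged = individual_calls.merge(
        metadata[["individual_id", "population"]], on="individual_id", how="left"
    )
    rows = []
    for pop, grp in merged.groupby("population", sort=True):
        if grp.empty:
            raise ValueError(f"empty population {pop!r}")
        n = len(grp)
        props = grp["call"].value_counts() / n
        cluster_props = props.drop(ADMIXED, errors="ignore")
        if cluster_props.empty:
            call = ADMIXED
        else:
            best = cluster_props.max()
            winners = cluster_props[cluster_props == best].index.tolist()
            call = winners[0] if len(winners) == 1 else ADMIXED
        rows.append(
            {
                "population": pop,
                "call": call,
                "prop_admixed": float(props.get(ADMIXED, 0.0)),
                **{f"prop_{c}": float(v) for c, v in cluster_props.items()},
            }
        )
    return pd.DataFrame(rows).fillna(0.0)


def admixture_replicates(
    genotypes: GenotypeMatrix,
    K: int,
    replicates: int = 5,
    seed: int | None = None,
    **kwargs,
) -> list[RunSummary]:
    """Run several replicates at one K with independent seeded streams."""
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=replicates)
    return [
        gibbs_admixture(genotypes, K, seed=int(s), replicate=r, **kwargs)
        for r, s in enumerate(seeds)
    ]
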