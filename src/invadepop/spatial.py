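"""Isolation-by-distance analysis.

Under restricted dispersal, differentiation between population pairs grows
with geographic separation.  Two complementary tests are provided: the
regression of linearised differentiation F_ST/(1 - F_ST) on the log of
great-circle distance (with a Pearson correlation test over all pairs,
whose non-independence is acknowledged), and a one-sided Mantel
permutation test between a genetic distance matrix (Cavalli-Sforza &
Edwards chord distance) and the geographic distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import haversine_distances

from .io import MISSING, GenotypeMatrix, metadata_for

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "IBDResult",
    "geo_distance_matrix",
    "rousset_ibd",
    "chord_distance_matrix",
    "mantel_test",
    "ibd_analysis",
]


@dataclass
class IBDResult:
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    mantel_r: float
    mantel_p: float
    n_perm: int
    n_populations: int


def population_coordinates(metadata: pd.DataFrame, populations=None) -> pd.DataFrame:
    """Per-population (latitude, longitude): the mean of member coordinates."""
    agg = (
        metadata.groupby("population", sort=True)[["latitude", "longitude"]]
        .mean()
    )
    if populations is not None:
        agg = agg.loc[list(populations)]
    return agg


def geo_distance_matrix(
    metadata: pd.DataFrame, populations=None
) -> pd.DataFrame:
    """Great-circle (haversine) distances between population centroids, km."""
    coords = population_coordinates(metadata, populations)
    rad = np.radians(coords[["latitude", "longitude"]].to_numpy())
    km = haversine_distances(rad) * EARTH_RADIUS_KM
    return pd.DataFrame(km, index=coords.index, columns=coords.index)


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices_from(m, k=-1)
    return m[i, j]


def rousset_ibd(pairwise_fst: pd.DataFrame, km: pd.DataFrame):
    """OLS of F_ST/(1 - F_ST) on ln(km distance), with a Pearson test.

    Pairs at zero distance (identical coordinates) or with F_ST = 1 are
    excluded with a warning.  A response with zero variance yields r = 0
    and an undefined (NaN) p-value.
    """
    pops = list(pairwise_fst.index)
    km = km.loc[pops, pops]
    f = pairwise_fst.to_numpy(dtype=float)
    d = km.to_numpy(dtype=float)
    y_all = _lower_triangle(f)
    d_all = _lower_triangle(d)
    keep = d_all > 0
    if (~keep).any():
        warnings.warn(
            f"{(~keep).sum()} population pair(s) at zero distance excluded "
            "from the log-distance regression"
        )
    sat = y_all >= 1
    if sat.any():
        warnings.warn(f"{sat.sum()} pair(s) with F_ST = 1 excluded")
        keep &= ~sat
    x = np.log(d_all[keep])
    y = y_all[keep] / (1 - y_all[keep])
    if x.size < 3:
        raise ValueError("too few population pairs for the IBD regression")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 0.0, float("nan"), 0.0, float(y.mean())
    res = stats.linregress(x, y)
    return (
        float(res.rvalue),
        float(res.pvalue),
        float(res.slope),
        float(res.intercept),
    )


def chord_distance_matrix(
    genotypes: GenotypeMatrix, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Cavalli-Sforza & Edwards chord distance between populations.

    D = (2/pi) * sqrt(2 * (1 - fbar)), with fbar the mean over shared
    non-missing loci of sum_a sqrt(p_a q_a).  Populations sharing no locus
    raise an error.
    """
    meta = metadata_for(genotypes, metadata)
    pops = sorted(meta["population"].unique())
    n_pops = len(pops)
    L = genotypes.n_loci
    freq = np.full((n_pops, L), np.nan)
    for i, pop in enumerate(pops):
        rows = meta.index[meta["population"] == pop].to_numpy()
        sub = genotypes.calls[rows]
        present = sub != MISSING
        n = present.sum(axis=0)
        alt = np.where(present, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq[i] = np.where(n > 0, alt / (2 * n), np.nan)
    out = np.zeros((n_pops, n_pops))
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            shared = ~(np.isnan(freq[i]) | np.isnan(freq[j]))
            if not shared.any():
                raise ValueError(
                    f"populations {pops[i]!r} and {pops[j]!r} share no genotyped locus"
                )
            p, q = freq[i, shared], freq[j, shared]
            fbar = np.mean(np.sqrt(p * q) + np.sqrt((1 - p) * (1 - q)))
            val = (2 / np.pi) * np.sqrt(2 * max(0.0, 1 - fbar))
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=pops, columns=pops)


def mantel_test(
    dist_a: pd.DataFrame,
    dist_b: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
):
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the strict lower triangles; the null
    is generated by jointly permuting rows and columns of the second
    matrix; p = (1 + #{r_perm >= r_obs}) / (n_perm + 1) for the one-sided
    'greater' alternative that isolation by distance predicts.
    """
    pops = list(dist_a.index)
    if len(pops) < 4:
        raise ValueError("Mantel test needs at least 4 populations")
    b = dist_b.loc[pops, pops].to_numpy(dtype=float)
    a = dist_a.to_numpy(dtype=float)
    x = _lower_triangle(a)
    rng = np.random.default_rng(seed)

    def corr(mat):
        y = _lower_triangle(mat)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(b)
    n = len(pops)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(b[np.ix_(perm, perm)])
        if alternative == "greater":
            hit = r_p >= r_obs
        elif alternative == "less":
            hit = r_p <= r_obs
        else:
            hit = abs(r_p) >= abs(r_obs)
        count += hit
    p = (1 + count) / (n_perm + 1)
    return r_obs, float(p)


def ibd_analysis(
    pairwise_fst: pd.DataFrame,
    genotypes: GenotypeMatrix,
    metadata: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
) -> IBDResult:
    """Full isolation-by-distance summary for one set of populations."""
    pops = list(pairwise_fst.index)
    km = geo_distance_matrix(metadata, populations=pops)
    r, p, slope, intercept = rousset_ibd(pairwise_fst, km)
    chord = chord_distance_matrix(genotypes, metadata).loc[pops, pops]
    mr, mp = mantel_test(km, chord, n_perm=n_perm, seed=seed)
    return IBDResult(
        pearson_r=r,
        pearson_p=p,
        slope=slope,
        intercept=intercept,
        mantel_r=mr,
        mantel_p=mp,
        n_perm=n_perm,
        n_populations=len(pops),
    )
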