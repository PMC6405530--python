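"""Principal component analysis of individual allele counts.

Missing calls are mean-imputed per locus before centering (so they fall
at the origin of that locus's axis and carry no signal), components come
from the singular value decomposition of the centered matrix, and each
group of individuals can be summarised by a 95% concentration ellipse on
any pair of axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import MISSING, GenotypeMatrix, metadata_for

__all__ = ["PCAResult", "genotype_pca", "group_ellipses"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # individuals x components
    explained_variance: np.ndarray
    loadings: pd.DataFrame  # loci x components
    centered: bool
    scaled: bool


def genotype_pca(
    genotypes: GenotypeMatrix,
    n_components: int | None = None,
    center: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA of the individuals x loci alternate-allele-count matrix.

    Loci with every call missing are dropped with a warning.  The sign of
    each component is fixed so its largest-magnitude loading is positive,
    making outputs deterministic.
    """
    if genotypes.n_individuals < 2 or genotypes.n_loci < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 loci")
    X = genotypes.calls.astype(float)
    X[genotypes.calls == MISSING] = np.nan
    all_missing = np.isnan(X).all(axis=0)
    loci = [l for l, drop in zip(genotypes.locus_ids, all_missing) if not drop]
    if all_missing.any():
        warnings.warn(f"dropping {all_missing.sum()} fully missing locus/loci")
        X = X[:, ~all_missing]
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    var = S**2 / (n - 1)
    max_rank = min(n - 1 if center else n, X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    U, S, Vt, var = U[:, :k], S[:k], Vt[:k], var[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U * S
    comp_names = [f"PC{c + 1}" for c in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=genotypes.individual_ids, columns=comp_names),
        explained_variance=var,
        loadings=pd.DataFrame(Vt.T, index=loci, columns=comp_names),
        centered=center,
        scaled=scale,
    )


def group_ellipses(
    result: PCAResult,
    metadata: pd.DataFrame,
    group_by: str = "range_label",
    components: tuple[str, str] = ("PC1", "PC2"),
    level: float = 0.95,
) -> pd.DataFrame:
    """Concentration-ellipse parameters per group on two score axes.

    The ellipse is the chi-squared(2 df) quantile contour of the group's
    score covariance: columns give the center, the covariance entries and
    the squared Mahalanobis radius covering ``level`` of the mass.
    """
    meta = metadata.set_index("individual_id")
    rows = []
    radius2 = chi2.ppf(level, df=2)
    pts_all = result.scores[list(components)]
    for grp, ids in meta.groupby(group_by, sort=True).groups.items():
        ids = [i for i in ids if i in pts_all.index]
        pts = pts_all.loc[ids].to_numpy()
        if len(pts) < 3:
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts.T)
        rows.append(
            {
                "group": grp,
                "cx": center[0],
                "cy": center[1],
                "cov_xx": cov[0, 0],
                "cov_xy": cov[0, 1],
                "cov_yy": cov[1, 1],
                "level": level,
                "mahalanobis_r2": radius2,
            }
        )
    return pd.DataFrame(rows)
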