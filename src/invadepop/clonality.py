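"""Clone detection and clonal-diversity statistics.

Trees that propagate vegetatively can be sampled twice: two ramets of one
genet carry the same multilocus genotype (MLG).  Within each population,
loci with any missing call in that population are dropped, and individuals
identical at all retained loci are grouped into clone classes.  Clonal
diversity is summarised by R = (G - 1)/(N - 1), where N is the sample size
and G the number of unique MLGs; R is 0 for a monoclonal stand and 1 when
every sample is distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeMatrix, metadata_for


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given inputs."""


@dataclass
class ClonalReport:
    """Per-population clone census."""

    population: str
    N: int
    G: int
    R: float
    clone_groups: list[list[str]]
    kept_representatives: list[str]
    n_retained_loci: int
    excluded: bool = False  # scanned but excluded from range-level testing


@dataclass
class RangeClonalityTest:
    """Yates-corrected chi-squared test of clone frequency between ranges."""

    contingency: np.ndarray  # rows: ranges; cols: (clones, unique genotypes)
    range_labels: list[str]
    chi2: float
    df: int
    p_value: float


def clonal_R(N: int, G: int) -> float:
    """Clonal diversity R = (G - 1)/(N - 1).

    Requires N >= 2 (undefined for a single sample) and 1 <= G <= N.
    """
    if N < 2:
        raise UndefinedStatisticError(f"R undefined for N={N} (< 2 samples)")
    if not 1 <= G <= N:
        raise ValueError(f"G={G} violates 1 <= G <= N={N}")
    return (G - 1) / (N - 1)


def _clone_partition(calls: np.ndarray, ids: list[str]) -> list[list[str]]:
    """Group individuals with identical rows; groups ordered by first member."""
    groups: dict[bytes, list[str]] = {}
    for i, ind in enumerate(ids):
        key = calls[i].tobytes()
        groups.setdefault(key, []).append(ind)
    return list(groups.values())


def detect_clones(
    genotypes: GenotypeMatrix,
    metadata: pd.DataFrame,
    exclude_sources: set[str] | frozenset[str] = frozenset(
        {"common_garden", "lab_seedling"}
    ),
):
    """Detect within-population clones and return a clone-free matrix.

    Within each population only loci with no missing call in that
    population are retained; individuals identical at all retained loci
    form one clone group and the first individual (input order) represents
    the group.  Populations whose individuals come from excluded source
    types (seed-grown material, expected clone-free) are scanned and
    reported with ``excluded=True`` but their counts are meant to be left
    out of range-level clonality testing.

    Returns
    -------
    reports : list of ClonalReport
    clone_free : GenotypeMatrix with one representative per clone group.
    """
    meta = metadata_for(genotypes, metadata)
    exclude_sources = set(exclude_sources)
    reports: list[ClonalReport] = []
    keep_ids: list[str] = []
    for pop in meta["population"].unique():
        pop_rows = meta.index[meta["population"] == pop].to_numpy()
        ids = [genotypes.individual_ids[i] for i in pop_rows]
        sub = genotypes.calls[pop_rows]
        complete = ~(sub == MISSING).any(axis=0)
        if not complete.any():
            raise UndefinedStatisticError(
                f"population {pop!r}: no locus is complete; clone status undecidable"
            )
        groups = _clone_partition(np.ascontiguousarray(sub[:, complete]), ids)
        reps = [g[0] for g in groups]
        N, G = len(ids), len(groups)
        sources = set(meta.loc[pop_rows, "source_type"])
        excluded = bool(sources & exclude_sources)
        reports.append(
            ClonalReport(
                population=str(pop),
                N=N,
                G=G,
                R=clonal_R(N, G) if N >= 2 else float("nan"),
                clone_groups=groups,
                kept_representatives=reps,
                n_retained_loci=int(complete.sum()),
                excluded=excluded,
            )
        )
        keep_ids.extend(reps)
    order = {ind: i for i, ind in enumerate(genotypes.individual_ids)}
    keep_ids.sort(key=order.__getitem__)
    return reports, genotypes.subset(individuals=keep_ids)


def range_clonality_test(
    reports: list[ClonalReport], metadata: pd.DataFrame
) -> RangeClonalityTest:
    """Pearson chi-squared test (Yates continuity correction) of clonality by range.

    Each population contributes N - G clone individuals (every duplicate
    beyond its group representative) and G unique genotypes; populations
    flagged ``excluded`` (seed-grown sources) are omitted.
    """
    pop_range = metadata.drop_duplicates("population").set_index("population")[
        "range_label"
    ]
    counts: dict[str, list[int]] = {}
    for rep in reports:
        if rep.excluded:
            continue
        rng = str(pop_range[rep.population])
        row = counts.setdefault(rng, [0, 0])
        row[0] += rep.N - rep.G
        row[1] += rep.G
    if len(counts) != 2:
        raise ValueError(
            f"range clonality test needs exactly 2 ranges, found {sorted(counts)}"
        )
    labels = sorted(counts)
    table = np.array([counts[r] for r in labels], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedStatisticError(
            "chi-squared test undefined: a margin of the 2x2 table is zero"
        )
    res = stats.chi2_contingency(table, correction=True)
    return RangeClonalityTest(
        contingency=table.astype(int),
        range_labels=labels,
        chi2=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
    )


def reports_to_frame(reports: list[ClonalReport]) -> pd.DataFrame:
    """Tabular view of clone reports (one row per population)."""
    return pd.DataFrame(
        {
            "population": [r.population for r in reports],
            "N": [r.N for r in reports],
            "G": [r.G for r in reports],
            "R": [r.R for r in reports],
            "n_retained_loci": [r.n_retained_loci for r in reports],
            "excluded_from_test": [r.excluded for r in reports],
        }
    )
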