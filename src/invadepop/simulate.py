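"""Synthetic two-range SNP data generator.

The generator reproduces the statistical structure the analysis pipeline
assumes, with known ground truth:

* a native range of demes on a 1-D spatial gradient whose allele
  frequencies drift from a common ancestor (Balding-Nichols Beta draws
  with drift parameter F), smoothed along the gradient so nearby demes
  stay correlated (isolation by distance);
* an invasive range founded through a bottleneck: a small founder sample
  drawn from a subset of native demes defines the invasive gene pool,
  which each invasive population then re-drifts from;
* within-population clonal replication (sampled ramets of one genet),
  per-call missing data, and a high-MAF-ascertained SNP panel chosen from
  a small discovery sample, emulating panel ascertainment bias.

Defaults describe the study design the pipeline targets: 8 native demes,
an invasive range founded from 2 of them through ~10 founders, a full
~251-locus panel and an ascertained ~113-locus panel, and clone fractions
of roughly a quarter of invasive and a twelfth of native samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "ascertained_panel"]


@dataclass
class SimConfig:
    """Parameters of the two-range simulation (see module docstring)."""

    n_native_demes: int = 8
    n_invasive_pops: int = 8
    pop_size: tuple[int, int] = (10, 20)
    n_loci_full: int = 251
    n_loci_ascertained: int = 113
    F_native: float = 0.15
    ibd_strength: float = 1.0
    founder_demes: tuple[int, ...] = (0, 1)
    founder_size: int = 10
    extra_drift_invasive: float = 0.10
    clonal_rate: float = 0.25
    clonal_rate_native: float = 0.08
    missing_rate: float = 0.02
    discovery_panel_size: int = 9
    maf_threshold: float = 0.2
    n_common_garden: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_native_demes < 1 or self.n_loci_full < 1:
            raise ValueError("counts must be >= 1")
        if self.n_invasive_pops > 0:
            if not set(self.founder_demes) <= set(range(self.n_native_demes)):
                raise ValueError("founder_demes must be a subset of native demes")
            if self.founder_size < 1:
                raise ValueError("founder_size must be >= 1")
            if not 0 < self.extra_drift_invasive < 1:
                raise ValueError("extra_drift_invasive must lie in (0, 1)")
        if not 0 < self.F_native < 1:
            raise ValueError("F_native must lie in (0, 1)")
        if self.ibd_strength < 0:
            raise ValueError("ibd_strength must be >= 0")
        for name in ("clonal_rate", "clonal_rate_native", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in (0, 0.5)")
        lo, hi = self.pop_size
        if lo < 1 or hi < lo:
            raise ValueError("pop_size must be a (low, high) range with low >= 1")
        if self.n_common_garden > self.n_native_demes:
            raise ValueError("n_common_garden exceeds native deme count")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    deme_freqs: np.ndarray  # native demes x loci
    invasive_freqs: np.ndarray  # invasive pops x loci
    founder_pool_freqs: np.ndarray  # loci
    founder_demes: tuple[int, ...]
    clone_groups: dict[str, list[list[str]]]  # population -> partition
    ascertainment_mask: np.ndarray  # bool, length n_loci_full
    ascertained_locus_ids: list[str] = field(default_factory=list)


def _balding_nichols(rng, p: np.ndarray, F: float, size=None) -> np.ndarray:
    """Beta(p(1-F)/F, (1-p)(1-F)/F) draws; degenerate p passes through."""
    scale = (1 - F) / F
    p = np.clip(p, 0.0, 1.0)
    interior = (p > 0) & (p < 1)
    out = np.array(p if size is None else np.broadcast_to(p, size), dtype=float)
    if size is None:
        draw = rng.beta(np.clip(p * scale, 1e-9, None), np.clip((1 - p) * scale, 1e-9, None))
        out = np.where(interior, draw, p)
    else:
        a = np.clip(p * scale, 1e-9, None)
        b = np.clip((1 - p) * scale, 1e-9, None)
        draw = rng.beta(np.broadcast_to(a, size), np.broadcast_to(b, size))
        out = np.where(np.broadcast_to(interior, size), draw, out)
    return out


def _plant_clones(rng, geno: np.ndarray, ids: list[str], rate: float):
    """Replace a fraction of individuals with copies of remaining members.

    Returns the modified genotype block and the identity partition (one
    group per genet, listing its sampled ramets).
    """
    n = len(ids)
    k = int(np.floor(rate * n))
    k = min(k, n - 1)
    origin = np.arange(n)
    if k > 0:
        replaced = rng.choice(n, size=k, replace=False)
        donors_pool = np.setdiff1d(np.arange(n), replaced)
        donors = rng.choice(donors_pool, size=k, replace=True)
        geno[replaced] = geno[donors]
        origin[replaced] = donors
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(int(origin[i]), []).append(ids[i])
    ordered = sorted(groups.values(), key=lambda g: ids.index(g[0]))
    return geno, ordered


def simulate_dataset(config: SimConfig):
    """Generate (GenotypeMatrix, metadata DataFrame, SimTruth).

    The returned matrix carries the full locus panel; use
    :func:`ascertained_panel` to restrict it to the high-MAF panel.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_loci_full
    locus_ids = [f"L{j + 1:03d}" for j in range(L)]

    p_anc = rng.uniform(0.05, 0.95, size=L)

    # native deme frequencies: independent drift, then spatial smoothing
    D = config.n_native_demes
    x = _balding_nichols(rng, p_anc, config.F_native, size=(D, L))
    if config.ibd_strength > 0 and D > 1:
        pos = np.arange(D)
        W = np.exp(-np.abs(pos[:, None] - pos[None, :]) / config.ibd_strength)
        W /= W.sum(axis=1, keepdims=True)
        deme_freqs = W @ x
    else:
        deme_freqs = x

    # invasive gene pool: a founder sample from the founder demes
    if config.n_invasive_pops > 0:
        fd = np.array(config.founder_demes)
        founder_deme_of = fd[np.arange(config.founder_size) % fd.size]
        founder_geno = rng.binomial(2, deme_freqs[founder_deme_of])
        founder_pool = founder_geno.sum(axis=0) / (2 * config.founder_size)
        inv_freqs = np.stack(
            [
                _balding_nichols(rng, founder_pool, config.extra_drift_invasive)
                for _ in range(config.n_invasive_pops)
            ]
        )
    else:
        founder_pool = np.zeros(L)
        inv_freqs = np.zeros((0, L))

    pops = []
    for d in range(D):
        source = "common_garden" if d < config.n_common_garden else "natural"
        pops.append(
            {
                "population": f"N{d + 1:02d}",
                "range_label": "native",
                "freqs": deme_freqs[d],
                "longitude": -85.0 + d,
                "latitude": 38.0,
                "source_type": source,
                "clonal_rate": config.clonal_rate_native,
            }
        )
    for j in range(config.n_invasive_pops):
        pops.append(
            {
                "population": f"I{j + 1:02d}",
                "range_label": "invasive",
                "freqs": inv_freqs[j],
                "longitude": 5.0 + j,
                "latitude": 48.0,
                "source_type": "natural",
                "clonal_rate": config.clonal_rate,
            }
        )

    lo, hi = config.pop_size
    all_ids: list[str] = []
    blocks: list[np.ndarray] = []
    meta_rows = []
    clone_truth: dict[str, list[list[str]]] = {}
    for pop in pops:
        n = int(rng.integers(lo, hi + 1))
        ids = [f"{pop['population']}_{i + 1:02d}" for i in range(n)]
        geno = rng.binomial(2, pop["freqs"], size=(n, L)).astype(np.int8)
        rate = pop["clonal_rate"] if pop["source_type"] == "natural" else 0.0
        geno, partition = _plant_clones(rng, geno, ids, rate)
        clone_truth[pop["population"]] = partition
        blocks.append(geno)
        all_ids.extend(ids)
        for ind in ids:
            meta_rows.append(
                {
                    "individual_id": ind,
                    "population": pop["population"],
                    "range_label": pop["range_label"],
                    "longitude": pop["longitude"],
                    "latitude": pop["latitude"],
                    "source_type": pop["source_type"],
                }
            )

    calls = np.vstack(blocks)
    if config.missing_rate > 0:
        mask = rng.uniform(size=calls.shape) < config.missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)

    # ascertainment: discovery sample of native individuals, re-genotyped
    disc_demes = np.arange(config.discovery_panel_size) % D
    disc_geno = rng.binomial(2, deme_freqs[disc_demes])
    disc_p = disc_geno.sum(axis=0) / (2 * config.discovery_panel_size)
    disc_maf = np.minimum(disc_p, 1 - disc_p)
    mask = disc_maf >= config.maf_threshold
    if mask.sum() < 10:
        raise ValueError(
            f"only {mask.sum()} loci pass the discovery MAF threshold "
            f"{config.maf_threshold}; lower the threshold or add loci"
        )
    passing = np.flatnonzero(mask)
    if passing.size > config.n_loci_ascertained:
        keep = np.sort(
            rng.choice(passing, size=config.n_loci_ascertained, replace=False)
        )
        mask = np.zeros(L, dtype=bool)
        mask[keep] = True

    gm = GenotypeMatrix(all_ids, locus_ids, calls)
    meta = pd.DataFrame(meta_rows)
    truth = SimTruth(
        deme_freqs=deme_freqs,
        invasive_freqs=inv_freqs,
        founder_pool_freqs=founder_pool,
        founder_demes=tuple(config.founder_demes),
        clone_groups=clone_truth,
        ascertainment_mask=mask,
        ascertained_locus_ids=[locus_ids[j] for j in np.flatnonzero(mask)],
    )
    return gm, meta, truth


def ascertained_panel(gm: GenotypeMatrix, truth: SimTruth) -> GenotypeMatrix:
    """Restrict a simulated matrix to the high-MAF ascertained panel."""
    return gm.subset(loci=truth.ascertained_locus_ids)
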