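"""End-to-end pipeline orchestration.

Stages run in the analysis order clone removal -> PCA -> admixture
(combined ranges, then each range separately) -> diversity/differentiation
-> isolation by distance, writing plain-text tables plus a JSON manifest
(parameters, seeds, versions) from which every output is reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import (
    admixture_replicates,
    align_runs,
    assign_individuals,
    assign_populations,
    average_runs,
    evanno_deltaK,
)
from .clonality import detect_clones, range_clonality_test, reports_to_frame
from .diversity import (
    allelic_richness,
    compare_allelic_richness,
    compare_tna,
    maf_profile,
    pop_diversity,
    total_alleles,
    wc_fst,
)
from .io import GenotypeMatrix, metadata_for, read_genotype_csv, read_metadata_csv
from .pca import genotype_pca, group_ellipses
from .simulate import SimConfig, simulate_dataset
from .spatial import ibd_analysis

DEFAULT_STAGES = ("clones", "pca", "admixture", "diversity", "ibd")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and per-stage parameters."""

    genotype_csv: str | None = None
    metadata_csv: str | None = None
    simulate: dict | None = None  # SimConfig fields; used when no input paths
    out_dir: str = "pipeline_out"
    stages: tuple[str, ...] = DEFAULT_STAGES
    seed: int = 0
    n_boot: int = 1000
    k_min: int = 1
    k_max: int = 4
    replicates: int = 3
    burn_in: int = 1000
    iters: int = 2000
    thin: int = 5
    ci_level: float = 0.90
    n_perm: int = 9999

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _seed_stream(seed: int):
    return np.random.default_rng(seed)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Any stage failure raises :class:`StageError` tagged with the stage
    name; outputs written before the failure remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _seed_stream(config.seed)
    stage_seeds = {s: int(rng.integers(0, 2**31 - 1)) for s in DEFAULT_STAGES}
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stage_seeds": stage_seeds,
        "outputs": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(name: str, df: pd.DataFrame):
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"].append(name)

    # ---- inputs -----------------------------------------------------------
    if config.genotype_csv and config.metadata_csv:
        gm = read_genotype_csv(config.genotype_csv)
        meta = read_metadata_csv(config.metadata_csv)
    else:
        sim_kwargs = dict(config.simulate or {})
        sim_kwargs.setdefault("seed", stage_seeds["clones"])
        gm, meta, _truth = simulate_dataset(SimConfig(**sim_kwargs))
        manifest["simulated"] = True

    clone_free = gm
    active = set(config.stages)

    # ---- clone removal ----------------------------------------------------
    if "clones" in active:
        try:
            reports, clone_free = detect_clones(gm, meta)
            tab = reports_to_frame(reports)
            record("clones.tsv", tab)
            try:
                test = range_clonality_test(reports, meta)
                manifest["range_clonality"] = {
                    "chi2": test.chi2,
                    "df": test.df,
                    "p_value": test.p_value,
                    "table": test.contingency.tolist(),
                    "ranges": test.range_labels,
                }
            except ValueError:
                manifest["range_clonality"] = None
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"[clones] {exc}") from exc

    meta_cf = metadata_for(clone_free, meta)

    # ---- PCA --------------------------------------------------------------
    if "pca" in active:
        try:
            res = genotype_pca(clone_free, n_components=5)
            scores = res.scores.rename_axis("individual_id").reset_index()
            record("pca_scores.tsv", scores)
            record("pca_ellipses.tsv", group_ellipses(res, meta))
            manifest["pca_explained_variance"] = res.explained_variance.tolist()
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"[pca] {exc}") from exc

    # ---- admixture --------------------------------------------------------
    if "admixture" in active:
        try:
            scopes = {"combined": clone_free}
            for rng_label in meta_cf["range_label"].unique():
                ids = meta_cf.loc[
                    meta_cf["range_label"] == rng_label, "individual_id"
                ].tolist()
                scopes[str(rng_label)] = clone_free.subset(individuals=ids)
            admix_rng = _seed_stream(stage_seeds["admixture"])
            manifest["admixture"] = {}
            for scope, sub in scopes.items():
                runs = []
                for K in range(config.k_min, config.k_max + 1):
                    runs.extend(
                        admixture_replicates(
                            sub,
                            K,
                            replicates=config.replicates,
                            seed=int(admix_rng.integers(0, 2**31 - 1)),
                            burn_in=config.burn_in,
                            iters=config.iters,
                            thin=config.thin,
                            ci=config.ci_level,
                        )
                    )
                sel = evanno_deltaK(runs)
                record(f"admixture_{scope}_deltaK.tsv", sel.table)
                chosen = [r for r in runs if r.K == sel.chosen_K]
                avg = average_runs(align_runs(chosen))
                q = pd.DataFrame(
                    avg.Q_mean,
                    index=avg.individual_ids,
                    columns=[f"cluster_{k + 1}" for k in range(avg.K)],
                )
                record(
                    f"admixture_{scope}_Q.tsv",
                    q.rename_axis("individual_id").reset_index(),
                )
                ind_calls = assign_individuals(avg)
                record(f"admixture_{scope}_individuals.tsv", ind_calls)
                record(
                    f"admixture_{scope}_populations.tsv",
                    assign_populations(ind_calls, meta),
                )
                manifest["admixture"][scope] = {
                    "chosen_K": sel.chosen_K,
                    "alpha_converged": avg.alpha_converged,
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"[admixture] {exc}") from exc

    # ---- diversity --------------------------------------------------------
    fst_results = {}
    if "diversity" in active:
        try:
            div_rng = _seed_stream(stage_seeds["diversity"])
            divs = pop_diversity(
                clone_free,
                meta,
                n_boot=config.n_boot,
                seed=int(div_rng.integers(0, 2**31 - 1)),
            )
            div_tab = pd.DataFrame(
                {
                    "population": [d.population for d in divs],
                    "N": [d.n_individuals for d in divs],
                    "Ho": [d.Ho for d in divs],
                    "Hs": [d.Hs for d in divs],
                    "FIS_mean": [d.FIS_mean for d in divs],
                    "FIS_LCI95": [d.FIS_CI95[0] for d in divs],
                    "FIS_HCI95": [d.FIS_CI95[1] for d in divs],
                    "FIS_significant": [d.significant for d in divs],
                }
            )
            record("diversity_populations.tsv", div_tab)

            manifest["fst"] = {}
            for scope, ids in _scope_ids(meta_cf):
                sub = clone_free.subset(individuals=ids) if ids else clone_free
                if metadata_for(sub, meta)["population"].nunique() < 2:
                    continue
                res = wc_fst(
                    sub,
                    meta,
                    n_boot=config.n_boot,
                    seed=int(div_rng.integers(0, 2**31 - 1)),
                    pairwise=(scope != "combined"),
                )
                fst_results[scope] = res
                manifest["fst"][scope] = {
                    "FST": res.FST,
                    "CI95": list(res.CI95),
                    "n_boot": res.n_boot,
                }

            ranges = meta_cf["range_label"].unique().tolist()
            manifest["range_diversity"] = {}
            ar = allelic_richness(clone_free, meta)
            for rng_label in ranges:
                tna = total_alleles(
                    clone_free,
                    meta,
                    rng_label,
                    n_boot=config.n_boot,
                    seed=int(div_rng.integers(0, 2**31 - 1)),
                )
                prof = maf_profile(clone_free, meta, rng_label)
                manifest["range_diversity"][rng_label] = {
                    "AR_mean": ar[rng_label].AR_mean,
                    "rarefaction_g": ar[rng_label].rarefaction_g,
                    "TNA": tna.TNA,
                    "MAF_modal_bin": list(prof["modal_bin"]),
                }
            if len(ranges) == 2:
                w, p = compare_allelic_richness(ar[ranges[0]], ar[ranges[1]])
                manifest["range_diversity"]["AR_wilcoxon"] = {"W": w, "p": p}
                t0 = total_alleles(
                    clone_free, meta, ranges[0], n_boot=config.n_boot,
                    seed=int(div_rng.integers(0, 2**31 - 1)),
                )
                t1 = total_alleles(
                    clone_free, meta, ranges[1], n_boot=config.n_boot,
                    seed=int(div_rng.integers(0, 2**31 - 1)),
                )
                u, pu = compare_tna(t0, t1)
                manifest["range_diversity"]["TNA_mannwhitney"] = {"U": u, "p": pu}
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"[diversity] {exc}") from exc

    # ---- isolation by distance -------------------------------------------
    if "ibd" in active:
        try:
            if not fst_results:
                raise ValueError(
                    "IBD requires pairwise F_ST from the diversity stage"
                )
            ibd_rng = _seed_stream(stage_seeds["ibd"])
            rows = []
            for scope, res in fst_results.items():
                if res.pairwise_FST is None or len(res.pairwise_FST) < 4:
                    continue
                ibd = ibd_analysis(
                    res.pairwise_FST,
                    clone_free,
                    meta,
                    n_perm=config.n_perm,
                    seed=int(ibd_rng.integers(0, 2**31 - 1)),
                )
                rows.append(
                    {
                        "scope": scope,
                        "pearson_r": ibd.pearson_r,
                        "pearson_p": ibd.pearson_p,
                        "slope": ibd.slope,
                        "mantel_r": ibd.mantel_r,
                        "mantel_p": ibd.mantel_p,
                        "n_populations": ibd.n_populations,
                        "n_perm": ibd.n_perm,
                    }
                )
            record("ibd.tsv", pd.DataFrame(rows))
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"[ibd] {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["outputs"].append("manifest.json")
    return manifest


def _scope_ids(meta_cf: pd.DataFrame):
    yield "combined", None
    for rng_label in meta_cf["range_label"].unique():
        yield str(rng_label), meta_cf.loc[
            meta_cf["range_label"] == rng_label, "individual_id"
        ].tolist()
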