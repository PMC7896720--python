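"""Run orchestration: configs, dataset presets, manifests, report bundles.

A run is fully determined by its :class:`RunConfig` (and the input
files it names): every stage consumes only declared inputs and all
randomness flows from the global seed, so reruns are bit-identical.

The *four-dataset* preset mirrors the filtering comparison at the heart
of the re-analysis: (1) unfiltered; (2) individuals with more than half
their loci missing removed; (3) dataset 2 plus loci with pooled-pair
F_IS < -0.2 removed; (4) dataset 2 plus loci with pooled-pair F_IS < 0
removed. Pairwise F_ST matrices across the four datasets show artifact
pairs collapsing toward zero while clean pairs stay put.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotype_io, popgen_stats, qc_filters, structure_analysis
from . import growth_model as gm
from . import synthetic_data as sd
from .containers import DepthTable, GenotypeMatrix, GrowthDataset

__all__ = ["RunConfig", "run", "four_datasets", "load_config"]


@dataclass
class RunConfig:
    """Inputs, stage toggles and parameters of one pipeline run."""

    out_dir: str = "radqc_run"
    seed: int = 0
    # inputs: file paths, or simulation configs used when paths are None
    genepop_path: str | None = None
    depth_path: str | None = None
    growth_path: str | None = None
    allele_digits: int = 2
    geno_sim: sd.GenoSimConfig | None = None
    growth_sim: sd.GrowthSimConfig | None = None
    # analysis toggles and parameters
    filter_steps: list[dict] = field(default_factory=list)
    fis_pair: tuple[str, str] | None = None  # pair for the four-dataset presets
    run_four_datasets: bool = False
    run_pca: bool = True
    run_fst_matrix: bool = True
    run_exact_tests: bool = True
    fst_distribution_pairs: list[tuple[str, str]] = field(default_factory=list)
    fst_subsample_n: int | None = None
    run_growth: bool = False
    mcmc: gm.McmcConfig = field(default_factory=gm.McmcConfig)
    make_plots: bool = False


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "geno_sim" in raw and raw["geno_sim"] is not None:
        gs = dict(raw["geno_sim"])
        for key in ("ancestral_freq_range", "undersplit_latent_freq_range"):
            if key in gs:
                gs[key] = tuple(gs[key])
        if "pop_dropout" in gs:
            gs["pop_dropout"] = {
                int(k): (v[0], tuple(v[1])) for k, v in gs["pop_dropout"].items()
            }
        raw["geno_sim"] = sd.GenoSimConfig(**gs)
    if "growth_sim" in raw and raw["growth_sim"] is not None:
        ws = dict(raw["growth_sim"])
        if "age_range" in ws:
            ws["age_range"] = tuple(ws["age_range"])
        raw["growth_sim"] = sd.GrowthSimConfig(**ws)
    if "mcmc" in raw and raw["mcmc"] is not None:
        raw["mcmc"] = gm.McmcConfig(**raw["mcmc"])
    if "fis_pair" in raw and raw["fis_pair"] is not None:
        raw["fis_pair"] = tuple(raw["fis_pair"])
    if "fst_distribution_pairs" in raw:
        raw["fst_distribution_pairs"] = [
            tuple(p) for p in raw["fst_distribution_pairs"]
        ]
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def four_datasets(
    matrix: GenotypeMatrix, fis_pair: tuple[str, str]
) -> dict[str, tuple[GenotypeMatrix, qc_filters.FilterReport]]:
    """The four nested filter datasets; keys d1..d4."""
    pa, pb = fis_pair
    specs = {
        "d1_unfiltered": [],
        "d2_individual_missingness": [
            {"step": "individual_max_missing", "threshold": 0.5}
        ],
        "d3_fis_minus0.2": [
            {"step": "individual_max_missing", "threshold": 0.5},
            {"step": "fis_min", "pop_a": pa, "pop_b": pb, "threshold": -0.2},
        ],
        "d4_fis_0": [
            {"step": "individual_max_missing", "threshold": 0.5},
            {"step": "fis_min", "pop_a": pa, "pop_b": pb, "threshold": 0.0},
        ],
    }
    return {
        name: qc_filters.apply_filters(matrix, qc_filters.FilterSpec.from_dicts(steps))
        for name, steps in specs.items()
    }


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    def enc(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, tuple):
            return list(v)
        if isinstance(v, dict):
            return {str(k): enc(x) for k, x in v.items()}
        if isinstance(v, list):
            return [enc(x) for x in v]
        return v

    return {f.name: enc(getattr(config, f.name)) for f in dataclasses.fields(config)}


def run(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns a dict of the main in-memory results (matrices, tables,
    fits) keyed by stage name; all tables are also written under
    ``config.out_dir``. Any stage error aborts with the stage name;
    outputs of earlier stages are left on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {"config": _config_echo(config), "inputs": {}, "outputs": []}

    def save_table(df: pd.DataFrame, name: str, index=True):
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        manifest["outputs"].append(name)

    stage = "inputs"
    try:
        matrix, depths = _load_genotypes(config, out, manifest)
        growth = _load_growth(config, out, manifest)
        if matrix is not None:
            results["matrix"] = matrix

        if matrix is not None and config.filter_steps:
            stage = "filter"
            spec = qc_filters.FilterSpec.from_dicts(config.filter_steps)
            matrix, report = qc_filters.apply_filters(matrix, spec, depths)
            results["filtered_matrix"] = matrix
            results["filter_report"] = report
            save_table(report.summary(), "filter_summary.tsv", index=False)
            (out / "filter_report.json").write_text(
                json.dumps(report.to_json_dict(), indent=2)
            )
            manifest["outputs"].append("filter_report.json")
            genotype_io.write_genepop(
                matrix, out / "filtered.genepop", config.allele_digits
            )
            manifest["outputs"].append("filtered.genepop")

        if matrix is not None:
            stage = "missingness"
            prof = popgen_stats.missingness(matrix)
            save_table(prof.per_individual.to_frame("missing_fraction"),
                       "missingness_individuals.tsv")
            save_table(prof.per_locus_by_pop, "missingness_locus_by_pop.tsv")
            results["missingness"] = prof

        if matrix is not None and config.run_pca:
            stage = "pca"
            res = structure_analysis.pca(matrix)
            scores = res.scores.assign(pop=matrix.pop_labels)
            save_table(scores, "pca_scores.tsv")
            results["pca"] = res

        if matrix is not None and config.run_four_datasets:
            stage = "four_datasets"
            if config.fis_pair is None:
                raise ValueError("four-dataset preset needs fis_pair")
            datasets = four_datasets(matrix, config.fis_pair)
            results["four_datasets"] = datasets
            rows = []
            for name, (m, _rep) in datasets.items():
                fst = popgen_stats.pairwise_fst_matrix(
                    m, with_tests=config.run_exact_tests
                )
                fst.insert(0, "dataset", name)
                rows.append(fst)
            theta_table = pd.concat(rows, ignore_index=True)
            save_table(theta_table, "four_dataset_fst.tsv", index=False)
            results["four_dataset_fst"] = theta_table

        elif matrix is not None and config.run_fst_matrix:
            stage = "fst_matrix"
            fst = popgen_stats.pairwise_fst_matrix(
                matrix, with_tests=config.run_exact_tests
            )
            save_table(fst, "pairwise_fst.tsv", index=False)
            results["pairwise_fst"] = fst

        if matrix is not None and config.fst_distribution_pairs:
            stage = "fst_distributions"
            rows = []
            for pa, pb in config.fst_distribution_pairs:
                dist = structure_analysis.fst_distribution(
                    matrix, pa, pb,
                    subsample_n=config.fst_subsample_n, seed=config.seed,
                )
                rows.append(dist.to_row())
            dist_table = pd.DataFrame(rows)
            save_table(dist_table, "fst_distributions.tsv", index=False)
            results["fst_distributions"] = dist_table

        if config.run_growth and growth is not None:
            stage = "growth"
            mcmc = dataclasses.replace(config.mcmc, seed=config.seed)
            fit_obj = gm.fit(growth, mcmc)
            results["growth_fit"] = fit_obj
            save_table(gm.posterior_summary(fit_obj), "growth_posterior.tsv")
            draws = pd.DataFrame(
                {k: v.reshape(-1) for k, v in fit_obj.draws.items()}
            )
            save_table(draws, "growth_draws.tsv", index=False)
            summary_rows = {}
            for loc in ("north", "south"):
                summary_rows[f"decline_{loc}"] = gm.summarize_draws(
                    gm.decline(fit_obj, loc)
                )
            contrast = gm.contrast_south_minus_north(fit_obj)
            summary_rows["contrast_south_minus_north"] = {
                k: v for k, v in contrast.items() if k != "draws"
            }
            save_table(
                pd.DataFrame.from_dict(summary_rows, orient="index"),
                "growth_derived.tsv",
            )
            results["growth_derived"] = summary_rows

        if config.make_plots and matrix is not None:
            stage = "plots"
            from . import plots

            plots.missingness_plot(
                popgen_stats.missingness(matrix), matrix, out / "missingness.png"
            )
            if "pca" in results:
                plots.pca_plot(results["pca"], matrix, out / "pca.png")
            manifest["outputs"].extend(["missingness.png", "pca.png"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"].sort()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _load_genotypes(config: RunConfig, out: Path, manifest: dict):
    if config.genepop_path is not None:
        matrix = genotype_io.read_genepop(config.genepop_path, config.allele_digits)
        manifest["inputs"]["genepop"] = _sha256(Path(config.genepop_path))
        depths = None
        if config.depth_path is not None:
            depths = genotype_io.read_depth_table(config.depth_path)
            manifest["inputs"]["depths"] = _sha256(Path(config.depth_path))
        return matrix, depths
    if config.geno_sim is not None:
        sim_cfg = dataclasses.replace(config.geno_sim, seed=config.seed)
        matrix, depths, truth = sd.simulate_genotypes(sim_cfg)
        genotype_io.write_genepop(matrix, out / "simulated.genepop",
                                  config.allele_digits)
        genotype_io.write_depth_table(depths, out / "simulated_depths.tsv")
        (out / "ground_truth.json").write_text(json.dumps(truth))
        manifest["outputs"].extend(
            ["simulated.genepop", "simulated_depths.tsv", "ground_truth.json"]
        )
        manifest["inputs"]["geno_sim_seed"] = sim_cfg.seed
        return matrix, depths
    return None, None


def _load_growth(config: RunConfig, out: Path, manifest: dict):
    if config.growth_path is not None:
        manifest["inputs"]["growth"] = _sha256(Path(config.growth_path))
        return genotype_io.read_growth_table(config.growth_path)
    if config.growth_sim is not None:
        sim_cfg = dataclasses.replace(config.growth_sim, seed=config.seed)
        data, truth = sd.simulate_growth(sim_cfg)
        genotype_io.write_growth_table(data, out / "simulated_growth.csv")
        (out / "growth_truth.json").write_text(json.dumps(truth))
        manifest["outputs"].extend(["simulated_growth.csv", "growth_truth.json"])
        manifest["inputs"]["growth_sim_seed"] = sim_cfg.seed
        return data
    return None
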