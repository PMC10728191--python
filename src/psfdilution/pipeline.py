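"""End-to-end orchestration: simulate -> dissimilarity -> PSF -> predictor ->
biodiversity effects -> community screen, with TSV outputs and a JSON report.

Each stage is a pure function of its input files plus the configuration; a
single seed fans out to per-stage streams, so any stage can be re-run in
isolation and the whole run is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import field as field_mod
from . import feedback, greenhouse, microbiome, predictor as pred_mod, synthetic

log = logging.getLogger("psfdilution")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "psf_run"
    stages: tuple[str, ...] = (
        "simulate",
        "dissimilarity",
        "estimate",
        "predict",
        "effects",
        "feedback_model",
    )
    sim: synthetic.SimulationConfig | None = None
    biomass: str = "total"
    predictors: tuple[str, ...] = synthetic.PATHOGEN_GROUPS
    max_richness: int | None = None
    ordered_pairs: bool = False
    write_full_screen: bool = True

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = synthetic.SimulationConfig(seed=self.seed)
        unknown = set(self.stages) - {
            "simulate", "dissimilarity", "estimate", "predict", "effects",
            "feedback_model",
        }
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.biomass not in ("total", "shoot"):
            raise ValueError("biomass must be 'total' or 'shoot'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", None)
        raw.update(overrides)
        cfg = cls(**raw)
        if sim_raw:
            sim_raw.setdefault("seed", cfg.seed)
            if "read_depth_range" in sim_raw:
                sim_raw["read_depth_range"] = tuple(sim_raw["read_depth_range"])
            cfg.sim = synthetic.SimulationConfig(**sim_raw)
        return cfg


def write_dissimilarity(dm: microbiome.DissimilarityMatrix, path: Path) -> None:
    dm.d.to_csv(path, sep="\t")


def read_dissimilarity(path: Path, group: str) -> microbiome.DissimilarityMatrix:
    d = pd.read_csv(path, sep="\t", index_col=0)
    d.columns = d.columns.astype(str)
    d.index = d.index.astype(str)
    return microbiome.DissimilarityMatrix(group=group, d=d)


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs {path.name}; run the producing stage first"
        )
    return path


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sim = cfg.sim
    pool = synthetic.make_species_pool(sim.n_families, sim.n_per_family)
    pairs = synthetic.make_pairing_design(pool)
    dissims = synthetic.simulate_all_dissimilarities(pool, sim)
    truth = synthetic.simulate_true_psf(dissims, sim)
    pots = synthetic.simulate_greenhouse(pool, pairs, truth, sim)
    design = synthetic.make_field_design(pool, sim)
    biomass = synthetic.simulate_field_biomass(design, truth, sim)

    pd.DataFrame(
        {"species": pool.species, "family": [pool.family[s] for s in pool.species]}
    ).to_csv(out / "species_pool.tsv", sep="\t", index=False)
    pd.DataFrame(pairs, columns=["species_a", "species_b"]).to_csv(
        out / "pairing_design.tsv", sep="\t", index=False
    )
    for g, dm in dissims.items():
        write_dissimilarity(dm, out / f"dissimilarity_{g}.tsv")
    truth.to_csv(out / "true_psf.tsv", sep="\t", index=False)
    pots.to_csv(out / "pots.tsv", sep="\t", index=False)
    design.to_csv(out / "plots.tsv", sep="\t", index=False)
    biomass.to_csv(out / "plot_biomass.tsv", sep="\t", index=False)
    mixtures = design[design["richness"] >= 2]
    for g in synthetic.PATHOGEN_GROUPS:
        table = synthetic.simulate_asv_tables(pool, sim, g, plots=mixtures)
        table.counts.to_csv(out / f"asv_counts_{g}.tsv", sep="\t")
        table.samples.to_csv(out / f"asv_samples_{g}.tsv", sep="\t")
        table.features.to_csv(out / f"asv_features_{g}.tsv", sep="\t")


def stage_dissimilarity(cfg: PipelineConfig, out: Path) -> dict:
    """Sequencing route: rarefy, filter to pathogens, Bray-Curtis, dilution
    signature.  Matrices are written per group as asv_dissimilarity_*.tsv."""
    report = {}
    for g in synthetic.PATHOGEN_GROUPS:
        counts = pd.read_csv(_need(out / f"asv_counts_{g}.tsv", "dissimilarity"),
                             sep="\t", index_col=0)
        samples = pd.read_csv(out / f"asv_samples_{g}.tsv", sep="\t", index_col=0)
        features = pd.read_csv(out / f"asv_features_{g}.tsv", sep="\t", index_col=0)
        features = features.fillna("")
        table = microbiome.FeatureCountTable(
            counts=counts, samples=samples, features=features
        )
        table = microbiome.rarefy(table, "min", seed=cfg.seed)
        table = microbiome.guild_filter(table, "plant_pathogen")
        mono_mask = table.samples["type"] == "monoculture"
        mono_table = microbiome.FeatureCountTable(
            counts=table.counts[table.samples.index[mono_mask]],
            samples=table.samples[mono_mask],
            features=table.features,
        )
        dm = microbiome.species_pair_dissimilarity(mono_table, group=g)
        write_dissimilarity(dm, out / f"asv_dissimilarity_{g}.tsv")
        mono_map = {
            sp: f"{sp}_m1" for sp in mono_table.samples["species"].unique()
        }
        mix = table.samples[table.samples["type"] == "mixture"].reset_index()
        sig = microbiome.dilution_signature(table, mono_map, mix)
        sig.to_csv(out / f"dilution_signature_{g}.tsv", sep="\t", index=False)
        report[g] = {
            "n_pathogen_features": int(len(table.counts)),
            "mean_asv_dissimilarity": float(
                dm.d.to_numpy()[np.triu_indices(len(dm.species), 1)].mean()
            ),
            "mean_signature_change_by_richness": {
                str(k): float(v)
                for k, v in sig.groupby("richness")["change"].mean().items()
            }
            if len(sig)
            else {},
        }
    return report


def stage_estimate(cfg: PipelineConfig, out: Path) -> dict:
    pots = pd.read_csv(_need(out / "pots.tsv", "estimate"), sep="\t")
    pool_df = pd.read_csv(_need(out / "species_pool.tsv", "estimate"), sep="\t")
    family = dict(zip(pool_df["species"], pool_df["family"]))
    pairs = [
        tuple(r)
        for r in pd.read_csv(out / "pairing_design.tsv", sep="\t").to_numpy()
    ]
    cells = greenhouse.fit_cell_means(pots, biomass=cfg.biomass)
    psfs = greenhouse.estimate_pairwise_psf(cells, pairs, family=family)
    summary = greenhouse.group_summary(psfs)
    psfs.to_csv(out / "pairwise_psf.tsv", sep="\t", index=False)
    summary.to_csv(out / "psf_meta.tsv", sep="\t")
    return {
        "n_pairs": int(len(psfs)),
        "overall": summary.loc["overall"].to_dict(),
    }


def stage_predict(cfg: PipelineConfig, out: Path) -> dict:
    psfs = pd.read_csv(_need(out / "pairwise_psf.tsv", "predict"), sep="\t")
    dissims = {
        g: read_dissimilarity(
            _need(out / f"dissimilarity_{g}.tsv", "predict"), g
        )
        for g in synthetic.ALL_GROUPS
    }
    data = pred_mod.assemble_predictor_set(psfs, dissims)
    selection = pred_mod.exhaustive_selection(
        data, predictors=list(synthetic.ALL_GROUPS)
    )
    try:
        fitted = pred_mod.build_predictor(selection, list(cfg.predictors))
    except ValueError:
        # best model omitted a configured predictor: fall back to the
        # exact-subset model from the same exhaustive enumeration
        wanted = set(cfg.predictors)
        row = selection.models[
            selection.models["subset"].map(lambda s: set(s) == wanted)
        ].iloc[0]
        fitted = pred_mod.PsfPredictor(
            coefficients={p: row["coefficients"][p] for p in cfg.predictors},
            intercept=selection.averaged_intercept,
        )
        log.warning("best model lacked a configured predictor; used exact subset fit")
    psf_matrix = pred_mod.predict_pairwise_psf(
        fitted, {g: dissims[g] for g in fitted.coefficients}
    )
    biomass = pd.read_csv(_need(out / "plot_biomass.tsv", "predict"), sep="\t")
    design = pd.read_csv(_need(out / "plots.tsv", "predict"), sep="\t")
    scores = []
    for plot_id, grp in biomass.groupby("plot_id"):
        dens = grp.set_index("species")["biomass_g"]
        dens = dens / dens.sum()
        psf = pred_mod.plot_predicted_psf(dens, psf_matrix, ordered_pairs=cfg.ordered_pairs)
        n = len(dens)
        scores.append(
            {
                "plot_id": plot_id,
                "richness": n,
                "predicted_psf": psf,
                "dilution": pred_mod.pathogen_dilution(psf, n),
            }
        )
    scores = pd.DataFrame(scores)
    sel_out = selection.models.drop(columns=["coefficients"]).assign(
        subset=selection.models["subset"].map(lambda s: "+".join(s) or "(intercept)")
    )
    sel_out.to_csv(out / "model_selection.tsv", sep="\t", index=False)
    (out / "predictor.json").write_text(
        json.dumps(
            {"coefficients": dict(fitted.coefficients), "intercept": fitted.intercept},
            indent=2,
            sort_keys=True,
        )
    )
    scores.to_csv(out / "plot_scores.tsv", sep="\t", index=False)
    return {
        "importance": {k: float(v) for k, v in selection.importance.items()},
        "important_predictors": selection.important_predictors,
        "coefficients": dict(fitted.coefficients),
        "intercept": float(fitted.intercept),
        "n_models": int(len(selection.models)),
    }


def stage_effects(cfg: PipelineConfig, out: Path) -> dict:
    biomass = pd.read_csv(_need(out / "plot_biomass.tsv", "effects"), sep="\t")
    design = pd.read_csv(_need(out / "plots.tsv", "effects"), sep="\t")
    scores = pd.read_csv(_need(out / "plot_scores.tsv", "effects"), sep="\t")
    coefs, converted, r = field_mod.cover_to_biomass(biomass)
    ref = field_mod.MonocultureReference.from_biomass(biomass, design)
    effects = field_mod.effects_table(biomass, design, ref)
    regressions = field_mod.effects_regression(effects, scores)
    tests = field_mod.overyielding_tests(effects)
    effects.to_csv(out / "effects.tsv", sep="\t", index=False)
    regressions.to_csv(out / "regressions.tsv", sep="\t", index=False)
    tests.to_csv(out / "overyielding_tests.tsv", sep="\t", index=False)
    coefs.to_csv(out / "cover_regressions.tsv", sep="\t")
    return {
        "n_mixtures": int(len(effects)),
        "cover_biomass_pearson_r": float(r),
        "regressions": regressions.to_dict(orient="records"),
        "overyielding": tests.to_dict(orient="records"),
    }


def stage_feedback_model(cfg: PipelineConfig, out: Path) -> dict:
    pred_path = _need(out / "predictor.json", "feedback_model")
    spec = json.loads(pred_path.read_text())
    fitted = pred_mod.PsfPredictor(
        coefficients=spec["coefficients"], intercept=spec["intercept"]
    )
    dissims = {
        g: read_dissimilarity(_need(out / f"dissimilarity_{g}.tsv", "feedback_model"), g)
        for g in fitted.coefficients
    }
    screen = feedback.screen_pool(fitted, dissims, max_richness=cfg.max_richness)
    summary = feedback.screen_summary(screen)
    if cfg.write_full_screen:
        screen.to_csv(out / "community_screen.tsv", sep="\t", index=False)
    summary.to_csv(out / "screen_summary.tsv", sep="\t", index=False)
    passing = screen[screen["passes"]]
    return {
        "n_communities": int(len(screen)),
        "n_passing": int(len(passing)),
        "richness_range_passing": [
            int(passing["richness"].min()),
            int(passing["richness"].max()),
        ]
        if len(passing)
        else None,
        "summary": summary.to_dict(orient="records"),
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "dissimilarity": stage_dissimilarity,
    "estimate": stage_estimate,
    "predict": stage_predict,
    "effects": stage_effects,
    "feedback_model": stage_feedback_model,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Writes all stage outputs plus ``report.json`` into ``cfg.out_dir`` and
    returns the report dict.  A stage failure aborts with the stage name;
    outputs of completed stages are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "design_counts": {},
    }
    for name in (
        "simulate", "dissimilarity", "estimate", "predict", "effects",
        "feedback_model",
    ):
        if name not in cfg.stages:
            continue
        log.info("running stage %s", name)
        try:
            result = _STAGE_FUNCS[name](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        if result:
            report[name] = result
    if (out / "plots.tsv").exists():
        design = pd.read_csv(out / "plots.tsv", sep="\t")
        pots = pd.read_csv(out / "pots.tsv", sep="\t")
        pairs = pd.read_csv(out / "pairing_design.tsv", sep="\t")
        report["design_counts"] = {
            "plots": int(len(design)),
            "mixture_plots": int((design["richness"] >= 2).sum()),
            "monoculture_plots": int((design["richness"] == 1).sum()),
            "pots": int(len(pots)),
            "pairwise_tests": int(len(pairs)),
        }
    if "feedback_model" in report:
        report["design_counts"]["communities"] = report["feedback_model"][
            "n_communities"
        ]
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Schema checks over pipeline TSV inputs; returns violation messages."""
    violations: list[str] = []
    required_cols = {
        "pots": {"plant", "inoculum", "replicate", "height_cm", "shoot_mass_g",
                 "root_mass_g"},
        "plots": {"plot_id", "richness", "dispersion", "composition"},
        "plot_biomass": {"plot_id", "species", "biomass_g", "cover_pct"},
    }
    for name, cols in required_cols.items():
        if name not in paths:
            continue
        p = Path(paths[name])
        if not p.exists():
            violations.append(f"{name}: file {p} missing")
            continue
        df = pd.read_csv(p, sep="\t")
        missing = cols - set(df.columns)
        if missing:
            violations.append(f"{name}: missing columns {sorted(missing)}")
    for name, p in paths.items():
        if not str(name).startswith("dissimilarity"):
            continue
        p = Path(p)
        if not p.exists():
            violations.append(f"{name}: file {p} missing")
            continue
        d = pd.read_csv(p, sep="\t", index_col=0)
        m = d.to_numpy(dtype=float)
        if m.shape[0] != m.shape[1]:
            violations.append(f"{name}: matrix not square")
            continue
        if not np.allclose(m, m.T, atol=1e-9):
            violations.append(f"{name}: matrix not symmetric")
        if not np.allclose(np.diag(m), 0, atol=1e-9):
            violations.append(f"{name}: nonzero diagonal")
        if (m < -1e-9).any() or (m > 1 + 1e-9).any():
            violations.append(f"{name}: entries outside [0, 1]")
    if "densities" in paths and Path(paths["densities"]).exists():
        dens = pd.read_csv(paths["densities"], sep="\t")
        sums = dens.groupby("plot_id")["p"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-6]
        for plot_id, s in bad.items():
            violations.append(f"densities: plot {plot_id} sums to {s:.4f}, not 1")
    return violations
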