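"""End-to-end orchestration: simulate -> train -> BAG -> classify -> compare
-> mediate, with provenance and resumable intermediate artifacts.

All randomness flows from one master seed, expanded deterministically per
stage, so a rerun with the same config reproduces every artifact bit for
bit.  When the output directory already holds a BAG table written under an
identical config hash, the expensive model-fitting stage is skipped and
downstream stages run from the cached table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasSpec, make_atlas
from .brain_age import (BagResult, BrainAgeModel, ModelSpec, fit_regional_models,
                        nested_cv_fit, predict_and_bag)
from .csvd import classify_csvd
from .group_stats import cohort_summary, regional_bag_comparison
from .io import config_hash, write_table
from .mediation import mediation_screen
from .simulate import (SimulationConfig, generate_application_cohort,
                       generate_training_cohort)

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline"]

log = logging.getLogger("csvd_brainage")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``regional_spec`` may use reduced hyperparameter grids to keep many-
    region runs desk-scale; ``regional_evaluate=False`` skips the outer CV
    loop for regional models (the global model is always fully evaluated).
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    atlas_cortical: int = 400
    atlas_subcortical: int = 14
    atlas_cerebellar: int = 28
    voxels_per_region: int = 10
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    regional_spec: ModelSpec | None = None
    regional_evaluate: bool = False
    percentile: float = 50.0
    alpha: float = 0.05
    mediation_B: int = 10_000
    mediation_outcomes: tuple[str, ...] = ("mmse",)
    mediation_regions: str = "significant"  # or "all"
    seed: int = 0
    outdir: str | Path = "pipeline_out"

    def validate(self) -> None:
        self.simulation.validate()
        self.model_spec.validate()
        if self.regional_spec is not None:
            self.regional_spec.validate()
        if self.mediation_B < 100:
            raise ValueError("mediation_B must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mediation_regions not in ("significant", "all"):
            raise ValueError("mediation_regions must be 'significant' or 'all'")


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    outdir: Path
    atlas: AtlasSpec
    train_subjects: pd.DataFrame
    app_subjects: pd.DataFrame
    bag: BagResult
    classification: object
    global_comparison: object
    regional_comparison: object
    mediation_table: pd.DataFrame
    summary_table: pd.DataFrame
    global_model: BrainAgeModel | None
    regional_models: dict[str, BrainAgeModel] | None
    provenance: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                log.error("stage %s: FAILED: %s", name, exc)
                raise PipelineError(name, exc) from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle.

    Outputs in ``config.outdir``: frozen ``config.json``, ``atlas.json``,
    ``train_subjects.tsv``, ``app_subjects.tsv``, ``bag_long.tsv``,
    ``cohort_summary.tsv`` (demographics-table shape), ``global_bag.json``
    (adjusted group contrast), ``regional_comparison.tsv``,
    ``mediation.tsv`` and ``provenance.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, outdir: Path) -> PipelineResult:
    # hash the analytic content only: where the outputs live must not
    # change what they contain
    chash = config_hash({k: v for k, v in config.__dict__.items()
                         if k != "outdir"})
    master = np.random.SeedSequence(config.seed)
    stage_seed = {name: int(s.generate_state(1)[0] % (2**31))
                  for name, s in zip(
                      ("simulate", "model", "mediation"), master.spawn(3))}

    atlas = make_atlas(config.atlas_cortical, config.atlas_subcortical,
                       config.atlas_cerebellar, config.voxels_per_region)
    atlas.to_json(outdir / "atlas.json")
    (outdir / "config.json").write_text(json.dumps(
        {"config_hash": chash, "seed": config.seed,
         "stage_seeds": stage_seed}, indent=1))

    sim = config.simulation
    sim.seed = stage_seed["simulate"]

    @_stage("simulate")
    def _simulate():
        tr_subj, tr_feat = generate_training_cohort(sim, atlas)
        ap_subj, ap_feat, truth = generate_application_cohort(sim, atlas)
        write_table(tr_subj, outdir / "train_subjects.tsv",
                    units={"age": "years"})
        write_table(ap_subj, outdir / "app_subjects.tsv",
                    units={"age": "years", "tiv_l": "l",
                           "wmh_volume_ml": "ml"})
        truth.to_json(outdir / "ground_truth.json")
        return tr_subj, tr_feat, ap_subj, ap_feat, truth

    tr_subj, tr_feat, ap_subj, ap_feat, truth = _simulate()

    bag_path = outdir / "bag_long.tsv"
    prov_path = outdir / "provenance.json"
    cached = None
    if bag_path.exists() and prov_path.exists():
        prev = json.loads(prov_path.read_text())
        if prev.get("config_hash") == chash:
            log.info("resuming from cached BAG table (config hash match)")
            cached = BagResult.from_tsv(bag_path)

    global_model = None
    regional_models = None
    if cached is not None:
        bag = cached
    else:
        mspec = ModelSpec(**{**config.model_spec.__dict__})
        mspec.seed = stage_seed["model"]
        rspec_src = config.regional_spec or config.model_spec
        rspec = ModelSpec(**{**rspec_src.__dict__})
        rspec.seed = stage_seed["model"]

        @_stage("train")
        def _train():
            gm = nested_cv_fit(
                tr_feat.region_mean().to_numpy(dtype=float),
                tr_subj["age"].to_numpy(dtype=float),
                mspec, feature_names=atlas.region_ids)
            rm = fit_regional_models(
                tr_feat, tr_subj["age"].to_numpy(dtype=float), atlas,
                rspec, evaluate=config.regional_evaluate)
            return gm, rm

        global_model, regional_models = _train()

        @_stage("predict")
        def _predict():
            b = predict_and_bag(global_model, regional_models, ap_feat,
                                ap_subj["age"].to_numpy(dtype=float))
            b.to_tsv(bag_path)
            return b

        bag = _predict()

    @_stage("classify")
    def _classify():
        markers = ap_subj[["subject_id", "wmh_volume_ml", "tiv_l",
                           "lacune_count", "cmb_count"]]
        return classify_csvd(markers, percentile=config.percentile)

    classification = _classify()
    flags = classification.flags

    @_stage("compare")
    def _compare():
        summary = cohort_summary(ap_subj, flags)
        write_table(summary, outdir / "cohort_summary.tsv")
        from .group_stats import ancova_group_effect, build_covariates
        covs = build_covariates(ap_subj)
        gb = bag.global_bag().loc[ap_subj["subject_id"]].to_numpy()
        g = flags.loc[ap_subj["subject_id"]].to_numpy(dtype=float)
        glob = ancova_group_effect(gb, g, covs, region_id="global")
        gdict = {
            "csvd_mean": float(gb[g == 1].mean()),
            "csvd_sd": float(gb[g == 1].std(ddof=1)),
            "noncsvd_mean": float(gb[g == 0].mean()),
            "noncsvd_sd": float(gb[g == 0].std(ddof=1)),
            "adjusted_difference": glob.coef,
            "pvalue": glob.pvalue,
            "partial_eta_sq": glob.partial_eta_sq,
        }
        (outdir / "global_bag.json").write_text(json.dumps(gdict, indent=1))
        regional = regional_bag_comparison(bag, ap_subj, flags, atlas,
                                           alpha=config.alpha)
        write_table(regional.table, outdir / "regional_comparison.tsv")
        return summary, glob, gdict, regional

    summary, glob, gdict, regional = _compare()

    @_stage("mediate")
    def _mediate():
        regions = (regional.significant_regions
                   if config.mediation_regions == "significant"
                   else [s for s in bag.scopes if s != "global"])
        if not regions:
            return pd.DataFrame()
        tab = mediation_screen(
            bag, ap_subj, flags, regions=regions,
            outcomes=config.mediation_outcomes, B=config.mediation_B,
            seed=stage_seed["mediation"], alpha=config.alpha, fwer=True)
        write_table(tab, outdir / "mediation.tsv")
        return tab

    mediation_table = _mediate()

    provenance = {
        "config_hash": chash,
        "seed": config.seed,
        "stage_seeds": stage_seed,
        "n_train": int(len(tr_subj)),
        "n_app": int(len(ap_subj)),
        "n_csvd": int(flags.sum()),
        "wmh_threshold": classification.threshold,
        "global_bag": gdict,
        "regional_summary": regional.summary(),
        "n_mediation_models": int(len(mediation_table)),
        "mediation_B": config.mediation_B,
        "alpha": config.alpha,
    }
    prov_path.write_text(json.dumps(provenance, indent=1))

    return PipelineResult(
        outdir=outdir, atlas=atlas,
        train_subjects=tr_subj, app_subjects=ap_subj,
        bag=bag, classification=classification,
        global_comparison=glob, regional_comparison=regional,
        mediation_table=mediation_table, summary_table=summary,
        global_model=global_model, regional_models=regional_models,
        provenance=provenance,
    )
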