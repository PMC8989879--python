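"""End-to-end orchestration: simulate/ingest -> train -> project -> stratify
-> rates -> group inference -> trial power -> regression transfer.

The pipeline is a thin sequencer over the library modules.  It runs the
three-cohort design: a labelled training cohort fits the classifier and the
probabilistic threshold; an unlabelled test cohort is stratified by the
prognostic index and its future tau/PACC rates are compared between
strata; a third cohort receives transferred per-ROI rate predictions.  All
outputs are plain CSV/YAML/JSON text written at fixed precision, listed in
a manifest with content hashes and the global seed so any stage can be
re-run reproducibly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import index as idx
from . import inference, power, rates, transfer
from .gmlvq import GMLVQ
from .roi import HIGH_SLOPE_ROIS, load_braak_map
from .synthetic import SyntheticConfig, generate_cohort
from .tables import (CLASS_DECLINING, CLASS_STABLE, amyloid_positive,
                     baseline_values, read_cohort, read_series, write_cohort,
                     write_series)

_FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    """Inputs, seeds and stage parameters for one full run.

    Exactly one of ``synthetic`` (generator overrides; may be an empty dict
    for defaults) or ``inputs`` (paths to cohort/series CSVs for train,
    test and transfer cohorts) must be set.
    """

    out_dir: str = "tautraj_out"
    seed: int = 0
    synthetic: dict | None = field(default_factory=dict)
    inputs: dict | None = None
    train: dict = field(default_factory=dict)      # GMLVQ.fit kwargs
    power_spec: dict = field(default_factory=dict)  # PowerSpec kwargs
    braak_map_path: str | None = None
    cv_resamples: int = 400
    run_cv: bool = True
    restratify_roi: str = "fusiform"
    restratify_grid: tuple = (0.0, 1.2, 0.2)  # start, stop, step

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def validate(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'synthetic' and 'inputs' must be configured")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


def _cohorts(config: PipelineConfig):
    """Yield (name, cohort_df, series_df) for train/test/transfer."""
    if config.synthetic is not None:
        base = SyntheticConfig(**config.synthetic)
        out = {}
        for offset, name in enumerate(("train", "test", "transfer")):
            c = generate_cohort(base.with_(seed=int(config.seed) + offset,
                                           cohort_name=name))
            out[name] = (c.cohort_table, c.series)
        return out
    out = {}
    for name in ("train", "test", "transfer"):
        spec = config.inputs[name]
        # the train stage itself checks for labels, so the abort names it
        out[name] = (read_cohort(spec["cohort"]), read_series(spec["series"]))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(config.seed), "stages": {}, "parameters": {}}

    def record(stage: str, name: str, path: Path):
        manifest["stages"].setdefault(stage, {})[name] = {
            "path": str(path), "sha256": _sha256(path)}

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # -- stage: cohorts ----------------------------------------------------
    try:
        cohorts = _cohorts(config)
        for name, (table, series) in cohorts.items():
            write_cohort(table, out / f"{name}_cohort.csv")
            write_series(series, out / f"{name}_series.csv")
            record("cohorts", f"{name}_cohort", out / f"{name}_cohort.csv")
            record("cohorts", f"{name}_series", out / f"{name}_series.csv")
    except Exception as exc:
        fail("cohorts", exc)

    # -- stage: train ------------------------------------------------------
    try:
        train_table = cohorts["train"][0]
        if "class_label" not in train_table.columns or train_table["class_label"].isna().all():
            raise ValueError("training cohort has no class labels")
        model = GMLVQ.from_dataframe(train_table).fit(
            seed=int(config.seed), **config.train)
        model.save(out / "gmlvq_model.yaml")
        record("train", "model", out / "gmlvq_model.yaml")
    except Exception as exc:
        fail("train", exc)

    # -- stage: threshold (3-class logistic on the training cohort) --------
    try:
        feats = train_table[["amyloid_centiloid", "mtl_gm_density", "apoe4"]]
        train_scores = pd.Series(model.scalar_projection(feats.to_numpy(float)),
                                 index=train_table["subject_id"], name="s")
        thr_model = idx.fit_threshold(train_scores.to_numpy(),
                                      train_table["class_label"].to_numpy())
        threshold = thr_model.threshold_s
        manifest["parameters"]["threshold_s"] = threshold
        manifest["parameters"]["threshold_separated"] = thr_model.separated
        _write_csv(train_scores.reset_index(), out / "train_scores.csv")
        record("threshold", "train_scores", out / "train_scores.csv")
    except Exception as exc:
        fail("threshold", exc)

    # -- stage: cross-validation ------------------------------------------
    if config.run_cv:
        try:
            cv = idx.balanced_resampling_cv(
                train_table, n_resamples=config.cv_resamples,
                seed=int(config.seed), **config.train)
            cv_df = pd.DataFrame({"sensitivity": cv.sensitivity,
                                  "specificity": cv.specificity})
            _write_csv(cv_df, out / "cv_resamples.csv")
            record("cv", "resamples", out / "cv_resamples.csv")
            manifest["parameters"]["cv_balanced_accuracy"] = cv.balanced_accuracy
        except Exception as exc:
            fail("cv", exc)

    # -- stage: project + stratify the test cohort -------------------------
    try:
        scores, strata = {}, {}
        for name in ("test", "transfer"):
            table = cohorts[name][0]
            s = pd.Series(model.scalar_projection(
                table[["amyloid_centiloid", "mtl_gm_density", "apoe4"]].to_numpy(float)),
                index=table["subject_id"], name="s")
            scores[name] = s
            assigned = pd.Series(idx.stratify(s.to_numpy(), threshold),
                                 index=s.index, name="stratum")
            strata[name] = assigned
            df = pd.DataFrame({"s": s, "stratum": assigned})
            _write_csv(df.reset_index(), out / f"{name}_scores.csv")
            record("project", f"{name}_scores", out / f"{name}_scores.csv")
    except Exception as exc:
        fail("project", exc)

    # -- stage: rates ------------------------------------------------------
    try:
        rate_tables = {}
        for name in ("test", "transfer"):
            rt = rates.build_rate_table(cohorts[name][1])
            rate_tables[name] = rt
            _write_csv(rt, out / f"{name}_rates.csv")
            record("rates", name, out / f"{name}_rates.csv")
    except Exception as exc:
        fail("rates", exc)

    # -- stage: group inference on the test cohort -------------------------
    try:
        rt = rate_tables["test"]
        assigned = strata["test"]
        declining = assigned.index[assigned == CLASS_DECLINING]
        stable = assigned.index[assigned == CLASS_STABLE]
        regional = {}
        for grp_name, grp in (("declining", declining), ("stable", stable)):
            res = inference.regional_accumulation_tests(rt, grp)
            regional[grp_name] = res
            _write_csv(res, out / f"regional_tests_{grp_name}.csv")
            record("inference", f"regional_{grp_name}", out / f"regional_tests_{grp_name}.csv")
        mean_d = regional["declining"].set_index("roi")["mean_rate"]
        mean_s = regional["stable"].set_index("roi")["mean_rate"].reindex(mean_d.index)
        glob = inference.global_rate_test(mean_d.to_numpy(), mean_s.to_numpy())
        icc = inference.icc_one_way(mean_d.to_numpy(), mean_s.to_numpy())

        test_table = cohorts["test"][0].set_index("subject_id")
        braak = inference.braak_baseline_contrast(
            baseline_values(cohorts["test"][1]).drop(columns="PACC"),
            load_braak_map(config.braak_map_path), declining, stable)
        _write_csv(braak, out / "braak_baseline_contrast.csv")
        record("inference", "braak", out / "braak_baseline_contrast.csv")

        dx = test_table.loc[assigned.index, "baseline_dx"]
        table2x2 = np.array([
            [int(((dx == "CN") & (assigned == CLASS_STABLE)).sum()),
             int(((dx == "CN") & (assigned == CLASS_DECLINING)).sum())],
            [int(((dx == "MCI") & (assigned == CLASS_STABLE)).sum()),
             int(((dx == "MCI") & (assigned == CLASS_DECLINING)).sum())],
        ])
        kappa = inference.cohens_kappa(table2x2)
        summary = {"global_rate_test": glob,
                   "icc_one_way": asdict(icc),
                   "kappa_vs_baseline_dx": asdict(kappa),
                   "kappa_table": table2x2.tolist()}
        (out / "inference_summary.json").write_text(json.dumps(summary, indent=2))
        record("inference", "summary", out / "inference_summary.json")
    except Exception as exc:
        fail("inference", exc)

    # -- stage: trial power ------------------------------------------------
    try:
        spec = power.PowerSpec(**config.power_spec)
        amyloid_pos = test_table.index[
            amyloid_positive(test_table["amyloid_centiloid"].to_numpy()) == 1]
        comp = power.compare_stratifications(
            rt, declining, amyloid_pos, list(HIGH_SLOPE_ROIS), spec)
        _write_csv(comp, out / "power_comparison.csv")
        record("power", "comparison", out / "power_comparison.csv")
        manifest["parameters"]["mean_power_reduction_pct"] = comp.attrs[
            "mean_reduction_pct"]
        start, stop, step = config.restratify_grid
        grid = np.arange(start, stop + 1e-9, step)
        restrat = power.restratify_and_power(scores["test"], rt,
                                             config.restratify_roi, grid, spec)
        _write_csv(restrat, out / "restratify_power.csv")
        record("power", "restratify", out / "restratify_power.csv")
    except Exception as exc:
        fail("power", exc)

    # -- stage: regression transfer ---------------------------------------
    try:
        result = transfer.transfer_experiment(
            scores["test"], rate_tables["test"],
            scores["transfer"], rate_tables["transfer"], threshold)
        models_df = pd.DataFrame([vars(m) for m in result["models"].values()])
        _write_csv(models_df, out / "roi_regressions.csv")
        record("transfer", "models", out / "roi_regressions.csv")
        for grp in ("declining", "stable"):
            _write_csv(result[grp], out / f"transfer_accuracy_{grp}.csv")
            record("transfer", grp, out / f"transfer_accuracy_{grp}.csv")
    except Exception as exc:
        fail("transfer", exc)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
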