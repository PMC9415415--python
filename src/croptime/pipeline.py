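"""End-to-end orchestration: simulate -> features -> stack -> train ->
evaluate -> timeline, with on-disk artifacts and a run manifest.

Every stage reads its inputs from the run directory, writes CSV/JSON
artifacts with documented headers, and appends row counts to
``manifest.json``.  All randomness derives from a single root seed, split
deterministically per stage, so a full run is reproducible byte for byte.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import accuracy, classify, stacking, synthetic
from .calendars import AcquisitionCalendar
from .spectral import BANDS, EMERGENCE_THRESHOLD, SoilLine, attach_indices, estimate_soil_line

__all__ = ["RunConfig", "PipelineError", "run_stage", "STAGES"]

STAGES = ("simulate", "features", "stack", "train", "evaluate", "timeline")


class PipelineError(RuntimeError):
    """A stage could not run (bad config or missing upstream artifact)."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (see docs/methods.md)."""

    outdir: Path
    seed: int = 0
    train_scenario: str = "survey2019"
    test_scenario: str = "cycle2020"
    combinations: tuple[str, ...] = ("C1", "C2", "C3", "C4")
    algorithms: tuple[str, ...] = ("svm_cubic", "bagged_trees")
    svm_C: float = 1.0
    n_trees: int = 100
    cv_folds: int = 5
    standardize: bool = True
    soil_line_source: str = "bare_plots"      # or "fixed"
    soil_line_slope: Optional[float] = None   # required when source == "fixed"
    emergence_threshold: float = EMERGENCE_THRESHOLD
    filter_scope: str = "all"
    tolerance: int = 5
    timeline_dates: Optional[tuple[dt.date, ...]] = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [c for c in self.combinations if c not in stacking.COMBINATIONS]
        if unknown:
            raise PipelineError(f"unknown combinations: {unknown}")
        for a in self.algorithms:
            if a not in ("svm_cubic", "bagged_trees"):
                raise PipelineError(f"unknown algorithm {a!r}")
        if self.soil_line_source not in ("bare_plots", "fixed"):
            raise PipelineError("soil_line_source must be 'bare_plots' or 'fixed'")
        if self.soil_line_source == "fixed" and self.soil_line_slope is None:
            raise PipelineError("soil_line_source 'fixed' requires soil_line_slope")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise PipelineError("config must set outdir")
        dates = raw.get("timeline_dates")
        if dates:
            raw["timeline_dates"] = tuple(
                d if isinstance(d, dt.date) else dt.date.fromisoformat(d)
                for d in dates)
        for key in ("combinations", "algorithms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        payload = {k: (str(v) if isinstance(v, (Path, dt.date)) else v)
                   for k, v in self.__dict__.items()}
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"stage '{stage}' needs {path.name}, which is produced by the "
            f"'{produced_by}' stage; run that stage first")
    return path


def _update_manifest(outdir: Path, stage: str, entries: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["stages"][stage] = entries
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def _load_table(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["date"] = pd.to_datetime(table["date"]).dt.date
    return table


def _load_calendar(path: Path) -> AcquisitionCalendar:
    cal = pd.read_csv(path)
    return AcquisitionCalendar(
        dates=tuple(pd.to_datetime(cal["date"]).dt.date),
        cloudy=tuple(bool(c) for c in cal["cloudy"]))


def _soil_line(cfg: RunConfig, train_table: pd.DataFrame) -> SoilLine:
    if cfg.soil_line_source == "fixed":
        return SoilLine(slope_a=float(cfg.soil_line_slope))
    bare = train_table[train_table["crop_label"] == "bare"]
    if bare.empty:
        raise PipelineError("no bare-soil records to estimate the soil line from; "
                            "set soil_line_source: fixed with a slope")
    return estimate_soil_line(bare[list(BANDS)].to_numpy())


def stage_simulate(cfg: RunConfig) -> dict:
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    counts = {}
    for role, scenario in (("train", cfg.train_scenario), ("test", cfg.test_scenario)):
        ds = synthetic.generate_dataset(scenario, _stage_seed(cfg.seed, f"simulate-{role}"))
        synthetic.dataset_to_csv(ds, out / f"{role}_reflectance.csv",
                                 out / f"{role}_calendar.csv")
        synthetic.write_plots_geojson(ds.plots, out / f"{role}_plots.geojson")
        meta = {
            "scenario": scenario,
            "n_plots": len(ds.plots),
            "n_bare_plots": len(ds.bare_plots),
            "train_plot_ids": ds.train_plot_ids,
            "validation_plot_ids": ds.validation_plot_ids,
            "analysis_dates": [d.isoformat() for d in ds.config.analysis_dates],
        }
        (out / f"{role}_meta.json").write_text(json.dumps(meta, indent=2))
        counts[f"{role}_rows"] = len(ds.table)
        counts[f"{role}_plots"] = len(ds.plots)
    return counts


def stage_features(cfg: RunConfig) -> dict:
    out = cfg.outdir
    counts = {}
    train = _load_table(_require(out / "train_reflectance.csv", "features", "simulate"))
    line = _soil_line(cfg, train)
    (out / "soil_line.json").write_text(json.dumps(
        {"slope_a": line.slope_a, "intercept": line.intercept,
         "source": cfg.soil_line_source}))
    for role in ("train", "test"):
        table = _load_table(_require(out / f"{role}_reflectance.csv",
                                     "features", "simulate"))
        feats = attach_indices(table, line, cfg.emergence_threshold)
        feats_out = feats.copy()
        feats_out["date"] = pd.to_datetime(feats_out["date"]).dt.strftime("%Y-%m-%d")
        feats_out.to_csv(out / f"{role}_features.csv", index=False)
        counts[f"{role}_rows"] = len(feats)
    counts["soil_line_slope"] = line.slope_a
    return counts


def stage_stack(cfg: RunConfig) -> dict:
    out = cfg.outdir
    _require(out / "soil_line.json", "stack", "features")
    line = SoilLine(**{k: v for k, v in
                       json.loads((out / "soil_line.json").read_text()).items()
                       if k in ("slope_a", "intercept")})
    table = _load_table(_require(out / "train_reflectance.csv", "stack", "simulate"))
    meta = json.loads(_require(out / "train_meta.json", "stack", "simulate").read_text())
    cal = _load_calendar(_require(out / "train_calendar.csv", "stack", "simulate"))
    analysis_dates = [dt.date.fromisoformat(d) for d in meta["analysis_dates"]] or None
    counts = {}
    for comb in cfg.combinations:
        spec = stacking.combination(comb, cfg.tolerance)
        wide = stacking.assemble_training_table(
            table, cal, spec, line, analysis_dates=analysis_dates,
            emergence_threshold=cfg.emergence_threshold,
            filter_scope=cfg.filter_scope)
        wide_out = wide.copy()
        wide_out["analysis_date"] = [d.isoformat() for d in wide_out["analysis_date"]]
        wide_out.to_csv(out / f"training_table_{comb}.csv", index=False)
        sidecar = {"combination": comb, "lags": list(spec.lags),
                   "tolerance": spec.tolerance,
                   "emergence_threshold": cfg.emergence_threshold,
                   "filter_scope": cfg.filter_scope,
                   "descriptors": stacking.descriptor_columns(spec),
                   "n_records": len(wide)}
        (out / f"training_table_{comb}.meta.json").write_text(
            json.dumps(sidecar, indent=2))
        counts[comb] = len(wide)
    return counts


def _classifier(cfg: RunConfig, algorithm: str, seed: int):
    if algorithm == "svm_cubic":
        return classify.PolySVMClassifier(C=cfg.svm_C, standardize=cfg.standardize)
    return classify.BaggedTreesClassifier(n_estimators=cfg.n_trees,
                                          standardize=cfg.standardize,
                                          random_state=seed)


def stage_train(cfg: RunConfig) -> dict:
    out = cfg.outdir
    meta = json.loads(_require(out / "train_meta.json", "train", "simulate").read_text())
    train_ids = set(meta["train_plot_ids"])
    counts = {}
    for comb in cfg.combinations:
        path = _require(out / f"training_table_{comb}.csv", "train", "stack")
        wide = pd.read_csv(path)
        cols = stacking.descriptor_columns(comb)
        subset = wide[wide["plot_id"].isin(train_ids)]
        for algo in cfg.algorithms:
            seed = _stage_seed(cfg.seed, f"train-{algo}-{comb}")
            model = _classifier(cfg, algo, seed)
            model.fit(subset[cols], subset["crop_label"])
            cv = classify.cross_validate(model, subset[cols], subset["crop_label"],
                                         folds=cfg.cv_folds, seed=seed)
            classify.save_model(model, out / f"model_{comb}_{algo}.joblib",
                                feature_names=cols)
            log = {"combination": comb, "algorithm": algo, "seed": seed,
                   "n_records": len(subset),
                   "cv_overall_accuracy": cv["overall_accuracy"],
                   "cv_kappa": cv["kappa"],
                   "cv_fold_overall_accuracy": cv["fold_overall_accuracy"]}
            (out / f"model_{comb}_{algo}.log.json").write_text(
                json.dumps(log, indent=2))
            counts[f"{comb}/{algo}"] = {"n_records": len(subset),
                                        "cv_oa": round(cv["overall_accuracy"], 2)}
    return counts


def stage_evaluate(cfg: RunConfig) -> dict:
    """Holdout validation on the training cycle's 50% validation plots."""
    out = cfg.outdir
    meta = json.loads(_require(out / "train_meta.json", "evaluate", "simulate").read_text())
    valid_ids = set(meta["validation_plot_ids"])
    rows = []
    for comb in cfg.combinations:
        path = _require(out / f"training_table_{comb}.csv", "evaluate", "stack")
        wide = pd.read_csv(path)
        cols = stacking.descriptor_columns(comb)
        subset = wide[wide["plot_id"].isin(valid_ids)]
        for algo in cfg.algorithms:
            model = classify.load_model(
                _require(out / f"model_{comb}_{algo}.joblib", "evaluate", "train"))
            report = accuracy.evaluate(model, subset, cols)
            row = {"combination": comb, "algorithm": algo, "n_records": report.n,
                   "overall_accuracy": report.overall_accuracy,
                   "kappa": report.kappa, "altman_rating": report.altman_rating}
            for cls, v in report.producers_accuracy.items():
                row[f"PA_{cls}"] = v
            for cls, v in report.users_accuracy.items():
                row[f"UA_{cls}"] = v
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "validation_report.csv", index=False)
    return {"rows": len(frame)}


def stage_timeline(cfg: RunConfig) -> dict:
    out = cfg.outdir
    table = _load_table(_require(out / "test_reflectance.csv", "timeline", "simulate"))
    cal = _load_calendar(_require(out / "test_calendar.csv", "timeline", "simulate"))
    meta = json.loads(_require(out / "test_meta.json", "timeline", "simulate").read_text())
    line = SoilLine(**{k: v for k, v in
                       json.loads(_require(out / "soil_line.json", "timeline",
                                           "features").read_text()).items()
                       if k in ("slope_a", "intercept")})
    dates = cfg.timeline_dates or tuple(
        dt.date.fromisoformat(d) for d in meta["analysis_dates"])
    counts = {}
    for algo in cfg.algorithms:
        models = {
            comb: classify.load_model(
                _require(out / f"model_{comb}_{algo}.joblib", "timeline", "train"))
            for comb in cfg.combinations}
        timeline = accuracy.timeline_evaluate(
            models, table, cal, dates, line,
            emergence_threshold=cfg.emergence_threshold,
            filter_scope=cfg.filter_scope, tolerance=cfg.tolerance)
        out_frame = timeline.copy()
        out_frame["date"] = [d.isoformat() for d in out_frame["date"]]
        out_frame.to_csv(out / f"timeline_{algo}.csv", index=False)
        accuracy.plot_timeline(timeline, out / f"timeline_{algo}.png")
        counts[algo] = len(timeline)
    return counts


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "features": stage_features,
    "stack": stage_stack,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "timeline": stage_timeline,
}


def run_stage(stage: str, cfg: RunConfig) -> dict:
    """Run one stage (or 'all') and record it in the manifest."""
    if stage == "all":
        results = {}
        for name in STAGES:
            results[name] = run_stage(name, cfg)
        return results
    if stage not in _STAGE_FUNCS:
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    result = _STAGE_FUNCS[stage](cfg)
    _update_manifest(cfg.outdir, stage, {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "stage_seed": _stage_seed(cfg.seed, stage),
        "counts": result,
    })
    return result
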