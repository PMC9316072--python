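"""End-to-end orchestration: simulate -> features -> relate -> stats ->
greyzone -> evaluate -> report.

Each stage writes plain-text artifacts (CSV/JSON) into the run directory,
stamped with a hash of the run configuration; a completed stage whose stamp
matches the current configuration is skipped on re-run, so a pipeline is
resumable per stage. All randomness flows through named per-stage seed
streams spawned from one master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig, VITAL_SIGNS
from .cohort_stats import correlations, stage_comparison_table
from .errors import EcShockError
from .features import FeatureScaler, build_feature_table, feature_columns
from .greyzone import GreyZoneAnalysis
from .nested_cv import NestedCVExperiment, default_model_specs
from .protocol import ProtocolDefinition, default_protocol
from .relational import build_relational
from .simulate import CohortDataset, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("ecshock.pipeline")

STAGES = ("simulate", "features", "relate", "stats", "greyzone", "evaluate", "report")

#: markers evaluated in the grey-zone stage: relational differences of the
#: window-mean EC channels and of the cuff vital signs
DEFAULT_GREYZONE_MARKERS = ("sv", "pep", "str", "icon", "hr", "sbp")


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    n_subjects: int = 30
    seed: int = 7
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    protocol: ProtocolDefinition = field(default_factory=default_protocol)
    models: tuple[str, ...] = ("rf",)
    n_rep: int = 29
    n_boot: int = 1000
    greyzone_markers: tuple[str, ...] = DEFAULT_GREYZONE_MARKERS
    outdir: str = "ecshock_run"

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "generator": self.generator.to_dict(),
            "protocol": self.protocol.to_dict(),
            "models": list(self.models),
            "n_rep": self.n_rep,
            "n_boot": self.n_boot,
            "greyzone_markers": list(self.greyzone_markers),
            "outdir": str(self.outdir),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["generator"] = GeneratorConfig.from_dict(d.get("generator", {}))
        d["protocol"] = ProtocolDefinition.from_dict(d["protocol"]) \
            if "protocol" in d else default_protocol()
        d["models"] = tuple(d.get("models", ("rf",)))
        d["greyzone_markers"] = tuple(d.get("greyzone_markers",
                                            DEFAULT_GREYZONE_MARKERS))
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed stream derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _stamp(outdir: Path, stage: str, cfg: RunConfig, outputs: list[Path]) -> None:
    (outdir / f".{stage}.done").write_text(json.dumps({
        "config_hash": cfg.config_hash(),
        "outputs": [str(p.name) for p in outputs],
    }))


def _is_done(outdir: Path, stage: str, cfg: RunConfig) -> bool:
    stamp = outdir / f".{stage}.done"
    if not stamp.exists():
        return False
    try:
        meta = json.loads(stamp.read_text())
    except json.JSONDecodeError:
        return False
    if meta.get("config_hash") != cfg.config_hash():
        return False
    return all((outdir / name).exists() for name in meta.get("outputs", []))


def run_pipeline(cfg: RunConfig, stages=STAGES, resume: bool = True) -> dict:
    """Execute the requested stages; returns the machine-readable report.

    A stage failure aborts with a stage-scoped error message. Completed
    stages with a matching configuration stamp are skipped when
    ``resume=True``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": cfg.config_hash()}
    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        runner = _STAGE_RUNNERS[stage]
        if resume and stage != "report" and _is_done(outdir, stage, cfg):
            log.info("[%s] up to date, skipping", stage)
            continue
        log.info("[%s] running", stage)
        try:
            outputs = runner(cfg, outdir, state)
        except EcShockError as exc:
            raise EcShockError(f"stage {stage!r} failed: {exc}") from exc
        if stage != "report":
            _stamp(outdir, stage, cfg, outputs)
    report_path = outdir / "report.json"
    if report_path.exists():
        report = json.loads(report_path.read_text())
    return report


# --------------------------------------------------------------------------
# stage runners (each loads its inputs from disk, so stages are resumable)


def _load_cohort(cfg: RunConfig, outdir: Path) -> CohortDataset:
    return CohortDataset.read_csv(outdir, protocol=cfg.protocol)


def _run_simulate(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    cohort = generate_cohort(cfg.n_subjects, cfg.generator, cfg.protocol,
                             seed=cfg.stage_seed("simulate"))
    cohort.write_csv(outdir)
    return [outdir / n for n in ("beats.csv", "echo.csv", "vitals.csv")]


def _run_features(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    cohort = _load_cohort(cfg, outdir)
    table = build_feature_table(cohort, cfg.protocol)
    table.to_csv(outdir / "features.csv", index=False)
    return [outdir / "features.csv"]


def _run_relate(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    table = pd.read_csv(outdir / "features.csv")
    cols = [c for c in feature_columns() if c in table.columns]
    scaler = FeatureScaler().fit(table, cols)
    z = scaler.transform(table)
    base = table[["subject_id", "stage", "sv_tte_ml"]].reset_index(drop=True)
    for marker, src in [("hr", "hr_mean"), *[(v, v) for v in VITAL_SIGNS]]:
        base[f"marker_{marker}"] = table[src].to_numpy()
    marker_cols = ["marker_hr"] + [f"marker_{v}" for v in VITAL_SIGNS]
    rel = build_relational(
        pd.concat([base, z.reset_index(drop=True)], axis=1),
        feature_cols=scaler.columns,
        marker_cols=marker_cols,
        protocol=cfg.protocol)
    rel.to_csv(outdir / "relational.csv", index=False)
    return [outdir / "relational.csv"]


def _run_stats(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    table = pd.read_csv(outdir / "features.csv")
    value_cols = ["sv_tte_ml", "sv_mean", "hr_mean", "icon_mean",
                  "co_mean", "pep_mean", "str_mean", *VITAL_SIGNS]
    stats = stage_comparison_table(table, value_cols)
    stats.to_csv(outdir / "stage_stats.csv", index=False)
    corr_rows = []
    for param in ("sv_mean", "icon_mean", "pep_mean", "str_mean",
                  "svv_mean", "hrv_mean", "hr_mean", *VITAL_SIGNS):
        for scope in ("population", "per-subject"):
            r = correlations(table, param, "sv_tte_ml", scope=scope)
            corr_rows.append({
                "parameter": param, "scope": scope, "pearson": r.pearson,
                "spearman": r.spearman, "cohen": r.cohen,
                "q25": r.q25, "q75": r.q75,
            })
    pd.DataFrame(corr_rows).to_csv(outdir / "correlations.csv", index=False)
    return [outdir / "stage_stats.csv", outdir / "correlations.csv"]


def _run_greyzone(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    rel = pd.read_csv(outdir / "relational.csv")
    rel = rel[rel["valid"]]
    seed_seq = np.random.SeedSequence(cfg.stage_seed("greyzone"))
    results = []
    for marker, child in zip(cfg.greyzone_markers,
                             seed_seq.spawn(len(cfg.greyzone_markers))):
        for col in (marker, f"marker_{marker}", f"{marker}_mean"):
            if col in rel.columns:
                break
        else:
            raise EcShockError(f"no relational column for marker {marker!r}")
        res = GreyZoneAnalysis(rel[col].to_numpy(float),
                               rel["label"].to_numpy(int),
                               name=marker).fit(
            n_boot=cfg.n_boot,
            random_state=np.random.default_rng(child))
        results.append(res.to_dict())
    (outdir / "greyzone.json").write_text(json.dumps(results, indent=2))
    return [outdir / "greyzone.json"]


def _run_evaluate(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    table = pd.read_csv(outdir / "features.csv")
    n_feat = len([c for c in feature_columns() if c in table.columns])
    specs = [m for m in default_model_specs(n_feat)
             if m.algorithm in set(cfg.models)]
    exp = NestedCVExperiment(table, models=specs, protocol=cfg.protocol)
    res = exp.fit(n_rep=cfg.n_rep, seed=cfg.stage_seed("evaluate"))
    res.auc_table().to_csv(outdir / "cv_aucs.csv", index=False)
    res.comparison_table().to_csv(outdir / "cv_comparisons.csv", index=False)
    sel_log = {
        name: {
            "selected_features": r.selected_features,
            "chosen_params": r.chosen_params,
            "expansion_events": r.expansion_events,
        } for name, r in res.results.items()
    }
    (outdir / "cv_log.json").write_text(json.dumps(sel_log, indent=2, default=str))
    (outdir / "cv_summary.txt").write_text(res.summary() + "\n")
    return [outdir / n for n in
            ("cv_aucs.csv", "cv_comparisons.csv", "cv_log.json", "cv_summary.txt")]


def _run_report(cfg: RunConfig, outdir: Path, state: dict) -> list[Path]:
    rel = pd.read_csv(outdir / "relational.csv")
    report = {
        "config_hash": cfg.config_hash(),
        "n_subjects": cfg.n_subjects,
        "relational_observations": int(len(rel)),
        "relational_valid": int(rel["valid"].sum()),
        "relational_invalid": int((~rel["valid"]).sum()),
        "relational_positive": int(rel.loc[rel["valid"], "label"].sum()),
    }
    if (outdir / "greyzone.json").exists():
        report["greyzone"] = json.loads((outdir / "greyzone.json").read_text())
    if (outdir / "correlations.csv").exists():
        report["correlations"] = pd.read_csv(
            outdir / "correlations.csv").to_dict("records")
    if (outdir / "cv_aucs.csv").exists():
        aucs = pd.read_csv(outdir / "cv_aucs.csv").dropna(subset=["auc"])
        report["cv_median_auc"] = {
            name: float(grp["auc"].median())
            for name, grp in aucs.groupby("name")}
    if (outdir / "cv_comparisons.csv").exists():
        report["cv_comparisons"] = pd.read_csv(
            outdir / "cv_comparisons.csv").to_dict("records")
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    lines = [f"ecshock run {report['config_hash']}",
             f"subjects: {report['n_subjects']}",
             f"relational observations: {report['relational_observations']} "
             f"({report['relational_invalid']} invalid, "
             f"{report['relational_positive']} positive)"]
    if "cv_median_auc" in report:
        for name, auc in report["cv_median_auc"].items():
            lines.append(f"median held-out AUC [{name}]: {auc:.3f}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return [outdir / "report.json", outdir / "summary.txt"]


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "features": _run_features,
    "relate": _run_relate,
    "stats": _run_stats,
    "greyzone": _run_greyzone,
    "evaluate": _run_evaluate,
    "report": _run_report,
}
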