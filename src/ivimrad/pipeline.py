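"""End-to-end study orchestration.

``run_study`` executes the full chain — synthetic cohort → three voxelwise
fitters → first-order histogram radiomics → cross-software agreement →
benign/malignant diagnostics → report — writing every stage's tables under
an output directory. The run is a pure function of (config, seed): CSVs
are byte-identical across repeated runs.

The numbered drivers under ``analysis/`` expose the same stages as
independently re-runnable command-line steps.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import BayesOptions
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .fitting import FitOptions, fit_roi
from . import agreement as agr
from . import diagnostics as diag
from . import radiomics as rad

__all__ = ["StudyConfig", "StudyReport", "run_study", "render_report",
           "cohort_frame", "compute_features"]

log = logging.getLogger(__name__)

FIT_METHODS = ("seg_a", "seg_b", "bayes")
_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of one study run; serializable to/from JSON and YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    fit: FitOptions = field(default_factory=FitOptions)
    bayes: BayesOptions = field(default_factory=lambda: BayesOptions(n_grid=48))
    shared_slope: bool = False
    excess_kurtosis: bool = False
    write_nifti: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        sub = {"cohort": CohortConfig, "fit": FitOptions, "bayes": BayesOptions}
        kwargs = {}
        for key, typ in sub.items():
            if key in d:
                payload = dict(d.pop(key))
                if key == "cohort" and "site_counts" in payload:
                    payload["site_counts"] = {
                        s: tuple(c) for s, c in payload["site_counts"].items()}
                fields = {f.name: f for f in dataclasses.fields(typ)}
                bad = set(payload) - set(fields)
                if bad:
                    raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
                for name, val in payload.items():
                    # JSON stores tuples as lists; coerce them back
                    if isinstance(val, list) and isinstance(
                            fields[name].default, tuple):
                        payload[name] = tuple(val)
                kwargs[key] = typ(**payload)
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**kwargs, **d)

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """File manifest plus in-memory stage results."""

    out_dir: Path
    manifest: dict[str, str]
    config: StudyConfig
    features: pd.DataFrame | None = None
    agreement_summaries: list | None = None
    diagnostic_summaries: list | None = None
    failed_stage: str | None = None

    def path(self, key: str) -> Path:
        return self.out_dir / self.manifest[key]


def cohort_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    rows = [dict(patient_id=l.patient_id, site_tag=l.site_tag, label=l.label,
                 n_voxels=l.n_voxels, scheme_variant=l.scheme.variant_index,
                 snr=l.snr) for l in cohort.lesions]
    return pd.DataFrame(rows)


def compute_features(cohort: SyntheticCohort, config: StudyConfig,
                     methods=FIT_METHODS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every lesion with every method and extract radiomic features.

    Returns the tidy feature table and a per-(patient, method, parameter)
    utilization table.
    """
    rows, util_rows = [], []
    t0 = time.time()
    for i, lesion in enumerate(cohort.lesions):
        S = cohort.noisy_signals[lesion.patient_id]
        for m in methods:
            pmap = fit_roi(S, lesion.scheme, m, options=config.fit,
                           patient_id=lesion.patient_id,
                           bayes_options=config.bayes)
            feats = rad.features_for_map(
                pmap, excess_kurtosis=config.excess_kurtosis)
            rows.append(dict(patient_id=lesion.patient_id,
                             site_tag=lesion.site_tag, label=lesion.label,
                             method_tag=m, features=feats))
            for par, f in feats.items():
                util_rows.append(dict(patient_id=lesion.patient_id,
                                      site_tag=lesion.site_tag,
                                      method_tag=m, parameter=par,
                                      utilization=f.utilization,
                                      n_used=f.n_used,
                                      n_voxels=lesion.n_voxels))
        if (i + 1) % 25 == 0:
            log.info("fitted %d/%d lesions (%.0f s)", i + 1,
                     len(cohort.lesions), time.time() - t0)
    return rad.feature_table(rows), pd.DataFrame(util_rows)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_study(config: StudyConfig, out_dir) -> StudyReport:
    """Execute all stages; idempotent given (config, seed).

    On a stage failure the partial manifest records the failed stage and
    the exception is re-raised after writing the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    report = StudyReport(out, manifest, config)
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    manifest["config"] = "config.json"
    stage = "simulate"
    try:
        t0 = time.time()
        cohort = generate_cohort(config.cohort, config.seed)
        _write(cohort_frame(cohort), out / "cohort.csv")
        manifest["cohort"] = "cohort.csv"
        if config.write_nifti:
            from .nifti_io import write_lesion_nifti
            nii_dir = out / "nifti"
            for lesion in cohort.lesions:
                write_lesion_nifti(cohort.noisy_signals[lesion.patient_id],
                                   lesion.scheme, nii_dir, lesion.patient_id)
            manifest["nifti_dir"] = "nifti"
        log.info("simulate: %d lesions in %.1f s", len(cohort), time.time() - t0)

        stage = "fit+radiomics"
        t0 = time.time()
        features, util = compute_features(cohort, config)
        _write(features, out / "features.csv")
        _write(util, out / "utilization.csv")
        manifest["features"] = "features.csv"
        manifest["utilization"] = "utilization.csv"
        report.features = features
        for m in FIT_METHODS:
            for par in ("f_p", "D_p", "D_t"):
                sel = util[(util.method_tag == m) & (util.parameter == par)]
                pct = 100 * sel.n_used.sum() / sel.n_voxels.sum()
                log.info("utilization %-6s %-4s %.2f%%", m, par, pct)
        log.info("fit+radiomics: %.1f s", time.time() - t0)

        stage = "agreement"
        summaries, records = agr.agreement_study(features)
        _write(agr.summaries_frame(summaries), out / "agreement_summary.csv")
        _write(agr.pairs_frame(records), out / "agreement_pairs.csv")
        manifest["agreement_summary"] = "agreement_summary.csv"
        manifest["agreement_pairs"] = "agreement_pairs.csv"
        report.agreement_summaries = summaries

        stage = "diagnostics"
        t0 = time.time()
        dsum = diag.diagnostic_study(features, shared_slope=config.shared_slope)
        auc_df, rank_df, p_df = diag.summary_frames(dsum)
        _write(auc_df, out / "auc_table.csv")
        _write(rank_df, out / "auc_summary.csv")
        _write(p_df, out / "delong_pvalues.csv")
        manifest["auc_table"] = "auc_table.csv"
        manifest["auc_summary"] = "auc_summary.csv"
        manifest["delong_pvalues"] = "delong_pvalues.csv"
        report.diagnostic_summaries = dsum
        log.info("diagnostics: %.1f s", time.time() - t0)

        stage = "report"
        (out / "report.md").write_text(render_report(report))
        manifest["report"] = "report.md"
    except Exception:
        report.failed_stage = stage
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    manifest["manifest"] = "manifest.json"
    return report


def render_report(report: StudyReport) -> str:
    """Human-readable markdown summary of a completed run.

    Parameter means are displayed in the field's customary units:
    f_p in %, D_p and D_t in 10⁻³ mm²/s.
    """
    cfg = report.config
    feats = report.features
    if feats is None:
        feats = pd.read_csv(report.path("features"))
    util = pd.read_csv(report.path("utilization"))
    lines = [
        "# Multi-software IVIM radiomics study",
        "",
        f"- config hash: `{cfg.config_hash()}`  seed: {cfg.seed}",
        f"- patients: {feats.patient_id.nunique()}  methods: {', '.join(FIT_METHODS)}",
        "",
        "## Mean ROI parameters by site, class and method",
        "",
        "f_p in %; D_p and D_t in 1e-3 mm²/s.",
        "",
        "| site | class | method | f_p | D_p | D_t |",
        "|---|---|---|---|---|---|",
    ]
    mean_feats = feats[feats.metric_name.isin(["f_p_mean", "D_p_mean", "D_t_mean"])]
    piv = mean_feats.pivot_table(index=["site_tag", "label", "method_tag"],
                                 columns="metric_name", values="value")
    for (site, label, m), row in piv.iterrows():
        lines.append(
            f"| {site} | {label} | {m} | {100 * row.f_p_mean:.2f} "
            f"| {1e3 * row.D_p_mean:.2f} | {1e3 * row.D_t_mean:.2f} |")
    lines += ["", "## Voxel utilization (% of lesion voxels in range)", "",
              "| method | f_p | D_p | D_t |", "|---|---|---|---|"]
    for m in FIT_METHODS:
        cells = []
        for par in ("f_p", "D_p", "D_t"):
            sel = util[(util.method_tag == m) & (util.parameter == par)]
            cells.append(f"{100 * sel.n_used.sum() / sel.n_voxels.sum():.2f}")
        lines.append("| " + " | ".join([m] + cells) + " |")
    lines += ["", "## Metric ranking by cross-software agreement", "",
              "| rank | metric | mean r | CV(r) % |", "|---|---|---|---|"]
    agr_df = pd.read_csv(report.path("agreement_summary"))
    for _, r in agr_df.sort_values("rank").iterrows():
        lines.append(f"| {int(r['rank'])} | {r.metric_name} | {r.mean_r:.3f} "
                     f"| {r.cv_r_pct:.2f} |")
    lines += ["", "## Metric ranking by diagnostic performance", "",
              "| metric | mean AUC | CV(AUC) % | mean LOU AUC | CV(LOU AUC) % |",
              "|---|---|---|---|---|"]
    rank_df = pd.read_csv(report.path("auc_summary"))
    for _, r in rank_df.iterrows():
        lines.append(f"| {r.metric_name} | {r.mean_auc:.3f} | {r.cv_auc_pct:.2f} "
                     f"| {r.mean_lou_auc:.3f} | {r.cv_lou_auc_pct:.2f} |")
    lines.append("")
    return "\n".join(lines)
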