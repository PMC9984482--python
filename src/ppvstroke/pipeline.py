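"""End-to-end analysis: ingest -> validate -> indices -> outcomes -> inference.

:func:`run_pipeline` consumes a cohort CSV and a BP-readings CSV, screens
each patient's series against the sampling policy, computes the PPV index
set, labels outcomes at the requested horizons, and writes the four
report tables a clinical BPV study prints:

* baseline characteristics by outcome group with Mann-Whitney p-values;
* Spearman correlations of each index with the mRS score, by
  thrombolysis subgroup;
* logistic models M1-M4 per index and horizon (OR per 10 mmHg, Wald CI);
* ROC analysis per index and horizon (AUC, DeLong CI, cut-off, Youden J).

Each table is written twice: machine form (full precision CSV) and
display form (rounded to the conventional one/three decimals). An
exclusion-count file accounts for every input patient, and a run log
records the package version, config hash and per-model convergence. The
default path is free of randomness, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_indices import (
    INDEX_NAMES,
    SamplingPolicy,
    derive_pulse_pressure,
    load_bp_readings,
    summarize_ppv,
    validate_sampling,
)
from .inference import MODEL_IDS, mann_whitney_u, roc_analysis, run_model_suite, spearman_rho

logger = logging.getLogger("ppvstroke")

#: indices entered into correlation / model / ROC tables (mean PP is kept
#: as a covariate and correlation row, not a variability index)
VARIABILITY_INDICES = ("cv", "sv", "msc", "dmm", "arv", "sd")

BASELINE_VARS = (
    "age", "female", "diabetes", "hypertension", "atrial_fibrillation",
    "heart_failure", "myocardial_infarction", "prior_stroke", "smoking",
    "coronary_heart_disease", "nihss_admission", "thrombolysed",
    "admission_sbp", "admission_dbp", "admission_pp",
)


@dataclass
class AnalysisConfig:
    """Configuration for one pipeline run."""

    cohort_csv: str
    readings_csv: str
    output_dir: str
    policy: SamplingPolicy = field(default_factory=SamplingPolicy)
    horizons: tuple[str, ...] = ("30d", "90d")
    subgroup: str = "all"  # all | thrombolysed | non_thrombolysed
    indices: tuple[str, ...] = VARIABILITY_INDICES
    models: tuple[str, ...] = MODEL_IDS
    alpha: float = 0.05
    seed: int = 0
    figures: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.horizons or not self.indices:
            raise ValueError("need at least one horizon and one index")
        if self.subgroup not in ("all", "thrombolysed", "non_thrombolysed"):
            raise ValueError(f"unknown subgroup {self.subgroup!r}")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "policy" in raw and isinstance(raw["policy"], dict):
            raw["policy"] = SamplingPolicy(**raw["policy"])
        for key in ("horizons", "indices", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def attach_indices(cohort: pd.DataFrame, series: dict, policy: SamplingPolicy):
    """Screen series, compute PPV indices, and merge them onto the cohort.

    Returns (analyzed cohort, exclusion counts dict). Patients failing the
    sampling policy or lacking any BP series are excluded with a counted
    reason; patients lacking follow-up mRS at every horizon are excluded
    as missing_followup.
    """
    excl = {"too_few_readings": 0, "gap_too_large": 0, "no_series": 0, "missing_followup": 0}
    idx_rows = {}
    for pid in cohort["patient_id"]:
        s = series.get(str(pid))
        if s is None or len(s) == 0:
            excl["no_series"] += 1
            continue
        verdict = validate_sampling(s, policy)
        if not verdict:
            excl[verdict.reason] += 1
            continue
        idx_rows[str(pid)] = summarize_ppv(derive_pulse_pressure(s)).as_dict() | {
            "n_readings": len(s)
        }
    idx_df = pd.DataFrame.from_dict(idx_rows, orient="index")
    keep = cohort["patient_id"].astype(str).isin(idx_df.index)
    analyzed = cohort.loc[keep].copy()
    no_follow = analyzed["mrs_30d"].isna() & analyzed["mrs_90d"].isna()
    excl["missing_followup"] = int(no_follow.sum())
    analyzed = analyzed.loc[~no_follow]
    drop_cols = [c for c in idx_df.columns if c in analyzed.columns]
    analyzed = analyzed.drop(columns=drop_cols).merge(
        idx_df, left_on="patient_id", right_index=True
    )
    return analyzed.reset_index(drop=True), excl


def _fmt(x, nd):
    return "" if pd.isna(x) else f"{x:.{nd}f}"


def baseline_table(cohort: pd.DataFrame, horizon: str) -> pd.DataFrame:
    """Baseline characteristics by dichotomized outcome with U-test p.

    The group-comparison p-value is the Mann-Whitney U test for every
    variable, binary flags included (a rank test on 0/1 data reduces to a
    proportion comparison); that is the convention of the report style
    this table mirrors.
    """
    unfav = cohort[f"mrs_{horizon}"] >= 3
    rows = []
    for var in BASELINE_VARS:
        if var not in cohort.columns:
            continue
        a = cohort.loc[~unfav, var].dropna()
        b = cohort.loc[unfav, var].dropna()
        try:
            _, p = mann_whitney_u(a, b)
        except ValueError:
            p = np.nan
        rows.append(
            {
                "variable": var,
                "favorable_mean": a.mean(),
                "favorable_sd": a.std(ddof=1),
                "unfavorable_mean": b.mean(),
                "unfavorable_sd": b.std(ddof=1),
                "n_favorable": len(a),
                "n_unfavorable": len(b),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(cohort: pd.DataFrame, horizons) -> pd.DataFrame:
    """Spearman rho of each index (and mean PP) with the mRS score, per
    thrombolysis subgroup and overall, plus a U test comparing the index
    between treated and untreated patients."""
    groups = {
        "thrombolysis": cohort[cohort["thrombolysed"] == 1],
        "non_thrombolysis": cohort[cohort["thrombolysed"] == 0],
        "all": cohort,
    }
    rows = []
    for index in (*VARIABILITY_INDICES, "mean_pp"):
        row: dict = {"index": index}
        for gname, g in groups.items():
            row[f"{gname}_n"] = len(g)
            row[f"{gname}_mean"] = g[index].mean()
            row[f"{gname}_sd"] = g[index].std(ddof=1)
            for h in horizons:
                mask = g[f"mrs_{h}"].notna()
                try:
                    rho, p = spearman_rho(g.loc[mask, index], g.loc[mask, f"mrs_{h}"])
                except ValueError:
                    rho, p = np.nan, np.nan
                row[f"{gname}_rho_{h}"] = rho
                row[f"{gname}_p_{h}"] = p
        a = groups["thrombolysis"][index].dropna()
        b = groups["non_thrombolysis"][index].dropna()
        try:
            _, row["u_test_p"] = mann_whitney_u(a, b)
        except ValueError:
            row["u_test_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def model_table(cohort: pd.DataFrame, horizons, indices, models) -> pd.DataFrame:
    rows = []
    for h in horizons:
        for index in indices:
            for res in run_model_suite(cohort, index, h):
                if res.model_id not in models:
                    continue
                rows.append(
                    {
                        "horizon": h,
                        "index": index,
                        "model": res.model_id,
                        "or_per_10mmHg": res.or_per_10mmHg,
                        "ci_low": res.ci95[0],
                        "ci_high": res.ci95[1],
                        "p_value": res.p_value,
                        "n_used": res.n_used,
                        "converged": res.converged,
                        "error": res.error or "",
                    }
                )
    cols = ["horizon", "index", "model", "or_per_10mmHg", "ci_low", "ci_high",
            "p_value", "n_used", "converged", "error"]
    return pd.DataFrame(rows, columns=cols)


def roc_table(cohort: pd.DataFrame, horizons, indices) -> pd.DataFrame:
    rows = []
    for h in horizons:
        unfav = (cohort[f"mrs_{h}"] >= 3).astype(float)
        mask = cohort[f"mrs_{h}"].notna()
        for index in indices:
            try:
                r = roc_analysis(cohort.loc[mask, index], unfav[mask])
                rows.append(
                    {
                        "horizon": h,
                        "index": index,
                        "auc": r.auc,
                        "auc_ci_low": r.auc_ci95[0],
                        "auc_ci_high": r.auc_ci95[1],
                        "cutoff": r.cutoff,
                        "youden_index": r.youden_index,
                        "p_value": r.p_value,
                    }
                )
            except ValueError as exc:
                rows.append({"horizon": h, "index": index, "error": str(exc)})
    cols = ["horizon", "index", "auc", "auc_ci_low", "auc_ci_high", "cutoff",
            "youden_index", "p_value", "error"]
    return pd.DataFrame(rows, columns=cols)


_DISPLAY_DECIMALS = {
    "or_per_10mmHg": 3, "ci_low": 3, "ci_high": 3, "p_value": 3,
    "auc": 3, "auc_ci_low": 3, "auc_ci_high": 3, "youden_index": 2,
    "cutoff": 0,
}


def _write_pair(df: pd.DataFrame, outdir: Path, stem: str) -> None:
    df.to_csv(outdir / f"{stem}.csv", index=False)
    disp = df.copy()
    for col in disp.columns:
        if disp[col].dtype.kind == "f":
            nd = _DISPLAY_DECIMALS.get(col, 1 if disp[col].abs().max() > 1 else 3)
            disp[col] = disp[col].map(lambda v: _fmt(v, nd))
    disp.to_csv(outdir / f"{stem}_display.csv", index=False)


def _roc_figure(cohort, horizon, indices, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    unfav = (cohort[f"mrs_{horizon}"] >= 3).astype(float).to_numpy()
    for index in indices:
        scores = cohort[index].to_numpy()
        ts = np.sort(np.unique(scores))[::-1]
        sens = [np.mean(scores[unfav == 1] >= t) for t in ts]
        fpr = [np.mean(scores[unfav == 0] >= t) for t in ts]
        ax.plot([0] + fpr + [1], [0] + sens + [1], label=index.upper())
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC, unfavorable outcome at {horizon}")
    ax.legend(fontsize=8)
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def run_pipeline(config: AnalysisConfig) -> dict[str, Path]:
    """Run the full analysis; returns a dict of written report paths."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = pd.read_csv(config.cohort_csv, dtype={"patient_id": str})
    series = load_bp_readings(config.readings_csv)
    n_in = len(cohort)
    analyzed, excl = attach_indices(cohort, series, config.policy)
    if analyzed.empty:
        raise RuntimeError("no patient passed the sampling policy")

    n_valid = len(analyzed)
    if config.subgroup == "thrombolysed":
        analyzed = analyzed[analyzed["thrombolysed"] == 1]
    elif config.subgroup == "non_thrombolysed":
        analyzed = analyzed[analyzed["thrombolysed"] == 0]
    excl["outside_subgroup"] = n_valid - len(analyzed)
    if len(analyzed) < 2:
        raise RuntimeError(f"fewer than 2 valid patients in subgroup {config.subgroup!r}")

    paths: dict[str, Path] = {}
    convergence: dict[str, bool] = {}
    skipped: list[str] = []

    for h in config.horizons:
        out_col = analyzed[f"mrs_{h}"]
        if out_col.notna().sum() and (out_col >= 3).nunique() == 1:
            logger.warning("single-class outcome at %s in subgroup %s: models skipped",
                           h, config.subgroup)
            skipped.append(h)

    _write_pair(pd.concat(
        [baseline_table(analyzed, h).assign(horizon=h) for h in config.horizons],
        ignore_index=True), outdir, "table1_baseline")
    _write_pair(correlation_table(analyzed, config.horizons), outdir, "table2_correlations")

    model_horizons = [h for h in config.horizons if h not in skipped]
    mt = model_table(analyzed, model_horizons, config.indices, config.models)
    _write_pair(mt, outdir, "table3_models")
    for _, r in mt.iterrows():
        convergence[f"{r['horizon']}:{r['index']}:{r['model']}"] = bool(r["converged"])
    _write_pair(roc_table(analyzed, model_horizons, config.indices), outdir, "table4_roc")

    if config.figures:
        for h in model_horizons:
            fp = outdir / f"roc_{h}.svg"
            _roc_figure(analyzed, h, config.indices, fp)
            paths[f"roc_figure_{h}"] = fp

    excl_record = {
        "patients_in": n_in,
        "patients_analyzed": len(analyzed),
        "exclusions": excl,
        "subgroup": config.subgroup,
    }
    (outdir / "exclusions.json").write_text(json.dumps(excl_record, indent=2, sort_keys=True))
    run_log = {
        "package_version": __version__,
        "config_hash": config.hash(),
        "config": config.resolved(),
        "model_convergence": convergence,
        "horizons_skipped": skipped,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True, default=str))

    for stem in ("table1_baseline", "table2_correlations", "table3_models", "table4_roc"):
        paths[stem] = outdir / f"{stem}.csv"
        paths[stem + "_display"] = outdir / f"{stem}_display.csv"
    paths["exclusions"] = outdir / "exclusions.json"
    paths["run_log"] = outdir / "run_log.json"
    return paths
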