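"""End-to-end pipeline: simulate -> build -> metrics -> adjust -> stats -> predict.

``run_pipeline`` chains every stage on a simulated (or loaded) cohort and
writes all intermediate tables, a manifest with configuration hash and
seeds, and JSON summaries.  ``analyze_cohort`` is the in-memory core shared
by the command-line interface, the test-suite and the acceptance script.

All randomness flows from one master seed through named substreams, so a
rerun with the same configuration reproduces every numeric output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .confounds import regress_out_sa, residualize, screen_network_size_effects
from .connectome import build_highres_connectome
from .metrics import (GLOBAL_HIGH, GLOBAL_LOW, METRIC_NAMES, MetricSettings,
                      MetricTable, build_lowres_nodal_table, build_metric_table)
from .predict import (combine_predictors, confusion_summary,
                      crossval_single_feature, select_outcome_predictors)
from .stats import (abnormality_distance, cohens_d, count_changed_regions,
                    duration_association, effects_dataframe, match_controls,
                    permutation_test, region_effects, zscore_table)
from .synthetic import CohortConfig, cohort_dataframe, generate_cohort

__all__ = [
    "PipelineConfig",
    "CohortAnalysis",
    "analyze_cohort",
    "run_pipeline",
    "duration_region_labels",
    "outcome_region_labels",
]


@dataclass
class PipelineConfig:
    """All knobs of the full pipeline, serializable to/from YAML."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    metrics: MetricSettings = field(default_factory=MetricSettings)
    n_perm: int = 1000              # permutation count for group tests
    duration_split_years: float = 20.0
    alpha: float = 0.05
    d_thresholds: tuple[float, float] = (0.5, 1.2)
    cv_folds: int = 5
    cv_repeats: int = 50
    selection_d_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.d_thresholds = tuple(self.d_thresholds)
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        if isinstance(self.metrics, dict):
            self.metrics = MetricSettings(**self.metrics)
        if self.n_perm < 1 or self.cv_folds < 2 or self.cv_repeats < 1:
            raise ValueError("invalid pipeline configuration")
        if self.duration_split_years <= 0 or self.alpha <= 0:
            raise ValueError("invalid pipeline configuration")

    def to_dict(self) -> dict:
        # JSON round-trip normalizes tuples to lists for YAML portability
        return json.loads(json.dumps(asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def duration_region_labels(cfg: CohortConfig) -> list[str]:
    """Lateralized labels of the planted duration-related (ipsi) regions."""
    return [f"ipsi_{j:02d}" for j in range(cfg.n_duration_regions)]


def outcome_region_labels(cfg: CohortConfig) -> list[str]:
    """Lateralized labels of the planted outcome-related (contra) regions."""
    return [f"contra_{j:02d}" for j in range(cfg.n_outcome_regions)]


@dataclass
class CohortAnalysis:
    """Bundle of every stage's outputs for one cohort."""

    cohort: pd.DataFrame
    metric_table: MetricTable
    corrected_table: MetricTable
    lowres_table: MetricTable | None
    lowres_corrected: MetricTable | None
    screen: object
    retained_metrics: list[str]
    z: pd.DataFrame
    z_lowres: pd.DataFrame | None
    effects: list
    duration: dict
    outcome: dict


def _within_region_labels(table: MetricTable) -> list[str]:
    return [r for r in table.data.region.unique()
            if r not in (GLOBAL_HIGH, GLOBAL_LOW)]


def correct_and_screen(table: MetricTable, cohort: pd.DataFrame,
                       alpha: float = 0.05, sa: bool = True):
    """Age/sex (+ SA) residualization followed by network-size screening.

    Screening here centers values and node counts per region first: the
    between-region metric profile is expected to vary with region size,
    but only the within-region covariation of a subject's metric with its
    network size can confound the per-region group comparisons downstream.
    """
    corrected, _ = residualize(table, cohort, ["age", "sex"])
    if sa and (corrected.data.metric == "SA").any():
        corrected, _ = regress_out_sa(corrected, cohort)
    within = _within_region_labels(table)
    screen = screen_network_size_effects(corrected.subset(regions=within),
                                         cohort, alpha=alpha,
                                         center_regions=True)
    metrics = sorted(table.data.metric.unique())
    retained = [m for m in metrics if m not in screen.excluded_metrics]
    return corrected, screen, retained


def analyze_duration(z: pd.DataFrame, cohort: pd.DataFrame,
                     region_labels: list[str], metric_labels: list[str],
                     split_years: float = 20.0, n_perm: int = 1000,
                     seed: int = 0) -> dict:
    """Distance-vs-duration association and the distance effect size.

    Distance = per-subject summed |z| over the duration-related regions and
    the retained metrics.  The patient distances are correlated with
    disease duration; the patient-vs-control distance contrast is the
    permutation test and Cohen's d of the two distance distributions.
    """
    cohort_ix = cohort.set_index("id") if "id" in cohort.columns else cohort
    dist = abnormality_distance(z, region_labels, metric_labels)
    patients = cohort_ix[cohort_ix.group == "patient"]
    controls = cohort_ix[cohort_ix.group == "control"]
    pd_dist = dist.reindex(patients.index).dropna()
    ctrl_dist = dist.reindex(controls.index).dropna()
    assoc = duration_association(pd_dist.to_numpy(),
                                 patients.loc[pd_dist.index, "duration"])
    d = cohens_d(pd_dist.to_numpy(), ctrl_dist.to_numpy())
    p = permutation_test(pd_dist.to_numpy(), ctrl_dist.to_numpy(),
                         n_perm=n_perm, seed=seed)
    return {"distances": dist, "association": assoc,
            "patient_control_d": d, "patient_control_p": p,
            "split_years": split_years}


def duration_group_counts(table: MetricTable, cohort: pd.DataFrame,
                          metric_labels: list[str],
                          split_years: float = 20.0,
                          d_thresholds=(0.5, 1.2), n_perm: int = 1000,
                          seed: int = 0) -> dict:
    """Changed-region counts for the short/long-duration patient groups.

    Each duration subgroup is compared to its own age/sex-matched control
    subset (the two control subsets maximally overlap); a region counts as
    changed when any retained metric reaches p < 0.05 and |weighted d|
    above the threshold.
    """
    cohort_ix = cohort.set_index("id") if "id" in cohort.columns else cohort
    patients = cohort_ix[cohort_ix.group == "patient"]
    within = _within_region_labels(table)
    sub = table.subset(regions=within, metrics=metric_labels)
    out = {}
    for name, mask in (("short", patients.duration <= split_years),
                       ("long", patients.duration > split_years)):
        ids = list(patients.index[mask])
        ctrl = match_controls(cohort_ix, ids, seed=seed)
        eff = region_effects(sub, cohort_ix, patient_ids=ids,
                             control_ids=ctrl, n_perm=n_perm, seed=seed)
        out[name] = {
            "n": len(ids),
            "counts": {thr: count_changed_regions(eff, thr, 0.05)
                       for thr in d_thresholds},
            "effects": eff,
        }
    return out


def analyze_outcome(z: pd.DataFrame, z_lowres: pd.DataFrame | None,
                    cohort: pd.DataFrame, metric_labels: list[str],
                    cfg: PipelineConfig, seed: int = 0) -> dict:
    """Combined-predictor outcome classification, high- vs low-resolution.

    Features are |z| values of patients; the combined predictor is the
    summed |z| over the features that separate good from bad outcome
    (selection on the full data, as in the source protocol).  When no
    feature passes selection the combined predictor falls back to all
    features, which yields chance-level performance by construction.
    """
    cohort_ix = cohort.set_index("id") if "id" in cohort.columns else cohort
    patients = cohort_ix[cohort_ix.group == "patient"]
    pids = list(patients.index)
    labels = (patients.outcome <= 2).to_numpy()

    def combined_result(ztab, metrics, tag, include_sa=False):
        zz = ztab[ztab.region.isin(_within_region_labels_from_z(ztab))]
        feats = select_outcome_predictors(
            zz, cohort_ix, alpha=cfg.alpha,
            d_threshold=cfg.selection_d_threshold, n_perm=cfg.n_perm,
            seed=seed, metrics=metrics)
        fallback = not feats
        if fallback:
            feats = sorted({(r, m) for r, m in
                            zip(zz.region, zz.metric) if m in metrics})
        if include_sa:
            feats = feats + sorted({(r, "SA") for r, _ in feats})
        feature = combine_predictors(zz, feats, subjects=pids).fillna(0.0)
        res = crossval_single_feature(feature.to_numpy(), labels, family="DM",
                                      k=cfg.cv_folds, n_repeats=cfg.cv_repeats,
                                      seed=seed)
        res.feature = tag
        conf = confusion_summary(res.per_repeat_confusion,
                                 int(labels.sum()), int((~labels).sum()))
        return {"result": res, "confusion": conf, "predictors": feats,
                "selection_fallback": fallback}

    within_metrics = [m for m in metric_labels if m != "SA"]
    out = {"highres": combined_result(z, within_metrics, "ALL"),
           "highres_sa": combined_result(z, within_metrics, "ALL+SA",
                                         include_sa=True)}
    if z_lowres is not None and len(z_lowres):
        out["lowres"] = combined_result(
            z_lowres, sorted(z_lowres.metric.unique()), "ALL_LOW")
    return out


def _within_region_labels_from_z(z: pd.DataFrame) -> list[str]:
    return [r for r in z.region.unique() if r not in (GLOBAL_HIGH, GLOBAL_LOW)]


def analyze_cohort(subjects, truth, cfg: PipelineConfig,
                   compute_lowres: bool = True,
                   compute_outcome: bool = True) -> CohortAnalysis:
    """Run the whole analysis on an in-memory cohort."""
    cohort = cohort_dataframe(subjects)
    table = build_metric_table(subjects, cfg.metrics, include_global=True,
                               lateralized=True)
    corrected, screen, retained = correct_and_screen(table, cohort,
                                                     alpha=cfg.alpha)
    z = zscore_table(corrected.subset(
        regions=_within_region_labels(table), metrics=retained), cohort)

    lowres = lowres_corr = None
    z_low = None
    if compute_lowres:
        lowres = build_lowres_nodal_table(subjects, cfg.metrics,
                                          lateralized=True)
        lowres_corr, _ = residualize(lowres, cohort, ["age", "sex"])
        z_low = zscore_table(lowres_corr, cohort)

    within = _within_region_labels(table)
    effects = region_effects(
        corrected.subset(regions=within, metrics=retained), cohort,
        n_perm=cfg.n_perm, seed=cfg.seed)

    dur_regions = duration_region_labels(cfg.cohort)
    duration = analyze_duration(z, cohort, dur_regions, retained,
                                cfg.duration_split_years, cfg.n_perm,
                                seed=cfg.seed)
    duration["group_counts"] = duration_group_counts(
        corrected, cohort, retained, cfg.duration_split_years,
        cfg.d_thresholds, cfg.n_perm, seed=cfg.seed)

    outcome = {}
    if compute_outcome:
        outcome = analyze_outcome(z, z_low, cohort, retained, cfg,
                                  seed=cfg.seed)

    return CohortAnalysis(
        cohort=cohort, metric_table=table, corrected_table=corrected,
        lowres_table=lowres, lowres_corrected=lowres_corr, screen=screen,
        retained_metrics=retained, z=z, z_lowres=z_low, effects=effects,
        duration=duration, outcome=outcome)


# ---------------------------------------------------------------------------
# Disk-level pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir, simulate: bool = True,
                 subjects=None, truth=None) -> dict:
    """Execute all stages, writing outputs and a manifest to ``outdir``."""
    from . import io as iomod
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = iomod.config_hash(cfg.to_dict())
    stage = "init"
    try:
        stage = "simulate"
        if simulate:
            subjects, truth = generate_cohort(cfg.cohort, seed=cfg.seed)
        if subjects is None:
            raise ValueError("no cohort: pass simulate=True or subjects")
        iomod.write_cohort_csv(subjects, outdir / "cohort.csv",
                               stage=stage, seed=cfg.seed)
        if truth is not None:
            iomod.write_ground_truth(truth, outdir / "ground_truth.json")

        stage = "analysis"
        analysis = analyze_cohort(subjects, truth, cfg)
        iomod.write_metric_table(analysis.metric_table,
                                 outdir / "metrics.tsv", stage="metrics",
                                 seed=cfg.seed, cfg_hash=chash)
        iomod.write_metric_table(analysis.corrected_table,
                                 outdir / "metrics_corrected.tsv",
                                 stage="adjust", seed=cfg.seed,
                                 cfg_hash=chash)
        analysis.screen.table.to_csv(outdir / "size_screen.tsv", sep="\t",
                                     index=False)
        effects_dataframe(analysis.effects).to_csv(
            outdir / "group_effects.tsv", sep="\t", index=False)

        stage = "summaries"
        assoc = analysis.duration["association"]
        counts = analysis.duration["group_counts"]
        summary = {
            "duration": {
                "pearson_r": assoc.pearson_r, "pearson_p": assoc.pearson_p,
                "spearman_rho": assoc.spearman_rho,
                "spearman_p": assoc.spearman_p, "n": assoc.n,
                "patient_control_d": analysis.duration["patient_control_d"],
                "patient_control_p": analysis.duration["patient_control_p"],
                "changed_regions": {
                    name: {str(k): v for k, v in info["counts"].items()}
                    for name, info in counts.items()},
            },
            "retained_metrics": analysis.retained_metrics,
            "excluded_metrics": analysis.screen.excluded_metrics,
        }
        for tag, block in analysis.outcome.items():
            res, conf = block["result"], block["confusion"]
            summary.setdefault("outcome", {})[tag] = {
                "auc": [res.auc_mean, res.auc_sd],
                "accuracy": [res.accuracy_mean, res.accuracy_sd],
                "sensitivity": [res.sensitivity_mean, res.sensitivity_sd],
                "specificity": [res.specificity_mean, res.specificity_sd],
                "confusion": {"TP": conf.tp_mean, "FN": conf.fn_mean,
                              "FP": conf.fp_mean, "TN": conf.tn_mean},
                "n_predictors": len(block["predictors"]),
            }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))

        manifest = {"version": __version__, "config": cfg.to_dict(),
                    "config_hash": chash, "seed": cfg.seed,
                    "stages": ["simulate", "analysis", "summaries"]}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str))
        return {"outdir": str(outdir), "summary": summary,
                "analysis": analysis}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
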