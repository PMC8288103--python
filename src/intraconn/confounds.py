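"""Confound control: covariate residualization and network-size screening.

Age and sex effects are removed with an ordinary-least-squares model fitted
on healthy controls only and applied to everyone, preserving the control
grand mean so that downstream z-scores stay interpretable:

    corrected = observed - (predicted - control mean)

Surface-area effects are removed the same way, per region, using that
region's SA as the covariate (after the age/sex pass).  Metrics whose
values track network size (node count) across control within-region
networks — Spearman rank correlation, Bonferroni-corrected — are flagged
and excluded from group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import MetricTable

__all__ = [
    "CovariateModel",
    "SizeScreenReport",
    "residualize",
    "regress_out_sa",
    "screen_network_size_effects",
]


@dataclass
class CovariateModel:
    """Fitted control-only OLS coefficients per (region, metric) cell."""

    covariates: list[str]
    coefficients: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    control_means: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class SizeScreenReport:
    """Per-metric Spearman rho against node count, with exclusion flags."""

    table: pd.DataFrame          # metric, rho, p, p_corrected, excluded
    alpha: float

    @property
    def excluded_metrics(self) -> list[str]:
        return list(self.table.loc[self.table.excluded, "metric"])


def _design_matrix(df: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in covariates:
        if c == "sex":
            cols.append((df["sex"] == "M").astype(float).to_numpy())  # F=0, M=1
        else:
            cols.append(df[c].astype(float).to_numpy())
    return np.column_stack(cols)


def residualize(table: MetricTable, cohort: pd.DataFrame,
                covariates: list[str] = ["age", "sex"],
                ) -> tuple[MetricTable, CovariateModel]:
    """Remove covariate effects using a control-only OLS fit per cell.

    ``cohort`` must have columns ``id``, ``group`` and the covariates.
    Every subject (controls and patients) is corrected by the deviation of
    its prediction from the control grand mean.  Cells with missing values
    keep them missing; a rank-deficient control design is rejected.
    """
    cohort = cohort.set_index("id") if "id" in cohort.columns else cohort
    control_ids = set(cohort.index[cohort.group == "control"])
    if len(control_ids) < 3:
        raise ValueError("need at least 3 controls to fit covariate models")

    data = table.data.merge(
        cohort[[c for c in ("age", "sex") if c in cohort.columns]],
        left_on="subject", right_index=True, how="left")
    model = CovariateModel(covariates=list(covariates))
    out_values = data.value.to_numpy().copy()
    is_control = data.subject.isin(control_ids).to_numpy()

    for (region, metric), idx in data.groupby(["region", "metric"]).groups.items():
        idx = np.asarray(idx)
        sub = data.loc[idx]
        y = sub.value.to_numpy()
        ctrl = is_control[idx] & ~np.isnan(y)
        if ctrl.sum() < 3:
            continue
        Xc = _design_matrix(sub.loc[idx[ctrl]], covariates)
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            raise ValueError(
                f"rank-deficient covariate design for ({region}, {metric})")
        yc = y[ctrl]
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        Xall = _design_matrix(sub, covariates)
        pred = Xall @ beta
        corrected = y - (pred - yc.mean())
        out_values[idx] = corrected
        model.coefficients[(region, metric)] = beta
        model.control_means[(region, metric)] = float(yc.mean())

    corrected_data = table.data.copy()
    corrected_data["value"] = out_values
    return MetricTable(corrected_data, table.node_counts,
                       {**table.provenance, "covariates": covariates}), model


def regress_out_sa(table: MetricTable, cohort: pd.DataFrame,
                   ) -> tuple[MetricTable, CovariateModel]:
    """Remove each region's surface-area effect from its other metrics.

    The covariate for cell (region, metric != SA) is the subject's SA value
    of that same region; the fit is control-only with control-grand-mean
    centering, as in :func:`residualize`.  SA itself is left untouched.
    """
    cohort = cohort.set_index("id") if "id" in cohort.columns else cohort
    control_ids = set(cohort.index[cohort.group == "control"])
    if len(control_ids) < 3:
        raise ValueError("need at least 3 controls to fit covariate models")

    sa = table.data[table.data.metric == "SA"].set_index(["subject", "region"])["value"]
    data = table.data
    out_values = data.value.to_numpy().copy()
    model = CovariateModel(covariates=["SA"])

    for (region, metric), idx in data.groupby(["region", "metric"]).groups.items():
        if metric == "SA":
            continue
        idx = np.asarray(idx)
        sub = data.loc[idx]
        y = sub.value.to_numpy()
        try:
            x = sa.loc[list(zip(sub.subject, sub.region))].to_numpy()
        except KeyError:
            continue
        ctrl = sub.subject.isin(control_ids).to_numpy() & ~np.isnan(y) & ~np.isnan(x)
        if ctrl.sum() < 3 or np.std(x[ctrl]) == 0:
            continue
        X = np.column_stack([np.ones(ctrl.sum()), x[ctrl]])
        beta, *_ = np.linalg.lstsq(X, y[ctrl], rcond=None)
        pred = beta[0] + beta[1] * x
        out_values[idx] = y - (pred - y[ctrl].mean())
        model.coefficients[(region, metric)] = beta
        model.control_means[(region, metric)] = float(y[ctrl].mean())

    corrected = table.data.copy()
    corrected["value"] = out_values
    return MetricTable(corrected, table.node_counts,
                       {**table.provenance, "sa_corrected": True}), model


def screen_network_size_effects(table: MetricTable, cohort: pd.DataFrame,
                                alpha: float = 0.05,
                                node_counts: dict[str, int] | None = None,
                                center_regions: bool = False,
                                ) -> SizeScreenReport:
    """Flag metrics correlated with network size across control regions.

    For each metric, all (control subject, region) values are pooled and
    Spearman-rank-correlated against the region node counts; metrics with
    Bonferroni-corrected p < alpha (family = number of metrics screened)
    are flagged ``excluded``.  Constant metrics have undefined rho and are
    flagged but never excluded.

    ``center_regions=True`` removes each region's control mean from both
    the metric and the node count before pooling, so the correlation
    captures only the *within-region* covariation with size — the
    component that can confound per-region group comparisons — rather than
    the between-region metric profile.  ``node_counts`` may then map
    (subject, region) pairs to per-subject counts; a plain region map
    yields zero within-region size variance and an undefined rho.
    """
    cohort = cohort.set_index("id") if "id" in cohort.columns else cohort
    control_ids = set(cohort.index[cohort.group == "control"])
    if not control_ids:
        raise ValueError("control subjects required for size screening")
    counts = node_counts or table.node_counts
    data = table.data[table.data.subject.isin(control_ids)
                      & table.data.region.isin(
                          {k[1] if isinstance(k, tuple) else k for k in counts})]
    metrics = sorted(data.metric.unique())
    m = len(metrics)
    rows = []
    for metric in metrics:
        sub = data[data.metric == metric].dropna(subset=["value"])
        per_subject = any(isinstance(k, tuple) for k in counts)
        if per_subject:
            x = np.array([counts.get((s, r), np.nan)
                          for s, r in zip(sub.subject, sub.region)], dtype=float)
        else:
            x = np.array([counts[r] for r in sub.region], dtype=float)
        y = sub.value.to_numpy()
        ok = ~np.isnan(x)
        x, y = x[ok], y[ok]
        regions = sub.region.to_numpy()[ok]
        if center_regions and len(y):
            for r in np.unique(regions):
                sel = regions == r
                x[sel] -= x[sel].mean()
                y[sel] -= y[sel].mean()
        if len(y) < 3 or np.all(y == y[0]) or np.all(x == x[0]):
            rows.append((metric, np.nan, np.nan, np.nan, False, True))
            continue
        rho, p = sps.spearmanr(x, y)
        p_corr = min(1.0, p * m)
        rows.append((metric, rho, p, p_corr, bool(p_corr < alpha), False))
    report = pd.DataFrame(rows, columns=["metric", "rho", "p", "p_corrected",
                                         "excluded", "undefined"])
    return SizeScreenReport(report, alpha)
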