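"""Group statistics: permutation tests, effect sizes, z-score distances.

The statistical core of the analysis:

* two-sided permutation test on the absolute mean difference (default
  5,000 permutations, add-one p-value estimator so p is never exactly 0);
* Cohen's d with pooled (n-1) standard deviation, and the sample-size
  weighted combination ``(n1*d1 + n2*d2) / (n1 + n2)`` of the left-surgery
  and right-surgery patient effects;
* effect-size bins (huge / very large / large / medium / small /
  very small / negligible at |d| thresholds 2.0, 1.2, 0.8, 0.5, 0.2, 0.01);
* Bonferroni correction;
* control-referenced z-score tables and the per-subject abnormality
  distance (summed |z| over a region/metric set);
* Pearson and Spearman duration associations;
* changed-region counts at (p, |d_weighted|) thresholds;
* the 2x2 Pearson chi-square (no continuity correction) used for the
  demographics table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import MetricTable

__all__ = [
    "EffectResult",
    "AssociationResult",
    "permutation_test",
    "cohens_d",
    "weighted_cohens_d",
    "effect_size_label",
    "bonferroni_correct",
    "zscore_table",
    "abnormality_distance",
    "duration_association",
    "count_changed_regions",
    "chi_square_2x2",
    "region_effects",
    "match_controls",
]

EFFECT_BINS = [(2.0, "huge"), (1.2, "very large"), (0.8, "large"),
               (0.5, "medium"), (0.2, "small"), (0.01, "very small")]


@dataclass
class EffectResult:
    """Per-feature group effect: side-specific and weighted Cohen's d."""

    region: str
    metric: str
    d1: float            # left-surgery patients vs controls
    d2: float            # right-surgery patients vs controls
    n1: int
    n2: int
    d_weighted: float
    p: float
    p_corrected: float = np.nan

    @property
    def bin(self) -> str:
        return effect_size_label(self.d_weighted)


@dataclass
class AssociationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def permutation_test(x, y, n_perm: int = 5000, seed: int = 0) -> float:
    """Two-sided label-permutation p for the absolute mean difference.

    p = (b + 1) / (n_perm + 1) where b counts permuted |mean(x) - mean(y)|
    >= the observed one (add-one estimator, never exactly zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = abs(x.mean() - y.mean())
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    rng = np.random.default_rng(seed)
    # vectorized permutations in blocks to bound memory
    b = 0
    block = max(1, min(n_perm, 2_000_000 // max(n, 1)))
    done = 0
    total = pooled.sum()
    while done < n_perm:
        m = min(block, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)[:, :nx]
        sx = pooled[idx].sum(axis=1)
        stat = np.abs(sx / nx - (total - sx) / (n - nx))
        b += int((stat >= observed - 1e-12).sum())
        done += m
    return (b + 1) / (n_perm + 1)


def cohens_d(x, y) -> float:
    """(mean(x) - mean(y)) / pooled SD, pooled with n-1 variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    nx, ny = len(x), len(y)
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) \
        / (nx + ny - 2)
    if pooled_var == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValueError("pooled SD is zero with unequal means")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def weighted_cohens_d(d1: float, n1: int, d2: float, n2: int) -> float:
    """Sample-size weighted combination (n1*d1 + n2*d2) / (n1 + n2)."""
    if n1 + n2 <= 0:
        raise ValueError("n1 + n2 must be positive")
    return (n1 * d1 + n2 * d2) / (n1 + n2)


def effect_size_label(d: float) -> str:
    """Bin |d| at thresholds 2.0/1.2/0.8/0.5/0.2/0.01 (lower-inclusive)."""
    a = abs(d)
    for threshold, label in EFFECT_BINS:
        if a >= threshold:
            return label
    return "negligible"


def bonferroni_correct(p_values) -> np.ndarray:
    """p * m capped at 1, with m the family size."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# z-scores and distances
# ---------------------------------------------------------------------------

def zscore_table(table: MetricTable, cohort: pd.DataFrame) -> pd.DataFrame:
    """Control-referenced z per (subject, region, metric).

    z = (value - control mean) / control SD (ddof=1).  Cells whose control
    SD is zero or undefined come back as NaN (flagged missing).  Controls
    are scored against their own group statistics, so a control's z shows
    its within-group deviation.
    """
    cohort = cohort.set_index("id") if "id" in cohort.columns else cohort
    control_ids = set(cohort.index[cohort.group == "control"])
    data = table.data
    ctrl = data[data.subject.isin(control_ids)]
    ref = ctrl.groupby(["region", "metric"])["value"].agg(["mean", "std"])
    merged = data.merge(ref, left_on=["region", "metric"], right_index=True,
                        how="left")
    sd = merged["std"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (merged.value.to_numpy() - merged["mean"].to_numpy()) / sd
    z[~np.isfinite(z)] = np.nan
    out = data[["subject", "region", "metric"]].copy()
    out["z"] = z
    out["abs_z"] = np.abs(z)
    return out


def abnormality_distance(z: pd.DataFrame, region_set, metric_set,
                         ) -> pd.Series:
    """Per-subject sum of |z| over the selected region x metric cells.

    Missing cells are skipped; a subject with no usable cell is NaN.
    """
    region_set = list(region_set)
    metric_set = list(metric_set)
    if not region_set or not metric_set:
        raise ValueError("region and metric sets must be non-empty")
    sel = z[z.region.isin(region_set) & z.metric.isin(metric_set)]
    return sel.groupby("subject")["abs_z"].sum(min_count=1)


def duration_association(distances, durations) -> AssociationResult:
    """Pearson and Spearman association between distance and duration."""
    x = np.asarray(distances, dtype=float)
    y = np.asarray(durations, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in distances or durations")
    r, rp = sps.pearsonr(x, y)
    rho, sp_ = sps.spearmanr(x, y)
    return AssociationResult(float(r), float(rp), float(rho), float(sp_),
                             len(x))


# ---------------------------------------------------------------------------
# Cohort-level comparisons
# ---------------------------------------------------------------------------

def match_controls(cohort: pd.DataFrame, patient_ids, seed: int = 0,
                   ) -> list[str]:
    """Age/sex-matched control subset of the same size as the patient group.

    For each patient (in seeded order) the nearest-age unused control of
    the same sex is selected (falling back to any sex once a sex pool is
    exhausted).  Running this for two overlapping patient subgroups yields
    maximally overlapping control groups because the greedy choice is
    deterministic given the seed.
    """
    cohort = cohort.set_index("id") if "id" in cohort.columns else cohort
    controls = cohort[cohort.group == "control"]
    patients = cohort.loc[list(patient_ids)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    available = dict(controls[["age", "sex"]].iterrows())
    chosen: list[str] = []
    for i in order:
        row = patients.iloc[i]
        pool = [(cid, c) for cid, c in available.items() if c.sex == row.sex]
        if not pool:
            pool = list(available.items())
        cid = min(pool, key=lambda t: abs(t[1].age - row.age))[0]
        chosen.append(cid)
        del available[cid]
    return chosen


def region_effects(table: MetricTable, cohort: pd.DataFrame,
                   patient_ids=None, control_ids=None, metrics=None,
                   n_perm: int = 1000, seed: int = 0) -> list[EffectResult]:
    """Per (region, metric) group comparison of patients against controls.

    d1/d2 are Cohen's d of left-/right-surgery patients vs the controls,
    combined into the weighted d; p is the two-sided permutation p of all
    selected patients vs controls; Bonferroni family = all cells tested.
    """
    cohort = cohort.set_index("id") if "id" in cohort.columns else cohort
    if patient_ids is None:
        patient_ids = list(cohort.index[cohort.group == "patient"])
    if control_ids is None:
        control_ids = list(cohort.index[cohort.group == "control"])
    patient_ids = list(patient_ids)
    left = [s for s in patient_ids if cohort.loc[s, "side"] == "L"]
    right = [s for s in patient_ids if cohort.loc[s, "side"] == "R"]
    data = table.data
    if metrics is not None:
        data = data[data.metric.isin(metrics)]
    results: list[EffectResult] = []
    rng = np.random.default_rng(seed)
    for (region, metric), sub in data.groupby(["region", "metric"]):
        vals = sub.set_index("subject")["value"]
        xc = vals.reindex(control_ids).dropna().to_numpy()
        xp = vals.reindex(patient_ids).dropna().to_numpy()
        x1 = vals.reindex(left).dropna().to_numpy()
        x2 = vals.reindex(right).dropna().to_numpy()
        if len(xc) < 2 or len(xp) < 2:
            continue
        try:
            d1 = cohens_d(x1, xc) if len(x1) >= 2 else np.nan
            d2 = cohens_d(x2, xc) if len(x2) >= 2 else np.nan
        except ValueError:
            continue
        if np.isnan(d1) and np.isnan(d2):
            continue
        n1, n2 = len(x1), len(x2)
        if np.isnan(d1):
            dw, n1 = d2, 0
        elif np.isnan(d2):
            dw, n2 = d1, 0
        else:
            dw = weighted_cohens_d(d1, n1, d2, n2)
        p = permutation_test(xp, xc, n_perm=n_perm,
                             seed=int(rng.integers(2 ** 31)))
        results.append(EffectResult(region=str(region), metric=str(metric),
                                    d1=float(d1), d2=float(d2), n1=n1, n2=n2,
                                    d_weighted=float(dw), p=p))
    if results:
        corr = bonferroni_correct([r.p for r in results])
        for r, pc in zip(results, corr):
            r.p_corrected = float(pc)
    return results


def effects_dataframe(effects: list[EffectResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": e.region, "metric": e.metric, "d1": e.d1, "d2": e.d2,
        "n1": e.n1, "n2": e.n2, "d_weighted": e.d_weighted, "p": e.p,
        "p_corrected": e.p_corrected, "bin": e.bin} for e in effects])


def count_changed_regions(effects: list[EffectResult], d_threshold: float,
                          p_threshold: float = 0.05) -> int:
    """Regions with >= 1 metric at p < p_threshold and |d_w| > d_threshold."""
    if d_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    changed = {e.region for e in effects
               if e.p < p_threshold and abs(e.d_weighted) > d_threshold}
    return len(changed)
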