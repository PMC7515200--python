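"""Kaplan-Meier estimation, log-rank comparison, and survival screening.

Patients are stratified into the highest and lowest quartiles of a feature
(TR expression, probe methylation, or link burden subgroups) and their
survival compared with the two-group log-rank test.  The survival screen
applies this per feature and flags features whose hypothesized extreme
group shows significantly worse survival.

Estimation and testing are delegated to lifelines; this module owns the
stratification rules, the directionality check, and the screen logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ClinicalTable, ValidationError


@dataclass
class StratifiedGroups:
    """High/low group assignment for one stratification variable."""

    variable: str
    assignments: pd.Series  # sample -> {"high", "low", "excluded"}
    rule: str = "quartiles"

    @property
    def high(self) -> list[str]:
        return list(self.assignments.index[self.assignments == "high"])

    @property
    def low(self) -> list[str]:
        return list(self.assignments.index[self.assignments == "low"])


@dataclass
class KmCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


@dataclass
class SurvivalComparison:
    curves: dict[str, KmCurve]
    logrank_chi2: float
    logrank_p: float


def quartile_stratify(values: pd.Series, variable: str = "") -> StratifiedGroups:
    """Assign the top floor(n/4) samples by value to "high" and the bottom
    floor(n/4) to "low"; the middle half is excluded.

    Ties are broken by stable sample-ID order (all-equal inputs warn but
    stratify deterministically).  Requires >= 8 non-missing samples.
    """
    vals = values.dropna()
    n = len(vals)
    if n < 8:
        raise ValidationError(f"quartile stratification needs >= 8 samples, got {n}")
    k = n // 4
    if vals.nunique() == 1:
        warnings.warn(
            f"all values equal for {variable or 'feature'}; "
            "quartiles assigned by sample-ID order", stacklevel=2
        )
    order = vals.sort_index(kind="mergesort").sort_values(kind="mergesort").index
    assignments = pd.Series("excluded", index=vals.index, dtype=object)
    assignments[order[:k]] = "low"
    assignments[order[-k:]] = "high"
    return StratifiedGroups(variable=variable, assignments=assignments)


def km_estimate(times, events) -> KmCurve:
    """Product-limit survival curve over distinct event times.

    Returns the step function evaluated at every distinct observed time
    (event or censoring), with the number at risk just before each time.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValidationError("empty group for KM estimation")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    grid = tab.index.to_numpy(float)
    surv = kmf.survival_function_at_times(grid).to_numpy(float)
    at_risk = tab["at_risk"].to_numpy(float)
    keep = grid > 0 if grid[0] == 0 and tab.iloc[0][["observed", "censored"]].sum() == 0 else slice(None)
    return KmCurve(times=grid[keep], survival=surv[keep], at_risk=at_risk[keep])


def logrank_test(times, events, group_labels) -> tuple[float, float]:
    """Two-group log-rank test.

    ``group_labels`` is a boolean/0-1 array naming the two groups.  Returns
    (chi2, p from chi2 with 1 df).  With no events anywhere the test is
    undefined and (0, 1) is returned with a warning.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group_labels = np.asarray(group_labels)
    if events.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return 0.0, 1.0
    g = group_labels.astype(bool)
    if g.all() or (~g).all():
        raise ValidationError("log-rank needs two non-empty groups")
    res = _ll_logrank(times[g], times[~g], events[g], events[~g])
    return float(res.test_statistic), float(res.p_value)


def compare_groups(
    clinical: ClinicalTable, groups: StratifiedGroups
) -> SurvivalComparison:
    """KM curves and log-rank p for the high vs low strata."""
    curves = {}
    frames = []
    for label in ("high", "low"):
        samples = getattr(groups, label)
        t, e = clinical.survival(samples)
        curves[label] = km_estimate(t, e)
        frames.append(pd.DataFrame({"time": t, "event": e, "group": label == "high"}))
    allf = pd.concat(frames)
    chi2, p = logrank_test(allf["time"], allf["event"], allf["group"])
    return SurvivalComparison(curves=curves, logrank_chi2=chi2, logrank_p=p)


def _worse_group(comparison: SurvivalComparison) -> str:
    """The stratum with the lower final survival estimate."""
    finals = {
        label: (curve.survival[-1] if curve.survival.size else 1.0)
        for label, curve in comparison.curves.items()
    }
    return min(finals, key=lambda k: (finals[k], k))


def survival_screen(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    worse: str = "low",
) -> pd.DataFrame:
    """Per-feature quartile survival screen over tumor samples.

    ``features`` is a feature x sample matrix (probe betas or gene
    expression).  Each feature is quartile-stratified; the log-rank test
    compares the extremes; ``direction`` records which extreme has worse
    survival (lower final KM estimate).  A feature is flagged iff
    p < alpha AND the hypothesized extreme (``worse``: "low" for probe
    methylation — enhancer active — or "high" for expression) is the worse
    group.  Raw log-rank p-values are reported as published; BH-adjusted
    values are added for transparency.
    """
    if worse not in ("low", "high"):
        raise ValidationError("worse must be 'low' or 'high'")
    tumor = [s for s in clinical.tumor_samples if s in features.columns]
    rows = []
    for feat, vals in features.loc[:, tumor].iterrows():
        try:
            groups = quartile_stratify(vals, variable=str(feat))
        except ValidationError:
            continue
        comp = compare_groups(clinical, groups)
        direction = _worse_group(comp)
        rows.append(
            {
                "feature": feat,
                "chi2": comp.logrank_chi2,
                "p": comp.logrank_p,
                "direction": direction,
                "flagged": bool(comp.logrank_p < alpha and direction == worse),
            }
        )
    out = pd.DataFrame(rows, columns=["feature", "chi2", "p", "direction", "flagged"])
    if not out.empty:
        from .links import adjust_bh

        out["adjusted_p"] = adjust_bh(out["p"])
    return out
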