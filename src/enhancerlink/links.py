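"""TR-probe link testing.

For every differentially methylated enhancer probe, tumor samples are split
into a low-methylation and a high-methylation group at the probe, and each
transcriptional regulator's expression is compared between the groups with
a one-sided rank-sum test:

* hypomethylated probe + higher expression in the low-beta (enhancer
  active) group  -> "activated" link (candidate oncogenic TR);
* hypermethylated probe + lower expression in the high-beta (enhancer
  silenced) group -> "inactivated" link (candidate tumor suppressor).

P-values are Benjamini-Hochberg adjusted within each direction across all
TR x probe tests, and links with adjusted p below ``alpha`` are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import ClassificationCutoffs
from .io import ClinicalTable, ExpressionMatrix, MethylationMatrix, ValidationError

logger = logging.getLogger(__name__)

LINK_COLUMNS = [
    "tr_gene", "probe_id", "direction", "n_group_low", "n_group_high",
    "statistic", "raw_p", "adjusted_p",
]


@dataclass
class LinkParams:
    """Link-test configuration.

    Group cutoffs default to the classification cutoffs so that the "subset
    of tumor samples" seen by the classifier and by the link test is the
    same.  ``test`` selects the statistic: ``wilcoxon`` (one-sided rank-sum,
    exact for small tie-free groups) or ``permutation_z`` (seed-controlled
    label permutation of a mean-difference z-score).
    """

    group_low_cutoff: float = ClassificationCutoffs.tumor_hypo_cutoff
    group_high_cutoff: float = ClassificationCutoffs.meth_cutoff
    min_group_size: int = 5
    alpha: float = 0.05
    test: str = "wilcoxon"
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.min_group_size < 2:
            raise ValidationError("min_group_size must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.test not in ("wilcoxon", "permutation_z"):
            raise ValidationError(f"unknown test {self.test!r}")


def split_tumor_groups(
    probe_betas: pd.Series, params: LinkParams
) -> tuple[list[str], list[str]]:
    """Split tumor samples at a probe into (low, high) methylation groups.

    low = beta < group_low_cutoff, high = beta > group_high_cutoff; samples
    in between (or missing) belong to neither.  Order follows the input
    index for determinism.
    """
    vals = probe_betas.dropna()
    low = list(vals.index[vals < params.group_low_cutoff])
    high = list(vals.index[vals > params.group_high_cutoff])
    return low, high


def rank_sum_test(
    expr_a: np.ndarray, expr_b: np.ndarray, side: str = "greater"
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) test of a vs b.

    ``side='greater'`` tests whether a tends to exceed b.  The exact null
    distribution is used when the pooled size is at most 25 and the data
    are tie-free; otherwise the normal approximation with tie correction.
    Returns (U statistic of a, one-sided p).
    """
    a = np.asarray(expr_a, float)
    b = np.asarray(expr_b, float)
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(pooled) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=side, method=method)
    return float(res.statistic), float(res.pvalue)


def permutation_z_test(
    expr_a: np.ndarray,
    expr_b: np.ndarray,
    side: str,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation p-value for the z-scored rank-sum statistic.

    The pooled values are ranked once; sample labels are shuffled
    ``n_permutations`` times and the standardized rank sum of group a is
    recomputed, so with many permutations the p-value converges to the
    rank-sum p on tie-free data.  p is the add-one-smoothed exceedance
    fraction in the configured direction.
    """
    a = np.asarray(expr_a, float)
    b = np.asarray(expr_b, float)
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled)
    if np.ptp(ranks) == 0:
        return 0.0, 1.0
    mu = na * (n + 1) / 2.0
    sd = np.sqrt(na * (n - na) * (n + 1) / 12.0)
    obs = (ranks[:na].sum() - mu) / sd
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        perm[i] = (rng.permutation(ranks)[:na].sum() - mu) / sd
    if side == "greater":
        exceed = np.sum(perm >= obs)
    else:
        exceed = np.sum(perm <= obs)
    return float(obs), float((exceed + 1) / (n_permutations + 1))


def adjust_bh(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    raw_p = np.asarray(raw_p, float)
    if raw_p.size == 0:
        return raw_p
    return multipletests(raw_p, method="fdr_bh")[1]


def find_links(
    expr: ExpressionMatrix,
    beta: MethylationMatrix,
    classes: pd.DataFrame,
    trs: list[str],
    clinical: ClinicalTable,
    params: LinkParams | None = None,
) -> pd.DataFrame:
    """Test every (differential probe, TR) pair and return significant links.

    ``classes`` is the output of :func:`enhancerlink.classify.classify_probes`.
    Activated candidates pair hypomethylated probes with higher expression
    in the low-beta group; inactivated candidates pair hypermethylated
    probes with lower expression in the high-beta group.  BH adjustment is
    applied within each direction; rows with adjusted_p < alpha are kept,
    sorted by (direction, tr_gene, probe_id).
    """
    params = params or LinkParams()
    tumor = [
        s
        for s in clinical.tumor_samples
        if s in beta.beta.columns and s in expr.values.columns
    ]
    if not tumor:
        raise ValidationError("no tumor samples shared between beta and expression")

    present_trs = [t for t in trs if t in expr.values.index]
    missing = sorted(set(trs) - set(present_trs))
    if missing:
        logger.warning("skipping %d TRs absent from expression matrix: %s",
                       len(missing), ",".join(missing[:10]))

    expr_t = expr.values.loc[present_trs, tumor]
    beta_t = beta.beta.loc[:, tumor]
    rng = np.random.default_rng(params.seed)

    records: list[dict] = []
    # In both directions the biological expectation is higher TR expression
    # in the low-methylation (enhancer-active) group: for hypomethylated
    # probes the low-beta tumors are the activated subset, for
    # hypermethylated probes the high-beta tumors are the silenced subset
    # ("lower expression in the high-methylation group" is the same
    # one-sided comparison with the groups swapped).
    for direction, probe_class, side in (
        ("activated", "hypomethylated", "greater"),
        ("inactivated", "hypermethylated", "greater"),
    ):
        probe_ids = list(classes.index[classes["class"] == probe_class])
        for probe_id in probe_ids:
            if probe_id not in beta_t.index:
                continue
            low, high = split_tumor_groups(beta_t.loc[probe_id], params)
            if len(low) < params.min_group_size or len(high) < params.min_group_size:
                logger.debug(
                    "probe %s skipped: group sizes %d/%d below %d",
                    probe_id, len(low), len(high), params.min_group_size,
                )
                continue
            e_low = expr_t[low].to_numpy(float)
            e_high = expr_t[high].to_numpy(float)
            n_pooled = e_low.shape[1] + e_high.shape[1]
            # one vectorized asymptotic call per probe when the exact
            # small-sample path cannot apply and there are no missing values
            if (
                params.test == "wilcoxon"
                and n_pooled > 25
                and not np.isnan(e_low).any()
                and not np.isnan(e_high).any()
            ):
                res = stats.mannwhitneyu(
                    e_low, e_high, alternative=side, method="asymptotic", axis=1
                )
                for k, tr in enumerate(present_trs):
                    records.append(
                        {
                            "tr_gene": tr,
                            "probe_id": probe_id,
                            "direction": direction,
                            "n_group_low": e_low.shape[1],
                            "n_group_high": e_high.shape[1],
                            "statistic": float(res.statistic[k]),
                            "raw_p": float(res.pvalue[k]),
                        }
                    )
                continue
            for k, tr in enumerate(present_trs):
                a, b = e_low[k], e_high[k]
                if np.isnan(a).any() or np.isnan(b).any():
                    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
                    if len(a) < params.min_group_size or len(b) < params.min_group_size:
                        continue
                if params.test == "wilcoxon":
                    stat, p = rank_sum_test(a, b, side=side)
                else:
                    stat, p = permutation_z_test(
                        a, b, side, params.n_permutations, rng
                    )
                records.append(
                    {
                        "tr_gene": tr,
                        "probe_id": probe_id,
                        "direction": direction,
                        "n_group_low": len(a),
                        "n_group_high": len(b),
                        "statistic": stat,
                        "raw_p": p,
                    }
                )

    table = pd.DataFrame(records, columns=LINK_COLUMNS[:-1])
    if table.empty:
        logger.warning("no testable TR x probe pairs; link table is empty")
        return pd.DataFrame(columns=LINK_COLUMNS)
    table["adjusted_p"] = np.nan
    for direction in ("activated", "inactivated"):
        mask = table["direction"] == direction
        if mask.any():
            table.loc[mask, "adjusted_p"] = adjust_bh(table.loc[mask, "raw_p"])
    kept = table[table["adjusted_p"] < params.alpha].copy()
    kept.sort_values(["direction", "tr_gene", "probe_id"], inplace=True,
                     kind="mergesort")
    kept.reset_index(drop=True, inplace=True)
    return kept


def n_tests(
    beta: MethylationMatrix,
    classes: pd.DataFrame,
    trs: list[str],
    clinical: ClinicalTable,
    expr: ExpressionMatrix,
    params: LinkParams | None = None,
) -> int:
    """Number of TR x probe tests find_links would perform (for calibration
    bookkeeping)."""
    params = params or LinkParams()
    tumor = [
        s
        for s in clinical.tumor_samples
        if s in beta.beta.columns and s in expr.values.columns
    ]
    present_trs = [t for t in trs if t in expr.values.index]
    count = 0
    for probe_class in ("hypomethylated", "hypermethylated"):
        for probe_id in classes.index[classes["class"] == probe_class]:
            if probe_id not in beta.beta.index:
                continue
            low, high = split_tumor_groups(beta.beta.loc[probe_id, tumor], params)
            if len(low) >= params.min_group_size and len(high) >= params.min_group_size:
                count += len(present_trs)
    return count


def write_links(table: pd.DataFrame, params: LinkParams, path) -> None:
    """Write the link TSV with a full parameter echo header."""
    with open(path, "w") as fh:
        for key, val in asdict(params).items():
            fh.write(f"# {key} = {val}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")
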