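"""TR ranking, interaction matrices, correlation, and per-sample burden.

Links produced by :mod:`enhancerlink.links` are summarized per TR (distinct
linked probes, ranked within direction), turned into binary probe x TR
interaction matrices, and compared across TRs through shared-probe overlap
and pairwise squared Pearson correlation of log-scale expression.  The
per-sample link burden counts, for a chosen TR set, how many of their
linked probes are hypomethylated in each tumor sample, defining "highly
linked" and "no-link" patient subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .classify import ClassificationCutoffs
from .io import ExpressionMatrix, MethylationMatrix, ValidationError


@dataclass
class RankingParams:
    """Minimum link counts for flagging key TRs per direction and the
    table depth used for reporting."""

    inactivated_min_links: int = 10
    activated_min_links: int = 50
    top_k: int = 12

    def __post_init__(self):
        if min(self.inactivated_min_links, self.activated_min_links, self.top_k) < 1:
            raise ValidationError("ranking thresholds must be >= 1")


@dataclass
class BurdenParams:
    """Per-sample burden settings: a sample "possesses" a link when the
    linked probe's beta is below ``active_beta_cutoff`` in that sample;
    samples at or above the ``burden_quantile`` of burden are "highly
    linked"."""

    burden_quantile: float = 0.90
    active_beta_cutoff: float = ClassificationCutoffs.tumor_hypo_cutoff

    def __post_init__(self):
        if not (0 < self.burden_quantile < 1):
            raise ValidationError("burden_quantile must be in (0, 1)")


def rank_trs(links: pd.DataFrame, params: RankingParams | None = None) -> pd.DataFrame:
    """Count distinct linked probes per TR and rank within direction.

    Returns columns tr_gene, direction, n_links, rank, flagged; rank 1 is
    the most-linked TR of its direction (ties broken by TR name for
    determinism); ``flagged`` marks TRs meeting the direction's min-links
    threshold.
    """
    params = params or RankingParams()
    if links.empty:
        return pd.DataFrame(columns=["tr_gene", "direction", "n_links", "rank", "flagged"])
    out = []
    for direction, sub in links.groupby("direction"):
        counts = (
            sub.groupby("tr_gene")["probe_id"].nunique().sort_values(ascending=False)
        )
        counts = counts.sort_index(kind="mergesort").sort_values(
            ascending=False, kind="mergesort"
        )
        threshold = (
            params.activated_min_links
            if direction == "activated"
            else params.inactivated_min_links
        )
        for rank, (tr, n) in enumerate(counts.items(), start=1):
            out.append(
                {
                    "tr_gene": tr,
                    "direction": direction,
                    "n_links": int(n),
                    "rank": rank,
                    "flagged": bool(n >= threshold),
                }
            )
    return pd.DataFrame(out)


def interaction_matrix(links: pd.DataFrame, trs: list[str]) -> pd.DataFrame:
    """Binary probe x TR matrix over the selected TRs.

    Rows are the union of probes linked to at least one selected TR; entry
    1 iff the link exists.  Row/column orders are sorted for reproducible
    export.
    """
    unknown = sorted(set(trs) - set(links["tr_gene"]))
    if unknown:
        raise ValidationError(f"TRs without any link: {unknown}")
    sub = links[links["tr_gene"].isin(trs)]
    probes = sorted(sub["probe_id"].unique())
    mat = pd.DataFrame(0, index=pd.Index(probes, name="probe_id"),
                       columns=sorted(set(trs)), dtype=int)
    for tr, probe in zip(sub["tr_gene"], sub["probe_id"]):
        mat.loc[probe, tr] = 1
    return mat


def shared_probe_fraction(
    links: pd.DataFrame, tr: str, others: set[str] | list[str]
) -> float:
    """Fraction of ``tr``'s linked probes also linked to any TR in ``others``.

    NaN when ``tr`` has no links (undefined).
    """
    probes_tr = set(links.loc[links["tr_gene"] == tr, "probe_id"])
    if not probes_tr:
        return float("nan")
    probes_others = set(
        links.loc[links["tr_gene"].isin(set(others)), "probe_id"]
    )
    return len(probes_tr & probes_others) / len(probes_tr)


def tr_expression_correlation(
    expr: ExpressionMatrix, trs: list[str], samples: list[str]
) -> pd.DataFrame:
    """Pairwise squared Pearson correlation (r^2) of log-scale expression.

    Computed across the given (tumor) samples; diagonal is 1; zero-variance
    genes yield NaN entries with a warning.
    """
    if len(samples) < 3:
        raise ValidationError("need >= 3 samples for correlation")
    log_vals = expr.log2().loc[trs, samples]
    sd = log_vals.std(axis=1, ddof=1)
    degenerate = list(sd.index[sd == 0])
    if degenerate:
        warnings.warn(
            f"zero-variance genes in correlation: {degenerate}", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(log_vals.to_numpy(float))
    r2 = pd.DataFrame(r**2, index=trs, columns=trs)
    np.fill_diagonal(r2.values, 1.0)
    for g in degenerate:
        r2.loc[g, :] = np.nan
        r2.loc[:, g] = np.nan
        r2.loc[g, g] = 1.0
    return r2


def sample_link_burden(
    beta: MethylationMatrix,
    links: pd.DataFrame,
    trs: list[str],
    tumor_samples: list[str],
    params: BurdenParams | None = None,
) -> pd.DataFrame:
    """Per-tumor-sample link burden and subgroup labels.

    burden(s) = number of (tr, probe) link records with tr in ``trs`` whose
    probe has beta < active_beta_cutoff in sample s (missing betas do not
    count).  Subgroups: "no_link" iff burden == 0; otherwise
    "highly_linked" iff burden >= the ``burden_quantile`` quantile of the
    burden distribution (inclusive at ties), else "intermediate".
    """
    params = params or BurdenParams()
    sub = links[links["tr_gene"].isin(set(trs))]
    pairs = sub[["tr_gene", "probe_id"]].drop_duplicates()
    burden = pd.Series(0, index=pd.Index(tumor_samples, name="sample_id"), dtype=int)
    probes_in_beta = [p for p in pairs["probe_id"].unique() if p in beta.beta.index]
    if probes_in_beta:
        active = beta.beta.loc[probes_in_beta, tumor_samples] < params.active_beta_cutoff
        per_probe_links = pairs["probe_id"].value_counts()
        weights = per_probe_links.reindex(probes_in_beta).to_numpy()
        burden[:] = (active.to_numpy(float) * weights[:, None]).sum(axis=0).astype(int)
    threshold = float(np.quantile(burden.to_numpy(), params.burden_quantile))
    group = np.where(
        burden == 0, "no_link",
        np.where(burden >= threshold, "highly_linked", "intermediate"),
    )
    return pd.DataFrame({"burden": burden, "subgroup": group})


# ---------------------------------------------------------------------------
# Heatmap export
# ---------------------------------------------------------------------------


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Min-max scale a continuous covariate to [0, 1].

    Zeros are first replaced by the minimum non-zero value (so "absent"
    codes do not stretch the scale); a constant vector maps to 0.5.
    """
    x = np.asarray(values, float).copy()
    nonzero = x[(x != 0) & ~np.isnan(x)]
    if nonzero.size:
        x[x == 0] = nonzero.min()
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        warnings.warn("constant covariate scaled to 0.5", stacklevel=2)
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def heatmap_export(
    beta_sub: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    cluster: bool = True,
) -> dict:
    """Prepare a heatmap bundle: raw betas, scaled covariate tracks, and
    deterministic row/column orders from average-linkage hierarchical
    clustering with Euclidean distance (missing betas filled with the row
    mean for distance computation only).

    Returns a dict with keys ``matrix`` (row/column-reordered betas),
    ``row_order``, ``col_order``, ``tracks`` (scaled covariates aligned to
    the column order).
    """
    mat = beta_sub.copy()
    filled = mat.apply(lambda row: row.fillna(row.mean()), axis=1).to_numpy(float)
    if cluster and mat.shape[0] > 2:
        row_order = list(leaves_list(linkage(filled, method="average",
                                             metric="euclidean")))
    else:
        row_order = list(range(mat.shape[0]))
    if cluster and mat.shape[1] > 2:
        col_order = list(leaves_list(linkage(filled.T, method="average",
                                             metric="euclidean")))
    else:
        col_order = list(range(mat.shape[1]))
    ordered = mat.iloc[row_order, col_order]
    tracks = None
    if covariates is not None:
        tracks = pd.DataFrame(index=ordered.columns)
        for name, col in covariates.items():
            if pd.api.types.is_numeric_dtype(col):
                scaled = pd.Series(
                    minmax_scale(col.to_numpy(float)), index=covariates.index
                )
                tracks[name] = scaled.reindex(ordered.columns)
            else:
                tracks[name] = col.reindex(ordered.columns)
    return {
        "matrix": ordered,
        "row_order": [mat.index[i] for i in row_order],
        "col_order": [mat.columns[i] for i in col_order],
        "tracks": tracks,
    }


def write_heatmap_bundle(bundle: dict, prefix: str) -> None:
    bundle["matrix"].to_csv(f"{prefix}.matrix.tsv", sep="\t", na_rep="NA",
                            float_format="%.10g")
    with open(f"{prefix}.row_order.txt", "w") as fh:
        fh.write("\n".join(map(str, bundle["row_order"])) + "\n")
    with open(f"{prefix}.col_order.txt", "w") as fh:
        fh.write("\n".join(map(str, bundle["col_order"])) + "\n")
    if bundle["tracks"] is not None:
        bundle["tracks"].to_csv(f"{prefix}.tracks.tsv", sep="\t", na_rep="NA",
                                float_format="%.10g")
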