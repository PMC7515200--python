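"""Candidate enhancer target-gene nomination.

Genes are candidate targets of a linked enhancer probe when their TSS lies
within a distance window of the probe (default 1 Mb, the scale of a
topologically associating domain).  Candidates are annotated with
tumor-vs-normal upregulation, TAD co-membership per Hi-C source, and
support from knockdown differential-expression tables (significantly
downregulated after knocking down the TR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GenomicRegion,
    TssRecord,
    ValidationError,
)
from .links import adjust_bh


@dataclass
class TargetSearchParams:
    window_bp: int = 1_000_000
    de_alpha: float = 0.05

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValidationError("window_bp must be positive")


@dataclass(frozen=True)
class TadRegion:
    """A topologically associating domain (0-based half-open) from one
    Hi-C source (cell type)."""

    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError("TAD end must exceed start")


def read_tads(path, source: str = "") -> list[TadRegion]:
    """Read TADs from a BED3 file; validates non-overlap within the source."""
    from .io import read_regions

    regions = read_regions(path, format="bed", source=source or None)
    tads = [TadRegion(r.chrom, r.start, r.end, source=source) for r in regions]
    validate_tads(tads)
    return tads


def validate_tads(tads: list[TadRegion]) -> None:
    by_chrom: dict[str, list[TadRegion]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        ts = sorted(ts, key=lambda t: t.start)
        for a, b in zip(ts, ts[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"overlapping TADs on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def genes_within_window(
    probe_chrom: str,
    probe_position: int,
    tss: list[TssRecord],
    params: TargetSearchParams | None = None,
) -> pd.DataFrame:
    """Genes with at least one TSS within ``window_bp`` of the probe.

    Distance is probe-point to TSS-point on the same chromosome; for a
    gene with several transcripts the minimum distance counts.  Returns a
    DataFrame (gene_id, distance_bp) sorted by distance then gene_id.
    """
    params = params or TargetSearchParams()
    best: dict[str, int] = {}
    for t in tss:
        if t.chrom != probe_chrom:
            continue
        d = abs(probe_position - t.position)
        if d <= params.window_bp and d < best.get(t.gene_id, params.window_bp + 1):
            best[t.gene_id] = d
    rows = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["gene_id", "distance_bp"])


def de_upregulated(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    params: TargetSearchParams | None = None,
) -> pd.DataFrame:
    """Tumor-vs-normal Welch t-test per gene on log-scale expression.

    Returns gene_id-indexed columns t, raw_p, adjusted_p (BH across all
    genes), mean_tumor, mean_normal, upregulated (adjusted_p < de_alpha and
    mean_tumor > mean_normal, on the log scale).  Genes with zero variance
    in both groups are skipped.
    """
    params = params or TargetSearchParams()
    log_vals = expr.log2()
    tumor = [s for s in clinical.tumor_samples if s in log_vals.columns]
    normal = [s for s in clinical.normal_samples if s in log_vals.columns]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValidationError("need >= 2 samples in each group for the t-test")
    xt = log_vals[tumor].to_numpy(float)
    xn = log_vals[normal].to_numpy(float)
    var_t = xt.var(axis=1, ddof=1)
    var_n = xn.var(axis=1, ddof=1)
    keep = ~((var_t == 0) & (var_n == 0))
    if not keep.all():
        import warnings

        warnings.warn(
            f"skipping {int((~keep).sum())} zero-variance genes in DE test",
            stacklevel=2,
        )
    t_stat, p = stats.ttest_ind(xt[keep], xn[keep], axis=1, equal_var=False)
    out = pd.DataFrame(
        {
            "t": t_stat,
            "raw_p": p,
            "adjusted_p": adjust_bh(p),
            "mean_tumor": xt[keep].mean(axis=1),
            "mean_normal": xn[keep].mean(axis=1),
        },
        index=pd.Index(np.asarray(expr.gene_ids)[keep], name="gene_id"),
    )
    out["upregulated"] = (out["adjusted_p"] < params.de_alpha) & (
        out["mean_tumor"] > out["mean_normal"]
    )
    return out


def same_tad(
    probe_chrom: str,
    probe_position: int,
    tss_chrom: str,
    tss_position: int,
    tads: list[TadRegion],
) -> bool:
    """True iff one TAD contains both the probe and the TSS.

    Points outside every TAD (or on different chromosomes) return False.
    """
    if probe_chrom != tss_chrom:
        return False
    for t in tads:
        if t.chrom == probe_chrom and t.start <= probe_position < t.end:
            return t.start <= tss_position < t.end
    return False


def integrate_knockdown(
    candidates: pd.DataFrame,
    de_tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Annotate candidates with knockdown support.

    A gene is supported by experiment E iff its adjusted_p < alpha and
    log2fc < 0 in E's table (significantly downregulated after knockdown).
    ``knockdown_support`` is "none", the single experiment name, or
    "multiple" (comma-joined list in ``knockdown_experiments``).
    """
    supported_by = {
        name: set(
            table.index[(table["adjusted_p"] < alpha) & (table["log2fc"] < 0)]
        )
        for name, table in de_tables.items()
    }
    supports: list[str] = []
    experiments: list[str] = []
    for gene in candidates["gene_id"]:
        hits = [name for name, genes in supported_by.items() if gene in genes]
        experiments.append(",".join(hits))
        if not hits:
            supports.append("none")
        elif len(hits) == 1:
            supports.append(hits[0])
        else:
            supports.append("multiple")
    out = candidates.copy()
    out["knockdown_support"] = supports
    out["knockdown_experiments"] = experiments
    return out


def map_targets(
    link_probes: pd.DataFrame,
    tss: list[TssRecord],
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    tads_by_source: dict[str, list[TadRegion]] | None = None,
    de_tables: dict[str, pd.DataFrame] | None = None,
    params: TargetSearchParams | None = None,
) -> pd.DataFrame:
    """Full target-candidate table for a set of linked probes.

    ``link_probes`` needs columns probe_id, chrom, position.  Output rows
    are (probe_id, gene_id) pairs within the window, annotated with
    distance_bp, upregulated, same_tad_<source> per TAD source plus
    same_tad_all, and knockdown support columns.
    """
    params = params or TargetSearchParams()
    tads_by_source = tads_by_source or {}
    for tads in tads_by_source.values():
        validate_tads(tads)
    de = de_upregulated(expr, clinical, params)
    up = de["upregulated"]

    # TAD lookup: index of the containing TAD per point, -1 when outside
    tad_index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for source, tads in tads_by_source.items():
        per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[TadRegion]] = {}
        for t in tads:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            ts = sorted(ts, key=lambda t: t.start)
            per_chrom[chrom] = (
                np.array([t.start for t in ts]),
                np.array([t.end for t in ts]),
            )
        tad_index[source] = per_chrom

    def tad_of(source: str, chrom: str, pos: np.ndarray) -> np.ndarray:
        per_chrom = tad_index[source]
        if chrom not in per_chrom:
            return np.full(len(pos), -1)
        starts, ends = per_chrom[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = (i >= 0) & (pos < ends[np.clip(i, 0, len(ends) - 1)])
        return np.where(ok, i, -1)

    # TSS arrays per chromosome
    tss_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in sorted({t.chrom for t in tss}):
        recs = [t for t in tss if t.chrom == chrom]
        tss_by_chrom[chrom] = (
            np.array([t.position for t in recs]),
            np.array([t.gene_id for t in recs], dtype=object),
        )

    frames = []
    for chrom, probes in link_probes.groupby("chrom"):
        if chrom not in tss_by_chrom:
            continue
        tpos, tgene = tss_by_chrom[chrom]
        ppos = probes["position"].to_numpy(int)
        dist = np.abs(ppos[:, None] - tpos[None, :])
        pi, tj = np.nonzero(dist <= params.window_bp)
        if len(pi) == 0:
            continue
        pairs = pd.DataFrame(
            {
                "probe_id": probes["probe_id"].to_numpy()[pi],
                "gene_id": tgene[tj],
                "distance_bp": dist[pi, tj],
            }
        )
        ppos_pairs = ppos[pi]
        tpos_pairs = tpos[tj]
        for source in tads_by_source:
            probe_tad = tad_of(source, chrom, ppos_pairs)
            tss_tad = tad_of(source, chrom, tpos_pairs)
            pairs[f"same_tad_{source}"] = (probe_tad >= 0) & (
                probe_tad == tss_tad
            )
        # reduce transcripts -> genes: min distance, any-TSS TAD membership
        agg = {"distance_bp": "min"}
        for source in tads_by_source:
            agg[f"same_tad_{source}"] = "max"
        reduced = (
            pairs.groupby(["probe_id", "gene_id"], sort=False)
            .agg(agg)
            .reset_index()
        )
        frames.append(reduced)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    out["distance_bp"] = out["distance_bp"].astype(int)
    out["upregulated"] = up.reindex(
        out["gene_id"], fill_value=False
    ).to_numpy(dtype=bool)
    tad_cols = [f"same_tad_{s}" for s in tads_by_source]
    for col in tad_cols:
        out[col] = out[col].astype(bool)
    out["same_tad_all"] = (
        out[tad_cols].all(axis=1) if tad_cols else bool(tads_by_source)
    )
    order = ["probe_id", "gene_id", "distance_bp", "upregulated"]
    out = out[order + tad_cols + ["same_tad_all"]]
    out = out.sort_values(["probe_id", "distance_bp", "gene_id"],
                          kind="mergesort").reset_index(drop=True)
    if de_tables:
        out = integrate_knockdown(out, de_tables, alpha=params.de_alpha)
    return out
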