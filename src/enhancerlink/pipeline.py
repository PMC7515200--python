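"""Stage orchestration: a flat run config, staged artifacts, and manifests.

Each stage reads validated inputs (or the artifacts of earlier stages),
runs the corresponding library call, and writes its outputs plus a
``<stage>.manifest.json`` recording the package version, seed, parameter
block, and SHA-256 of every input consumed — enough to regenerate the
artifact.  Re-running a stage with identical inputs and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import AtlasParams, build_atlas
from .classify import ClassificationCutoffs, classify_probes, write_classification
from .io import (
    ValidationError,
    read_clinical,
    read_gene_list,
    read_de_table,
    read_manifest,
    read_matrix,
    read_meme_motifs,
    read_regions,
    read_tss,
    write_regions,
)
from .links import LinkParams, find_links, write_links
from .motif import MotifScanParams, enrichment_fraction, hits_table
from .network import (
    BurdenParams,
    RankingParams,
    heatmap_export,
    interaction_matrix,
    rank_trs,
    sample_link_burden,
    tr_expression_correlation,
    write_heatmap_bundle,
)
from .survival import survival_screen
from .targets import TargetSearchParams, map_targets, read_tads

logger = logging.getLogger(__name__)

STAGES = ("atlas", "classify", "link", "rank", "survival", "targets", "motif")

_PARAM_CLASSES = {
    "atlas": AtlasParams,
    "classify": ClassificationCutoffs,
    "link": LinkParams,
    "rank": RankingParams,
    "burden": BurdenParams,
    "targets": TargetSearchParams,
    "motif": MotifScanParams,
}

_INPUT_KEYS = {
    "enhancers", "open_chromatin", "manifest", "gtf", "beta", "expression",
    "clinical", "trs", "tads", "knockdown", "genome", "motifs",
}


class RunConfig:
    """Validated run configuration (one flat file per run).

    ``inputs`` maps input names to paths (lists for peak sets, dicts for
    TAD sources and knockdown experiments); ``params`` holds one block per
    stage.  Unknown keys are rejected so silent typos cannot change a run.
    """

    def __init__(self, inputs: dict, params: dict | None = None, seed: int = 0,
                 expression_transform: str = "linear"):
        unknown = set(inputs) - _INPUT_KEYS
        if unknown:
            raise ValidationError(f"unknown input keys: {sorted(unknown)}")
        params = params or {}
        unknown = set(params) - set(_PARAM_CLASSES)
        if unknown:
            raise ValidationError(f"unknown parameter blocks: {sorted(unknown)}")
        self.inputs = inputs
        self.seed = int(seed)
        self.expression_transform = expression_transform
        self.params = {}
        for name, cls in _PARAM_CLASSES.items():
            block = dict(params.get(name, {}))
            known = {f.name for f in dataclasses.fields(cls)}
            bad = set(block) - known
            if bad:
                raise ValidationError(
                    f"unknown keys in params.{name}: {sorted(bad)}"
                )
            if name == "link":
                block.setdefault("seed", self.seed)
            self.params[name] = cls(**block)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"inputs", "params", "seed", "expression_transform"}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            inputs=raw.get("inputs", {}),
            params=raw.get("params", {}),
            seed=raw.get("seed", 0),
            expression_transform=raw.get("expression_transform", "linear"),
        )
        cfg.check_paths()
        return cfg

    def _iter_paths(self):
        for key, val in self.inputs.items():
            if isinstance(val, dict):
                yield from val.values()
            elif isinstance(val, (list, tuple)):
                yield from val
            else:
                yield val

    def check_paths(self) -> None:
        missing = [str(p) for p in self._iter_paths() if not Path(p).exists()]
        if missing:
            raise ValidationError(f"config references missing paths: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(stage: str, outdir: Path, config: RunConfig,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "params": {
            name: dataclasses.asdict(block) for name, block in config.params.items()
        },
        "inputs": {str(p): _sha256(Path(p)) for p in sorted(map(str, inputs))},
        "outputs": sorted(str(p) for p in outputs),
    }
    with open(outdir / f"{stage}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(outdir: Path, artifact: str, needed_by: str, produced_by: str) -> Path:
    path = outdir / artifact
    if not path.exists():
        raise ValidationError(
            f"stage '{needed_by}' needs {artifact}; run stage '{produced_by}' first"
        )
    return path


def _read_artifact_tsv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def run_stage(stage: str, config: RunConfig, outdir: str | Path) -> list[Path]:
    """Run one pipeline stage, writing artifacts + manifest into outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        written = []
        for s in STAGES:
            written += run_stage(s, config, outdir)
        return written
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}")
    fn = globals()[f"_stage_{stage}"]
    inputs, outputs = fn(config, outdir)
    _write_manifest(stage, outdir, config, inputs, outputs)
    return outputs


def _stage_atlas(config: RunConfig, outdir: Path):
    ins = [Path(p) for p in config.inputs["enhancers"]]
    ino = [Path(p) for p in config.inputs["open_chromatin"]]
    man, gtf = Path(config.inputs["manifest"]), Path(config.inputs["gtf"])
    atlas = build_atlas(
        [read_regions(p) for p in ins],
        [read_regions(p) for p in ino],
        read_manifest(man),
        read_tss(gtf),
        config.params["atlas"],
    )
    out_tsv = outdir / "atlas.tsv"
    atlas.write(out_tsv)
    enh_bed = outdir / "atlas_enhancers.bed"
    oc_bed = outdir / "atlas_open_chromatin.bed"
    write_regions(atlas.enhancer_regions, enh_bed)
    write_regions(atlas.open_regions, oc_bed)
    return ins + ino + [man, gtf], [out_tsv, enh_bed, oc_bed]


def _stage_classify(config: RunConfig, outdir: Path):
    atlas_tsv = _require(outdir, "atlas.tsv", "classify", "atlas")
    beta_p, clin_p = Path(config.inputs["beta"]), Path(config.inputs["clinical"])
    beta = read_matrix(beta_p, kind="beta")
    clinical = read_clinical(clin_p)
    atlas_probes = _read_artifact_tsv(atlas_tsv)["probe_id"].astype(str)
    present = [p for p in atlas_probes if p in beta.beta.index]
    from .io import MethylationMatrix

    sub = MethylationMatrix(beta=beta.beta.loc[present])
    table = classify_probes(sub, clinical, config.params["classify"])
    out = outdir / "classification.tsv"
    write_classification(table, config.params["classify"], out)
    return [atlas_tsv, beta_p, clin_p], [out]


def _stage_link(config: RunConfig, outdir: Path):
    cls_tsv = _require(outdir, "classification.tsv", "link", "classify")
    beta_p, expr_p = Path(config.inputs["beta"]), Path(config.inputs["expression"])
    clin_p, trs_p = Path(config.inputs["clinical"]), Path(config.inputs["trs"])
    classes = _read_artifact_tsv(cls_tsv, index_col=0)
    links = find_links(
        read_matrix(expr_p, kind="expression",
                    transform=config.expression_transform),
        read_matrix(beta_p, kind="beta"),
        classes,
        read_gene_list(trs_p),
        read_clinical(clin_p),
        config.params["link"],
    )
    out = outdir / "links.tsv"
    write_links(links, config.params["link"], out)
    return [cls_tsv, beta_p, expr_p, clin_p, trs_p], [out]


def _stage_rank(config: RunConfig, outdir: Path):
    links_tsv = _require(outdir, "links.tsv", "rank", "link")
    beta_p, expr_p = Path(config.inputs["beta"]), Path(config.inputs["expression"])
    clin_p = Path(config.inputs["clinical"])
    links = _read_artifact_tsv(links_tsv)
    ranks = rank_trs(links, config.params["rank"])
    out_rank = outdir / "tr_ranks.tsv"
    ranks.to_csv(out_rank, sep="\t", index=False)
    outputs = [out_rank]

    flagged_act = ranks.query("direction == 'activated' and flagged")["tr_gene"]
    if not flagged_act.empty:
        sel = list(flagged_act)
        mat = interaction_matrix(links, sel)
        out_mat = outdir / "interaction_matrix.tsv"
        mat.to_csv(out_mat, sep="\t")
        clinical = read_clinical(clin_p)
        expr = read_matrix(expr_p, kind="expression",
                           transform=config.expression_transform)
        tumor = [s for s in clinical.tumor_samples if s in expr.values.columns]
        present = [t for t in sel if t in expr.values.index]
        r2 = tr_expression_correlation(expr, present, tumor)
        out_r2 = outdir / "tr_r2.tsv"
        r2.to_csv(out_r2, sep="\t", float_format="%.10g")
        beta = read_matrix(beta_p, kind="beta")
        tumor_b = [s for s in clinical.tumor_samples if s in beta.beta.columns]
        burden = sample_link_burden(beta, links, sel, tumor_b,
                                    config.params["burden"])
        out_burden = outdir / "burden.tsv"
        burden.to_csv(out_burden, sep="\t")
        probes = sorted(
            links.loc[links["tr_gene"].isin(sel), "probe_id"].unique()
        )
        probes = [p for p in probes if p in beta.beta.index]
        if probes:
            bundle = heatmap_export(
                beta.beta.loc[probes, tumor_b], clinical.covariates.loc[tumor_b]
            )
            write_heatmap_bundle(bundle, str(outdir / "heatmap"))
            outputs += [
                outdir / "heatmap.matrix.tsv",
                outdir / "heatmap.row_order.txt",
                outdir / "heatmap.col_order.txt",
                outdir / "heatmap.tracks.tsv",
            ]
        outputs += [out_mat, out_r2, out_burden]
    return [links_tsv, beta_p, expr_p, clin_p], outputs


def _stage_survival(config: RunConfig, outdir: Path):
    links_tsv = _require(outdir, "links.tsv", "survival", "link")
    beta_p, expr_p = Path(config.inputs["beta"]), Path(config.inputs["expression"])
    clin_p = Path(config.inputs["clinical"])
    links = _read_artifact_tsv(links_tsv)
    clinical = read_clinical(clin_p)
    outputs = []

    act = links[links["direction"] == "activated"]
    probes = sorted(act["probe_id"].unique())
    beta = read_matrix(beta_p, kind="beta")
    probes = [p for p in probes if p in beta.beta.index]
    if probes:
        screen = survival_screen(beta.beta.loc[probes], clinical, worse="low")
        out = outdir / "survival_probes.tsv"
        screen.to_csv(out, sep="\t", index=False, float_format="%.10g")
        outputs.append(out)

    trs = sorted(act["tr_gene"].unique())
    expr = read_matrix(expr_p, kind="expression",
                       transform=config.expression_transform)
    trs = [t for t in trs if t in expr.values.index]
    if trs:
        screen = survival_screen(expr.log2().loc[trs], clinical, worse="high")
        out = outdir / "survival_trs.tsv"
        screen.to_csv(out, sep="\t", index=False, float_format="%.10g")
        outputs.append(out)
    return [links_tsv, beta_p, expr_p, clin_p], outputs


def _stage_targets(config: RunConfig, outdir: Path):
    links_tsv = _require(outdir, "links.tsv", "targets", "link")
    atlas_tsv = _require(outdir, "atlas.tsv", "targets", "atlas")
    gtf = Path(config.inputs["gtf"])
    expr_p, clin_p = Path(config.inputs["expression"]), Path(config.inputs["clinical"])
    links = _read_artifact_tsv(links_tsv)
    atlas_df = _read_artifact_tsv(atlas_tsv)
    probes = atlas_df[
        atlas_df["probe_id"].isin(links["probe_id"].unique())
    ][["probe_id", "chrom", "position"]]
    tads_by_source = {
        name: read_tads(path, source=name)
        for name, path in (config.inputs.get("tads") or {}).items()
    }
    de_tables = {
        name: read_de_table(path)
        for name, path in (config.inputs.get("knockdown") or {}).items()
    }
    table = map_targets(
        probes,
        read_tss(gtf),
        read_matrix(expr_p, kind="expression",
                    transform=config.expression_transform),
        read_clinical(clin_p),
        tads_by_source=tads_by_source,
        de_tables=de_tables,
        params=config.params["targets"],
    )
    out = outdir / "targets.tsv"
    table.to_csv(out, sep="\t", index=False)
    ins = [links_tsv, atlas_tsv, gtf, expr_p, clin_p]
    ins += [Path(p) for p in (config.inputs.get("tads") or {}).values()]
    ins += [Path(p) for p in (config.inputs.get("knockdown") or {}).values()]
    return ins, [out]


def _stage_motif(config: RunConfig, outdir: Path):
    links_tsv = _require(outdir, "links.tsv", "motif", "link")
    atlas_tsv = _require(outdir, "atlas.tsv", "motif", "atlas")
    genome_p = Path(config.inputs["genome"])
    motifs_p = Path(config.inputs["motifs"])
    from pyfaidx import Fasta

    genome = Fasta(str(genome_p), as_raw=True, sequence_always_upper=True)
    pwms = read_meme_motifs(motifs_p)
    links = _read_artifact_tsv(links_tsv)
    atlas_df = _read_artifact_tsv(atlas_tsv)
    probes_df = atlas_df[
        atlas_df["probe_id"].isin(links["probe_id"].unique())
    ]
    probes = [
        (str(r["probe_id"]), str(r["chrom"]), int(r["position"]))
        for _, r in probes_df.iterrows()
        if str(r["chrom"]) in genome.keys()
    ]
    params = config.params["motif"]
    hits = hits_table(probes, genome, pwms, params)
    out_hits = outdir / "motif_hits.tsv"
    hits.to_csv(out_hits, sep="\t", index=False, float_format="%.6g")
    frac = enrichment_fraction(probes, genome, pwms, params)
    out_frac = outdir / "motif_fraction.tsv"
    with open(out_frac, "w") as fh:
        fh.write("motif_set\tn_probes\tfraction\n")
        fh.write(f"all\t{len(probes)}\t{frac:.6g}\n")
    return [links_tsv, atlas_tsv, genome_p, motifs_p], [out_hits, out_frac]
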