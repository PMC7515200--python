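"""Synthetic input bundles with planted ground truth.

The generator emits an internally consistent set of inputs — peak files,
probe manifest, gene annotation, beta and expression matrices, clinical
table, TR catalogue, TADs, knockdown DE tables, and a motif-planted genome
— in exactly the formats the readers consume, together with truth tables
naming every planted probe class, TR-probe link, and affected-sample
label.

The statistical structure mimics the tumor-activation signal the pipeline
is built to detect: betas are drawn from low/high-mode Beta distributions
(respecting the [0, 1] support and the bimodality of array data); each
planted activated TR has a random tumor subset in which its linked probes
lose ``delta_beta`` of methylation and its own expression gains
``expression_shift_sd`` standard deviations on the log scale; survival
times are exponential with hazard scaled per unit of planted link burden,
so the survival screen has recoverable truth.

This is not a simulator of array chemistry, tumor purity, or clonal
structure; see docs/methods.md for what passing on these fixtures does and
does not demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GenomicRegion,
    MethylationMatrix,
    ProbeManifestRecord,
    TssRecord,
    ValidationError,
    write_clinical,
    write_manifest,
    write_matrix,
    write_meme_motifs,
    write_regions,
)
from .motif import Pwm
from .targets import TadRegion

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedTr:
    """One planted transcriptional regulator and its enhancer signal."""

    tr_gene: str
    n_linked_probes: int = 60
    tumor_fraction_affected: float = 0.4
    delta_beta: float = 0.5
    expression_shift_sd: float = 2.0

    def __post_init__(self):
        if not (0 < self.tumor_fraction_affected <= 1):
            raise ValidationError("tumor_fraction_affected must be in (0, 1]")
        if self.delta_beta < 0 or self.delta_beta > 1:
            raise ValidationError("delta_beta must be in [0, 1]")


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic bundle.

    Defaults reproduce the standard recovery setting: 20 normal + 200
    tumor samples, 2,000 probes, 3,000 genes, a 100-gene TR catalogue, and
    three planted activated TRs with 60 linked probes each (delta_beta
    0.5, +2 SD expression shift, 40% of tumors affected).
    """

    seed: int = 0
    n_normal: int = 20
    n_tumor: int = 200
    n_probes: int = 2000
    n_genes: int = 3000
    n_trs: int = 100
    planted_activated_trs: list[PlantedTr] = field(
        default_factory=lambda: [
            PlantedTr("G0000"), PlantedTr("G0001"), PlantedTr("G0002"),
        ]
    )
    planted_inactivated_trs: list[PlantedTr] = field(default_factory=list)
    # beta model: low/high Beta modes + clipped gaussian noise
    beta_low_shape: tuple[float, float] = (5.0, 45.0)
    beta_high_shape: tuple[float, float] = (45.0, 5.0)
    beta_noise_sd: float = 0.02
    atlas_fraction: float = 0.85  # probes placed in open-within-enhancer loci
    probe_spacing_bp: int = 4000
    # survival model
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    hazard_ratio_per_link: float = 1.01
    censoring_hazard: float = 1.0 / 3000.0
    # motif sub-fixture (separate contig)
    n_motif_windows: int = 100
    n_motif_planted: int = 60
    motif_width: int = 8
    motif_window_spacing: int = 2500
    # TADs
    tad_size_bp: int = 400_000

    def __post_init__(self):
        total_planted = sum(
            t.n_linked_probes
            for t in self.planted_activated_trs + self.planted_inactivated_trs
        )
        if total_planted > int(self.atlas_fraction * self.n_probes):
            raise ValidationError(
                f"{total_planted} planted linked probes exceed the "
                f"~{int(self.atlas_fraction * self.n_probes)} atlas-eligible probes"
            )
        if self.n_motif_planted > self.n_motif_windows:
            raise ValidationError("n_motif_planted exceeds n_motif_windows")
        for t in self.planted_activated_trs + self.planted_inactivated_trs:
            if t.tr_gene not in self._tr_catalogue():
                raise ValidationError(f"planted TR {t.tr_gene} not in the TR catalogue")

    def _tr_catalogue(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_trs)]


def null_config(seed: int = 0, **overrides) -> FixtureConfig:
    """A config with differential probes but no expression signal: planted
    TRs keep their beta pattern (so probes classify as differential and are
    tested) but the expression shift is zero, so the truth table contains
    no links."""
    cfg = FixtureConfig(seed=seed, **overrides)
    cfg.planted_activated_trs = [
        replace(t, expression_shift_sd=0.0) for t in cfg.planted_activated_trs
    ]
    cfg.planted_inactivated_trs = [
        replace(t, expression_shift_sd=0.0) for t in cfg.planted_inactivated_trs
    ]
    return cfg


@dataclass
class FixtureBundle:
    """In-memory bundle of all generated inputs plus truth tables."""

    config: FixtureConfig
    enhancer_sets: list[list[GenomicRegion]]
    open_sets: list[list[GenomicRegion]]
    manifest: list[ProbeManifestRecord]
    tss: list[TssRecord]
    beta: MethylationMatrix
    expr: ExpressionMatrix
    clinical: ClinicalTable
    trs: list[str]
    tads: dict[str, list[TadRegion]]
    de_tables: dict[str, pd.DataFrame]
    genome: dict[str, str]
    motif_pwm: Pwm
    motif_probes: list[tuple[str, str, int]]
    motif_planted_ids: set[str]
    truth_probes: pd.DataFrame
    truth_links: pd.DataFrame
    truth_samples: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every input in its external format; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        for i, regions in enumerate(self.enhancer_sets):
            p = outdir / f"enhancers_{i}.bed"
            write_regions(regions, p)
            paths[f"enhancers_{i}"] = p
        for i, regions in enumerate(self.open_sets):
            p = outdir / f"open_chromatin_{i}.bed"
            write_regions(regions, p)
            paths[f"open_chromatin_{i}"] = p

        paths["manifest"] = outdir / "manifest.tsv"
        write_manifest(self.manifest, paths["manifest"])

        paths["gtf"] = outdir / "annotation.gtf"
        with open(paths["gtf"], "w") as fh:
            for t in self.tss:
                # 1-based inclusive; emit a 1 kb transcript body
                if t.strand == "+":
                    start, end = t.position + 1, t.position + 1000
                else:
                    start, end = max(t.position - 999, 1), t.position + 1
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                )
                fh.write(
                    f"{t.chrom}\tsynthetic\ttranscript\t{start}\t{end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )

        paths["beta"] = outdir / "beta.tsv"
        write_matrix(self.beta, paths["beta"])
        paths["expression"] = outdir / "expression.tsv"
        write_matrix(self.expr, paths["expression"])
        paths["clinical"] = outdir / "clinical.tsv"
        write_clinical(self.clinical, paths["clinical"])

        paths["trs"] = outdir / "tr_catalogue.txt"
        with open(paths["trs"], "w") as fh:
            fh.write("\n".join(self.trs) + "\n")

        for source, tads in self.tads.items():
            p = outdir / f"tads_{source}.bed"
            with open(p, "w") as fh:
                for t in tads:
                    fh.write(f"{t.chrom}\t{t.start}\t{t.end}\n")
            paths[f"tads_{source}"] = p

        for name, table in self.de_tables.items():
            p = outdir / f"knockdown_{name}.tsv"
            table.to_csv(p, sep="\t", index=False, float_format="%.10g")
            paths[f"knockdown_{name}"] = p

        paths["genome"] = outdir / "genome.fa"
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k : k + 80] + "\n")

        paths["motifs"] = outdir / "motifs.meme"
        write_meme_motifs([self.motif_pwm], paths["motifs"])

        paths["motif_probes"] = outdir / "motif_probes.tsv"
        with open(paths["motif_probes"], "w") as fh:
            fh.write("probe_id\tchrom\tposition\tplanted\n")
            for pid, chrom, pos in self.motif_probes:
                fh.write(
                    f"{pid}\t{chrom}\t{pos}\t{int(pid in self.motif_planted_ids)}\n"
                )

        paths["truth_probes"] = outdir / "truth_probes.tsv"
        self.truth_probes.to_csv(paths["truth_probes"], sep="\t", index=False)
        paths["truth_links"] = outdir / "truth_links.tsv"
        self.truth_links.to_csv(paths["truth_links"], sep="\t", index=False)
        paths["truth_samples"] = outdir / "truth_samples.tsv"
        self.truth_samples.to_csv(paths["truth_samples"], sep="\t", index=False)
        return paths


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def generate_fixture(config: FixtureConfig | None = None) -> FixtureBundle:
    """Generate the full bundle. Identical config (incl. seed) gives an
    identical bundle."""
    cfg = config or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)

    probe_ids = [f"cg{i:06d}" for i in range(cfg.n_probes)]
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    trs = cfg._tr_catalogue()
    normal_ids = [f"N{i:03d}" for i in range(cfg.n_normal)]
    tumor_ids = [f"T{i:03d}" for i in range(cfg.n_tumor)]
    samples = normal_ids + tumor_ids

    # ---- genomic layout: probes along chr1, genes midway between probes
    spacing = cfg.probe_spacing_bp
    probe_pos = np.array([2000 + i * spacing for i in range(cfg.n_probes)])
    manifest = [
        ProbeManifestRecord(pid, "chr1", int(pos))
        for pid, pos in zip(probe_ids, probe_pos)
    ]

    # atlas eligibility: 85% open-within-enhancer, 5% enhancer-only,
    # 5% open-only, 5% TSS-proximal (a TSS planted 1 kb away)
    roll = rng.random(cfg.n_probes)
    f = cfg.atlas_fraction
    atlas_member = roll < f
    enh_only = (roll >= f) & (roll < f + 0.05)
    open_only = (roll >= f + 0.05) & (roll < f + 0.10)
    tss_proximal = roll >= f + 0.10
    in_enh = atlas_member | tss_proximal
    in_open = atlas_member | tss_proximal

    enhancers, open_chrom = [], []
    for i in range(cfg.n_probes):
        p = int(probe_pos[i])
        if in_enh[i] or enh_only[i] or tss_proximal[i]:
            enhancers.append(GenomicRegion("chr1", p - 800, p + 800, source="enh"))
        if in_open[i] or open_only[i] or tss_proximal[i]:
            open_chrom.append(GenomicRegion("chr1", p - 200, p + 200, source="open"))
    # split each peak class into two "datasets" to exercise the union rule
    half = len(enhancers) // 2
    enhancer_sets = [enhancers[:half], enhancers[half:]]
    halfo = len(open_chrom) // 2
    open_sets = [open_chrom[:halfo], open_chrom[halfo:]]

    tss: list[TssRecord] = []
    for j, gid in enumerate(gene_ids):
        anchor = int(probe_pos[j % cfg.n_probes]) + spacing // 2
        strand = "+" if j % 2 == 0 else "-"
        tss.append(TssRecord(gid, "chr1", anchor, strand, transcript_id=f"{gid}.1"))
    for i in np.flatnonzero(tss_proximal):
        tss.append(
            TssRecord(
                f"GX{i:04d}", "chr1", int(probe_pos[i]) + 1000, "+",
                transcript_id=f"GX{i:04d}.1",
            )
        )

    # ---- assign planted probes from atlas members
    eligible = list(np.flatnonzero(atlas_member))
    rng.shuffle(eligible)
    cursor = 0
    planted_probe_idx: dict[str, np.ndarray] = {}
    for t in cfg.planted_activated_trs + cfg.planted_inactivated_trs:
        planted_probe_idx[t.tr_gene] = np.array(
            eligible[cursor : cursor + t.n_linked_probes]
        )
        cursor += t.n_linked_probes
    rest = np.array(eligible[cursor:] + list(np.flatnonzero(~atlas_member)))

    # ---- beta matrix
    lo_a, lo_b = cfg.beta_low_shape
    hi_a, hi_b = cfg.beta_high_shape
    beta_vals = np.empty((cfg.n_probes, len(samples)))
    baseline_high = rng.random(cfg.n_probes) < 0.5  # background mode per probe
    for i in range(cfg.n_probes):
        a, b = (hi_a, hi_b) if baseline_high[i] else (lo_a, lo_b)
        beta_vals[i] = rng.beta(a, b, size=len(samples))

    affected: dict[str, np.ndarray] = {}
    for t in cfg.planted_activated_trs:
        n_aff = int(round(t.tumor_fraction_affected * cfg.n_tumor))
        aff = rng.choice(cfg.n_tumor, size=n_aff, replace=False)
        affected[t.tr_gene] = np.sort(aff)
        cols = cfg.n_normal + aff
        for i in planted_probe_idx[t.tr_gene]:
            beta_vals[i] = rng.beta(hi_a, hi_b, size=len(samples))  # high baseline
            beta_vals[i, cols] -= t.delta_beta
    for t in cfg.planted_inactivated_trs:
        n_aff = int(round(t.tumor_fraction_affected * cfg.n_tumor))
        aff = rng.choice(cfg.n_tumor, size=n_aff, replace=False)
        affected[t.tr_gene] = np.sort(aff)
        cols = cfg.n_normal + aff
        for i in planted_probe_idx[t.tr_gene]:
            beta_vals[i] = rng.beta(lo_a, lo_b, size=len(samples))  # low baseline
            beta_vals[i, cols] += t.delta_beta
    beta_vals = _clip01(
        beta_vals + rng.normal(0.0, cfg.beta_noise_sd, size=beta_vals.shape)
    )
    beta = MethylationMatrix(
        beta=pd.DataFrame(beta_vals, index=probe_ids, columns=samples)
    )

    # ---- expression matrix (stored linear; signal planted on log2 scale)
    mu = rng.uniform(3.0, 8.0, size=cfg.n_genes)
    log_expr = rng.normal(mu[:, None], 1.0, size=(cfg.n_genes, len(samples)))
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    for t in cfg.planted_activated_trs:
        cols = cfg.n_normal + affected[t.tr_gene]
        log_expr[gene_index[t.tr_gene], cols] += t.expression_shift_sd
    for t in cfg.planted_inactivated_trs:
        cols = cfg.n_normal + affected[t.tr_gene]
        log_expr[gene_index[t.tr_gene], cols] -= t.expression_shift_sd
    # tumor-wide upregulation of the nearest gene to each planted probe,
    # giving the target mapper recoverable truth
    target_genes: set[str] = set()
    for t in cfg.planted_activated_trs:
        for i in planted_probe_idx[t.tr_gene]:
            target_genes.add(gene_ids[i % cfg.n_genes])
    tumor_cols = np.arange(cfg.n_normal, len(samples))
    for gid in sorted(target_genes):
        log_expr[gene_index[gid], tumor_cols] += 2.0
    expr = ExpressionMatrix(
        values=pd.DataFrame(
            2.0 ** log_expr, index=gene_ids, columns=samples
        ),
        transform="linear",
    )

    # ---- truth tables
    probe_class = np.where(baseline_high, "methylated", "unmethylated").astype(object)
    planted_by: dict[int, str] = {}
    for t in cfg.planted_activated_trs:
        for i in planted_probe_idx[t.tr_gene]:
            probe_class[i] = "hypomethylated" if t.delta_beta > 0 else "methylated"
            planted_by[i] = t.tr_gene
    for t in cfg.planted_inactivated_trs:
        for i in planted_probe_idx[t.tr_gene]:
            probe_class[i] = "hypermethylated" if t.delta_beta > 0 else "unmethylated"
            planted_by[i] = t.tr_gene
    truth_probes = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": "chr1",
            "position": probe_pos,
            "atlas_member": atlas_member,
            "class": probe_class,
            "planted_tr": [planted_by.get(i, "") for i in range(cfg.n_probes)],
        }
    )

    link_rows = []
    for t in cfg.planted_activated_trs:
        if t.delta_beta > 0 and t.expression_shift_sd > 0:
            for i in planted_probe_idx[t.tr_gene]:
                link_rows.append((t.tr_gene, probe_ids[i], "activated"))
    for t in cfg.planted_inactivated_trs:
        if t.delta_beta > 0 and t.expression_shift_sd > 0:
            for i in planted_probe_idx[t.tr_gene]:
                link_rows.append((t.tr_gene, probe_ids[i], "inactivated"))
    truth_links = pd.DataFrame(
        link_rows, columns=["tr_gene", "probe_id", "direction"]
    )

    # ---- survival: hazard scales with true-link burden
    active_cut = 0.4
    burden = np.zeros(cfg.n_tumor)
    for _, row in truth_links.iterrows():
        i = probe_ids.index(row["probe_id"])
        burden += beta_vals[i, cfg.n_normal :] < active_cut
    hazard = cfg.baseline_hazard * cfg.hazard_ratio_per_link**burden
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / cfg.censoring_hazard, size=cfg.n_tumor)
    time_t = np.minimum(t_event, t_cens)
    event_t = (t_event <= t_cens).astype(int)
    time_n = rng.exponential(1.0 / cfg.baseline_hazard, size=cfg.n_normal)

    age = rng.integers(40, 85, size=len(samples))
    clinical = ClinicalTable(
        data=pd.DataFrame(
            {
                "sample_id": samples,
                "group": ["normal"] * cfg.n_normal + ["tumor"] * cfg.n_tumor,
                "time": np.round(np.concatenate([time_n, time_t]), 1),
                "event": np.concatenate(
                    [np.ones(cfg.n_normal, int), event_t]
                ),
                "age": age,
            }
        )
    )

    truth_samples = pd.DataFrame({"sample_id": tumor_ids, "true_burden": burden.astype(int)})
    for t in cfg.planted_activated_trs + cfg.planted_inactivated_trs:
        flags = np.zeros(cfg.n_tumor, bool)
        flags[affected[t.tr_gene]] = True
        truth_samples[f"affected_{t.tr_gene}"] = flags

    # ---- TADs (two sources, phase-shifted tilings of chr1)
    chr1_len = int(probe_pos[-1]) + spacing
    tads = {
        "cellA": _tile_tads("chr1", chr1_len, cfg.tad_size_bp, 0, "cellA"),
        "cellB": _tile_tads("chr1", chr1_len, cfg.tad_size_bp,
                            cfg.tad_size_bp // 2, "cellB"),
    }

    # ---- knockdown DE tables for the first two planted activated TRs
    de_tables: dict[str, pd.DataFrame] = {}
    for t in cfg.planted_activated_trs[:2]:
        down = sorted(
            {gene_ids[i % cfg.n_genes] for i in planted_probe_idx[t.tr_gene]}
        )
        n_decoys = min(200, cfg.n_genes // 2)
        decoys = [g for g in rng.choice(gene_ids, size=n_decoys, replace=False)
                  if g not in down]
        rows = [
            {"gene_id": g, "log2fc": float(rng.normal(-1.0, 0.2)),
             "adjusted_p": float(10 ** rng.uniform(-9, -4))}
            for g in down
        ] + [
            {"gene_id": g, "log2fc": float(rng.normal(0.0, 0.3)),
             "adjusted_p": float(rng.uniform(0.2, 1.0))}
            for g in decoys
        ]
        de_tables[t.tr_gene] = pd.DataFrame(rows).set_index("gene_id", drop=False)

    # ---- motif sub-fixture on its own contig
    genome, motif_pwm, motif_probes, planted_ids = _motif_fixture(cfg, rng)

    return FixtureBundle(
        config=cfg,
        enhancer_sets=enhancer_sets,
        open_sets=open_sets,
        manifest=manifest,
        tss=tss,
        beta=beta,
        expr=expr,
        clinical=clinical,
        trs=trs,
        tads=tads,
        de_tables=de_tables,
        genome=genome,
        motif_pwm=motif_pwm,
        motif_probes=motif_probes,
        motif_planted_ids=planted_ids,
        truth_probes=truth_probes,
        truth_links=truth_links,
        truth_samples=truth_samples,
    )


def _tile_tads(chrom: str, length: int, size: int, phase: int, source: str):
    tads = []
    start = 0
    if phase > 0:
        tads.append(TadRegion(chrom, 0, phase, source=source))
        start = phase
    while start < length:
        tads.append(TadRegion(chrom, start, start + size, source=source))
        start += size
    return tads


def _motif_fixture(cfg: FixtureConfig, rng: np.random.Generator):
    """Random contig with a sharp-consensus PWM planted at the centre of a
    chosen subset of probe windows.

    To give an exactly known planted fraction, chance occurrences of the
    consensus (or its reverse complement) outside the planted sites are
    scrubbed by mutating one base — a fixture-construction step, not a
    property of real genomes.
    """
    width = cfg.motif_width
    spacing = cfg.motif_window_spacing
    n = cfg.n_motif_windows
    length = (n + 1) * spacing
    seq = rng.integers(0, 4, size=length)
    consensus = rng.integers(0, 4, size=width)

    probs = np.full((width, 4), 0.001)
    probs[np.arange(width), consensus] = 0.997
    pwm = Pwm(motif_id="PLANTED", probabilities=probs)

    positions = [spacing // 2 + i * spacing for i in range(n)]
    planted = set(rng.choice(n, size=cfg.n_motif_planted, replace=False).tolist())
    plant_sites = []
    for i in sorted(planted):
        site = positions[i] - width // 2
        seq[site : site + width] = consensus
        plant_sites.append(site)

    comp = np.array([3, 2, 1, 0])
    rc_consensus = comp[consensus][::-1]
    plant_set = set(plant_sites)
    for _ in range(20):  # scrub chance off-target occurrences
        dirty = []
        for pat in (consensus, rc_consensus):
            windows = np.lib.stride_tricks.sliding_window_view(seq, width)
            matches = np.flatnonzero((windows == pat).all(axis=1))
            dirty += [m for m in matches if m not in plant_set]
        if not dirty:
            break
        for m in dirty:
            j = m + width // 2
            if j in {s + k for s in plant_set for k in range(width)}:
                j = m  # avoid mutating inside a planted site
            seq[j] = (seq[j] + 1 + rng.integers(0, 3)) % 4

    contig = "".join(_BASES[b] for b in seq)
    probes = [(f"mp{i:03d}", "chrS", positions[i]) for i in range(n)]
    planted_ids = {f"mp{i:03d}" for i in planted}
    return {"chrS": contig}, pwm, probes, planted_ids
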