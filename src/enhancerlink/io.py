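"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(BED convention).  Formats that use 1-based coordinates (GTF, HM450-style
probe manifests) are converted on read and converted back on write.  Every
reader validates its input and raises :class:`ParseError` (malformed text,
with a line number) or :class:`ValidationError` (well-formed text violating
a domain invariant, e.g. a beta value outside [0, 1]).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed input violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open.

    ``source`` tags the dataset the interval came from (e.g. the peak file
    name); merged intervals carry comma-joined tags.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    source: str | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("region chromosome name must be non-empty")
        if self.start < 0:
            raise ValidationError(f"region start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"region end {self.end} <= start {self.start} on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position < self.end


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site, 0-based, one per transcript."""

    gene_id: str
    chrom: str
    position: int
    strand: str
    transcript_id: str | None = None

    def __post_init__(self):
        if self.position < 0:
            raise ValidationError(f"TSS position {self.position} < 0")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"TSS strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class ProbeManifestRecord:
    """An array probe with its single CpG coordinate (0-based)."""

    probe_id: str
    chrom: str
    position: int

    def __post_init__(self):
        if self.position < 0:
            raise ValidationError(f"probe {self.probe_id} position < 0")


# ---------------------------------------------------------------------------
# Matrix containers
# ---------------------------------------------------------------------------


@dataclass
class MethylationMatrix:
    """Beta values, probes x samples, NaN = missing. All values in [0, 1]."""

    beta: pd.DataFrame

    def __post_init__(self):
        _check_unique(self.beta.index, "probe")
        _check_unique(self.beta.columns, "sample")
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValidationError(
                f"beta value {vals[i, j]} outside [0,1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes x samples.

    ``transform`` records the stored scale: ``linear`` (non-negative
    normalized values) or ``log2p1`` (log2(x+1)).  Fold changes are computed
    on the linear scale and correlations on the log scale, so both views are
    exposed regardless of the stored scale.
    """

    values: pd.DataFrame
    transform: str = "linear"

    def __post_init__(self):
        if self.transform not in ("linear", "log2p1"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals[~np.isnan(vals)])):
            raise ValidationError("expression values must be finite")
        if np.nanmin(vals) < 0 and self.transform == "linear":
            raise ValidationError("linear expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2(self) -> pd.DataFrame:
        """Expression on the log2(x+1) scale."""
        if self.transform == "log2p1":
            return self.values
        return np.log2(self.values + 1.0)

    def linear(self) -> pd.DataFrame:
        """Expression on the linear scale."""
        if self.transform == "linear":
            return self.values
        return 2.0 ** self.values - 1.0


@dataclass
class ClinicalTable:
    """Per-sample group labels, survival times (days) and event flags.

    ``data`` must contain columns sample_id, group, time, event; any further
    columns are treated as covariates.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "group", "time", "event")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
        _check_unique(self.data["sample_id"], "sample")
        if not set(self.data["group"]) <= {"normal", "tumor"}:
            bad = sorted(set(self.data["group"]) - {"normal", "tumor"})
            raise ValidationError(f"unknown group labels {bad}")
        if (self.data["time"].dropna() < 0).any():
            raise ValidationError("survival times must be >= 0")
        if not set(self.data["event"].dropna()) <= {0, 1}:
            raise ValidationError("event flags must be 0 or 1")
        self.data = self.data.set_index("sample_id", drop=False)

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.data.loc[self.data["group"] == "tumor", "sample_id"])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.data.loc[self.data["group"] == "normal", "sample_id"])

    def survival(self, samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(times, events) for the given samples, dropping missing entries."""
        sub = self.data.loc[list(samples), ["time", "event"]].dropna()
        return sub["time"].to_numpy(float), sub["event"].to_numpy(int)

    @property
    def covariates(self) -> pd.DataFrame:
        extra = [c for c in self.data.columns if c not in self.REQUIRED]
        return self.data[extra]


def _check_unique(labels, what: str) -> None:
    dup = pd.Index(labels).duplicated()
    if dup.any():
        first = pd.Index(labels)[dup][0]
        raise ValidationError(f"duplicate {what} ID {first!r}")


# ---------------------------------------------------------------------------
# Region files (BED / narrowPeak)
# ---------------------------------------------------------------------------


def _normalize_chrom(chrom: str, chrom_prefix: str | None) -> str:
    if chrom_prefix == "add" and not chrom.startswith("chr"):
        return "chr" + chrom
    if chrom_prefix == "strip" and chrom.startswith("chr"):
        return chrom[3:]
    return chrom


def read_regions(
    path: str | Path,
    format: str = "bed",
    source: str | None = None,
    chrom_prefix: str | None = None,
) -> list[GenomicRegion]:
    """Read BED3+/narrowPeak intervals as 0-based half-open regions.

    narrowPeak summit/statistic columns (5-10) are ignored; only chrom,
    start, end and name survive.  ``chrom_prefix`` may be ``"add"`` or
    ``"strip"`` to canonicalise chromosome naming across mixed sources.
    """
    if format not in ("bed", "narrowpeak"):
        raise ValueError(f"unknown region format {format!r}")
    path = Path(path)
    if source is None:
        source = path.name
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
            try:
                regions.append(
                    GenomicRegion(
                        chrom=_normalize_chrom(fields[0], chrom_prefix),
                        start=start,
                        end=end,
                        name=name,
                        source=source,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path.name}:{lineno}: {exc}") from None
    return regions


def write_regions(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED4 (name '.' when absent)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\n")


# ---------------------------------------------------------------------------
# GTF transcription start sites
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_tss(
    path: str | Path,
    feature: str = "transcript",
    one_per_gene: bool = False,
) -> list[TssRecord]:
    """Extract TSS records from a GENCODE-style GTF.

    GTF coordinates are 1-based inclusive; the TSS is ``start - 1`` on the
    + strand and ``end - 1`` on the - strand, yielding a 0-based point.  By
    default every transcript contributes a TSS; ``one_per_gene`` keeps only
    the most upstream TSS per gene (5'-most with respect to strand).
    """
    path = Path(path)
    records: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path.name}:{lineno}: expected 9 GTF fields")
            if fields[2] != feature:
                continue
            strand = fields[6]
            if strand not in ("+", "-"):
                raise ValidationError(
                    f"{path.name}:{lineno}: missing or invalid strand {strand!r}"
                )
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path.name}:{lineno}: no gene_id attribute")
            start, end = int(fields[3]), int(fields[4])
            position = start - 1 if strand == "+" else end - 1
            records.append(
                TssRecord(
                    gene_id=gene_id,
                    chrom=fields[0],
                    position=position,
                    strand=strand,
                    transcript_id=attrs.get("transcript_id"),
                )
            )
    if one_per_gene:
        best: dict[str, TssRecord] = {}
        for rec in records:
            cur = best.get(rec.gene_id)
            if cur is None:
                best[rec.gene_id] = rec
            elif (rec.strand == "+" and rec.position < cur.position) or (
                rec.strand == "-" and rec.position > cur.position
            ):
                best[rec.gene_id] = rec
        records = list(best.values())
    return records


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path, chrom_prefix: str | None = None) -> list[ProbeManifestRecord]:
    """Read a probe manifest TSV: probe_id, chrom, position (1-based in the
    file, converted to 0-based).  A header line starting with 'probe' is
    allowed and skipped."""
    path = Path(path)
    records: list[ProbeManifestRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower().startswith("probe"):
                continue
            if len(fields) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected 3 fields")
            probe_id = fields[0]
            if probe_id in seen:
                raise ValidationError(
                    f"{path.name}:{lineno}: duplicate probe ID {probe_id!r}"
                )
            seen.add(probe_id)
            try:
                pos1 = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from None
            records.append(
                ProbeManifestRecord(
                    probe_id=probe_id,
                    chrom=_normalize_chrom(fields[1], chrom_prefix),
                    position=pos1 - 1,
                )
            )
    return records


def write_manifest(records: Iterable[ProbeManifestRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tchrom\tposition\n")
        for r in records:
            fh.write(f"{r.probe_id}\t{r.chrom}\t{r.position + 1}\n")


# ---------------------------------------------------------------------------
# Matrices, clinical tables, gene lists, DE tables
# ---------------------------------------------------------------------------


def read_matrix(
    path: str | Path, kind: str, transform: str = "linear"
) -> MethylationMatrix | ExpressionMatrix:
    """Read a feature x sample TSV (first row sample IDs, first column
    feature IDs).  'NA' and empty cells parse as missing."""
    if kind not in ("beta", "expression"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA", ""],
        float_precision="round_trip",
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.astype(float)
    if kind == "beta":
        return MethylationMatrix(beta=df)
    return ExpressionMatrix(values=df, transform=transform)


def write_matrix(matrix: MethylationMatrix | ExpressionMatrix, path: str | Path) -> None:
    df = matrix.beta if isinstance(matrix, MethylationMatrix) else matrix.values
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    return ClinicalTable(data=df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line (used for the TR catalogue)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Knockdown differential-expression table: gene_id, log2fc, adjusted_p."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "log2fc", "adjusted_p"):
        if col not in df.columns:
            raise ValidationError(f"DE table missing column {col!r}")
    p = df["adjusted_p"].dropna()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("DE adjusted_p outside [0,1]")
    return df.set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

# The probability rows must survive parsing exactly as written, so this is a
# direct text parser for the minimal dialect (version header, optional
# alphabet/strands/background lines, letter-probability matrix blocks).

_BASES = "ACGT"


def read_meme_motifs(path: str | Path, tol: float = 1e-6):
    """Parse a MEME-minimal motif file into a list of :class:`~enhancerlink.motif.Pwm`.

    Each probability row must sum to 1 within ``tol``.  Background
    frequencies default to uniform when the file omits them.
    """
    from .motif import Pwm  # local import: motif depends on nothing here

    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if not any(l.lower().startswith("meme version") for l in lines):
        raise ParseError(f"{path.name}: missing 'MEME version' header")

    background = np.full(4, 0.25)
    motifs: list = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[k]: float(toks[k + 1]) for k in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in _BASES])
            if abs(background.sum() - 1.0) > tol:
                raise ValidationError(f"{path.name}: background does not sum to 1")
        elif line.startswith("MOTIF"):
            toks = line.split()
            motif_id = toks[1] if len(toks) > 1 else f"motif{len(motifs) + 1}"
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise ParseError(
                        f"{path.name}: motif {motif_id} has no probability matrix"
                    )
                j += 1
            if j >= len(lines):
                raise ParseError(
                    f"{path.name}: motif {motif_id} has no probability matrix"
                )
            header = lines[j].strip()
            m = re.search(r"w=\s*(\d+)", header)
            if m is None:
                raise ParseError(f"{path.name}:{j + 1}: matrix header lacks 'w='")
            width = int(m.group(1))
            rows = []
            for k in range(width):
                toks = lines[j + 1 + k].split()
                if len(toks) < 4:
                    raise ParseError(
                        f"{path.name}:{j + 2 + k}: expected 4 probabilities"
                    )
                row = np.array([float(t) for t in toks[:4]])
                if abs(row.sum() - 1.0) > tol:
                    raise ValidationError(
                        f"{path.name}:{j + 2 + k}: probability row sums to "
                        f"{row.sum():.8f}, not 1"
                    )
                rows.append(row)
            motifs.append(
                Pwm(
                    motif_id=motif_id,
                    probabilities=np.vstack(rows),
                    background=background.copy(),
                )
            )
            i = j + width
        i += 1
    return motifs


def write_meme_motifs(motifs, path: str | Path) -> None:
    """Write PWMs in MEME-minimal format (uniform strands, shared background)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(
                " ".join(f"{b} {bg[k]:.6f}" for k, b in enumerate(_BASES)) + "\n\n"
            )
        for pwm in motifs:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probabilities:
                fh.write(" ".join(f"{v:.10f}" for v in row) + "\n")
            fh.write("\n")
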