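"""PWM motif scanning of enhancer-probe windows.

Sequence windows centred on linked probes (half-width default 1,117 bp,
half the mean enhancer length of the pooled peak set) are scanned on both
strands with log-odds position weight matrices.  Per-offset p-values are
exact tail probabilities of the log-odds score under the background model,
computed by dynamic programming over a discretized score distribution (the
approach FIMO takes); an offset is a hit when p <= the threshold (default
1e-4).  The per-motif enrichment statistic is the fraction of probe
windows containing at least one hit from any PWM variant of the motif set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GenomicRegion, ValidationError

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class Pwm:
    """Position weight matrix with background for log-odds scanning.

    probabilities: width x 4 (A, C, G, T), rows summing to 1.
    background: 4 base frequencies summing to 1.
    pseudocount: mixed into each probability as p + pseudocount * bg before
        the log-odds ratio, so zero entries stay finite.
    """

    motif_id: str
    probabilities: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, float)
        self.background = np.asarray(self.background, float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValidationError("PWM probabilities must be width x 4")
        if np.any(np.abs(self.probabilities.sum(axis=1) - 1.0) > 1e-6):
            raise ValidationError(f"PWM {self.motif_id}: rows must sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValidationError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    def score_matrix(self) -> np.ndarray:
        """Per-position log2-odds scores: log2((p + pc*bg) / bg)."""
        num = self.probabilities + self.pseudocount * self.background
        return np.log2(num / self.background)


@dataclass
class MotifScanParams:
    half_window_bp: int = 1117
    p_threshold: float = 1e-4
    scan_both_strands: bool = True
    granularity: float = 1e-3  # score discretization, in bits

    def __post_init__(self):
        if self.half_window_bp <= 0:
            raise ValidationError("half_window_bp must be positive")
        if not (0 < self.p_threshold <= 1):
            raise ValidationError("p_threshold must be in (0, 1]")


@dataclass(frozen=True)
class MotifHit:
    offset: int
    strand: str
    score: float
    p: float


def half_mean_enhancer_size(regions: list[GenomicRegion]) -> int:
    """Half the mean enhancer length, rounded to the nearest bp."""
    if not regions:
        raise ValidationError("need at least one region")
    mean_len = float(np.mean([len(r) for r in regions]))
    return int(round(mean_len / 2))


# ---------------------------------------------------------------------------
# Exact p-values by dynamic programming over the discretized score
# ---------------------------------------------------------------------------


def score_pvalue_table(pwm: Pwm, granularity: float = 1e-3):
    """Exact tail distribution of the discretized log-odds score under the
    background model.

    Scores are shifted and rounded to integer multiples of ``granularity``
    bits.  Returns (int_scores_offsets, tail) where ``tail[s]`` is
    P(integer score >= s) for the summed integer score s, plus the
    per-position integer score matrix needed to score sequences on the
    same lattice.
    """
    scores = pwm.score_matrix()
    int_scores = np.rint(scores / granularity).astype(np.int64)
    # shift each column so minimum is 0 for a compact DP table
    mins = int_scores.min(axis=1)
    shifted = int_scores - mins[:, None]
    max_total = int(shifted.max(axis=1).sum())
    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    bg = pwm.background
    for i in range(pwm.width):
        new = np.zeros_like(dist)
        for b in range(4):
            s = int(shifted[i, b])
            if bg[b] > 0:
                new[s:] += dist[: len(dist) - s or None] * bg[b]
        dist = new
    tail = np.cumsum(dist[::-1])[::-1]
    return int_scores, int(mins.sum()), tail


class PwmScanner:
    """Precomputed scanner for one PWM: integer score lattice + exact
    tail probabilities."""

    def __init__(self, pwm: Pwm, params: MotifScanParams | None = None):
        self.pwm = pwm
        self.params = params or MotifScanParams()
        self.int_scores, self._shift, self._tail = score_pvalue_table(
            pwm, self.params.granularity
        )
        self._shifted = self.int_scores - self.int_scores.min(axis=1)[:, None]

    def pvalue_of_int_score(self, total: int) -> float:
        """P(score >= total) for a summed integer lattice score."""
        idx = total - self._shift
        if idx <= 0:
            return 1.0
        if idx >= len(self._tail):
            return 0.0
        return float(self._tail[idx])

    def _scan_one_strand(self, seq: str, strand: str, window_len: int):
        w = self.pwm.width
        hits = []
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        idx = np.full(len(seq), -1, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            idx[codes == ord(b)] = i
        for off in range(len(seq) - w + 1):
            window = idx[off : off + w]
            if (window < 0).any():  # N at a scored position
                continue
            total = int(self.int_scores[np.arange(w), window].sum())
            p = self.pvalue_of_int_score(total)
            if p <= self.params.p_threshold:
                fwd_off = off if strand == "+" else window_len - w - off
                hits.append(
                    MotifHit(
                        offset=fwd_off,
                        strand=strand,
                        score=float(total * self.params.granularity),
                        p=p,
                    )
                )
        return hits

    def scan(self, sequence: str) -> list[MotifHit]:
        """All hits in ``sequence`` (both strands when configured).

        Offsets are 0-based starts of the motif occurrence on the forward
        strand coordinate system regardless of strand.
        """
        seq = sequence.upper()
        if len(seq) < self.pwm.width:
            return []
        hits = self._scan_one_strand(seq, "+", len(seq))
        if self.params.scan_both_strands:
            rc = seq.translate(_COMPLEMENT)[::-1]
            hits += self._scan_one_strand(rc, "-", len(seq))
        return sorted(hits, key=lambda h: (h.offset, h.strand))


def scan_window(
    sequence: str, pwm: Pwm, params: MotifScanParams | None = None
) -> list[MotifHit]:
    """Convenience wrapper: scan one sequence with one PWM."""
    return PwmScanner(pwm, params).scan(sequence)


# ---------------------------------------------------------------------------
# Enrichment over probe windows
# ---------------------------------------------------------------------------


def probe_window_sequence(genome, chrom: str, position: int, half_window: int) -> str:
    """Extract the +/- half_window sequence around a probe from a pyfaidx
    Fasta (or dict of strings), truncating at contig ends with a warning."""
    if hasattr(genome, "keys") and not hasattr(genome, "faidx"):
        contig = genome[chrom]
        contig_len = len(contig)
    else:
        contig = genome[chrom]
        contig_len = len(contig)
    start = position - half_window
    end = position + half_window + 1
    if start < 0 or end > contig_len:
        warnings.warn(
            f"probe window [{start},{end}) truncated to contig {chrom} bounds",
            stacklevel=2,
        )
        start, end = max(start, 0), min(end, contig_len)
    seq = contig[start:end]
    return str(seq)


def enrichment_fraction(
    probes: list[tuple[str, str, int]],
    genome,
    pwms: list[Pwm],
    params: MotifScanParams | None = None,
) -> float:
    """Fraction of probe windows with >= 1 hit from any PWM in the set.

    ``probes`` is a list of (probe_id, chrom, position).  Any of the
    motif's PWM variants counts (the pooled-per-TR rule).  NaN when the
    probe list is empty.
    """
    params = params or MotifScanParams()
    if not probes:
        return float("nan")
    scanners = [PwmScanner(pwm, params) for pwm in pwms]
    n_hit = 0
    for _probe_id, chrom, position in probes:
        seq = probe_window_sequence(genome, chrom, position, params.half_window_bp)
        if any(scanner.scan(seq) for scanner in scanners):
            n_hit += 1
    return n_hit / len(probes)


def hits_table(
    probes: list[tuple[str, str, int]],
    genome,
    pwms: list[Pwm],
    params: MotifScanParams | None = None,
):
    """Per-hit records (probe, motif, offset, strand, score, p) as a
    DataFrame, for TSV export."""
    import pandas as pd

    params = params or MotifScanParams()
    scanners = [(pwm.motif_id, PwmScanner(pwm, params)) for pwm in pwms]
    rows = []
    for probe_id, chrom, position in probes:
        seq = probe_window_sequence(genome, chrom, position, params.half_window_bp)
        for motif_id, scanner in scanners:
            for h in scanner.scan(seq):
                rows.append(
                    {
                        "probe_id": probe_id,
                        "motif": motif_id,
                        "offset": h.offset,
                        "strand": h.strand,
                        "score": h.score,
                        "p": h.p,
                    }
                )
    return pd.DataFrame(
        rows, columns=["probe_id", "motif", "offset", "strand", "score", "p"]
    )
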