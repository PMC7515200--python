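"""Enhancer-probe atlas construction.

Enhancer peaks (H3K27ac) from many datasets are pooled by union, open
chromatin peaks likewise, and the two merged sets are intersected.  Array
probes whose CpG falls inside the intersection and lies further than a
TSS-exclusion distance (default 1.5 kb) from every annotated TSS form the
atlas of distal enhancer probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GenomicRegion, ProbeManifestRecord, TssRecord, ValidationError


@dataclass
class AtlasParams:
    """Atlas construction parameters.

    tss_exclusion_bp: probes within this distance of any TSS are dropped
        (strict: retained iff min distance > threshold).
    merge_gap_bp: intervals closer than this are merged when pooling peaks.
    min_dataset_support: require a peak base to be covered by at least this
        many input datasets before merging (1 = plain union).
    """

    tss_exclusion_bp: int = 1500
    merge_gap_bp: int = 0
    min_dataset_support: int = 1

    def __post_init__(self):
        if self.tss_exclusion_bp < 0:
            raise ValidationError("tss_exclusion_bp must be >= 0")
        if self.min_dataset_support < 1:
            raise ValidationError("min_dataset_support must be >= 1")


@dataclass
class AtlasProbe:
    probe_id: str
    chrom: str
    position: int
    open_region: GenomicRegion
    enhancer_region: GenomicRegion


@dataclass
class EnhancerProbeAtlas:
    """Probes assigned to TSS-distal open-chromatin-within-enhancer loci."""

    probes: list[AtlasProbe]
    enhancer_regions: list[GenomicRegion]
    open_regions: list[GenomicRegion]
    params: AtlasParams

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "probe_id": p.probe_id,
                "chrom": p.chrom,
                "position": p.position,
                "open_start": p.open_region.start,
                "open_end": p.open_region.end,
                "enhancer_start": p.enhancer_region.start,
                "enhancer_end": p.enhancer_region.end,
                "sources": p.enhancer_region.source or "",
            }
            for p in self.probes
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "probe_id", "chrom", "position", "open_start", "open_end",
                "enhancer_start", "enhancer_end", "sources",
            ],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval algebra (sorted sweep; source tags propagated on merge)
# ---------------------------------------------------------------------------


def merge_regions(
    sets: Sequence[Sequence[GenomicRegion]], gap: int = 0
) -> list[GenomicRegion]:
    """Union all input interval sets, merging intervals within ``gap`` bp.

    Source tags of merged intervals are concatenated (comma-joined, unique,
    input order preserved).  Output sorted by (chrom, start).
    """
    pooled = [r for s in sets for r in s]
    if not pooled:
        return []
    pooled.sort(key=lambda r: (r.chrom, r.start, r.end))
    merged: list[GenomicRegion] = []
    cur_chrom, cur_start, cur_end = pooled[0].chrom, pooled[0].start, pooled[0].end
    cur_sources: list[str] = []

    def note_source(r: GenomicRegion):
        if r.source and r.source not in cur_sources:
            cur_sources.append(r.source)

    note_source(pooled[0])
    for r in pooled[1:]:
        if r.chrom == cur_chrom and r.start <= cur_end + gap:
            cur_end = max(cur_end, r.end)
            note_source(r)
        else:
            merged.append(
                GenomicRegion(cur_chrom, cur_start, cur_end,
                              source=",".join(cur_sources) or None)
            )
            cur_chrom, cur_start, cur_end = r.chrom, r.start, r.end
            cur_sources = []
            note_source(r)
    merged.append(
        GenomicRegion(cur_chrom, cur_start, cur_end,
                      source=",".join(cur_sources) or None)
    )
    return merged


def merge_with_support(
    sets: Sequence[Sequence[GenomicRegion]], gap: int = 0, min_support: int = 1
) -> list[GenomicRegion]:
    """Union with an optional dataset-support vote: keep bases covered by at
    least ``min_support`` of the input datasets, then gap-merge."""
    if min_support <= 1:
        return merge_regions(sets, gap=gap)
    # sweep over per-dataset merged intervals counting coverage depth
    events: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        for r in merge_regions([s]):
            events.setdefault(r.chrom, []).append((r.start, +1))
            events[r.chrom].append((r.end, -1))
    kept: list[GenomicRegion] = []
    for chrom in sorted(events):
        pts = sorted(events[chrom])
        depth, open_start = 0, None
        for pos, delta in pts:
            prev = depth
            depth += delta
            if prev < min_support <= depth:
                open_start = pos
            elif prev >= min_support > depth and open_start is not None:
                if pos > open_start:
                    kept.append(GenomicRegion(chrom, open_start, pos))
                open_start = None
    return merge_regions([kept], gap=gap)


def intersect_regions(
    a: Sequence[GenomicRegion], b: Sequence[GenomicRegion]
) -> list[GenomicRegion]:
    """Maximal intervals covered by both a and b (each merged first)."""
    am = merge_regions([a])
    bm = merge_regions([b])
    out: list[GenomicRegion] = []
    by_chrom_b: dict[str, list[GenomicRegion]] = {}
    for r in bm:
        by_chrom_b.setdefault(r.chrom, []).append(r)
    for chrom in sorted({r.chrom for r in am} & set(by_chrom_b)):
        ra = [r for r in am if r.chrom == chrom]
        rb = by_chrom_b[chrom]
        i = j = 0
        while i < len(ra) and j < len(rb):
            lo = max(ra[i].start, rb[j].start)
            hi = min(ra[i].end, rb[j].end)
            if lo < hi:
                src = ",".join(
                    s for s in (ra[i].source, rb[j].source) if s
                ) or None
                out.append(GenomicRegion(chrom, lo, hi, source=src))
            if ra[i].end < rb[j].end:
                i += 1
            else:
                j += 1
    return out


# ---------------------------------------------------------------------------
# TSS proximity filtering
# ---------------------------------------------------------------------------


def _tss_positions_by_chrom(tss: Sequence[TssRecord]) -> dict[str, np.ndarray]:
    by: dict[str, list[int]] = {}
    for t in tss:
        by.setdefault(t.chrom, []).append(t.position)
    return {c: np.array(sorted(v)) for c, v in by.items()}


def min_tss_distance(chrom: str, position: int, tss_index: dict[str, np.ndarray]) -> int:
    """Minimum |position - TSS| over all TSS; strand-ignored, point-to-point.
    Positions on chromosomes with no TSS are infinitely distant."""
    arr = tss_index.get(chrom)
    if arr is None or len(arr) == 0:
        return np.iinfo(np.int64).max
    i = int(np.searchsorted(arr, position))
    cand = []
    if i < len(arr):
        cand.append(abs(int(arr[i]) - position))
    if i > 0:
        cand.append(abs(position - int(arr[i - 1])))
    return min(cand)


def exclude_tss_proximal(
    probes: Sequence[ProbeManifestRecord],
    tss: Sequence[TssRecord],
    params: AtlasParams,
) -> list[ProbeManifestRecord]:
    """Keep probes whose minimum TSS distance is strictly greater than
    ``tss_exclusion_bp``.  An empty TSS list is an error: it would silently
    disable the filter."""
    if not tss:
        raise ValidationError("TSS list is empty; refusing to skip the TSS filter")
    index = _tss_positions_by_chrom(tss)
    return [
        p
        for p in probes
        if min_tss_distance(p.chrom, p.position, index) > params.tss_exclusion_bp
    ]


def exclude_tss_proximal_regions(
    regions: Sequence[GenomicRegion],
    tss: Sequence[TssRecord],
    params: AtlasParams,
) -> list[GenomicRegion]:
    """Drop any region overlapping a TSS +/- tss_exclusion_bp window."""
    if not tss:
        raise ValidationError("TSS list is empty; refusing to skip the TSS filter")
    index = _tss_positions_by_chrom(tss)
    kept = []
    for r in regions:
        arr = index.get(r.chrom)
        if arr is None:
            kept.append(r)
            continue
        # overlap iff some TSS in [start - d, end - 1 + d]
        d = params.tss_exclusion_bp
        i = np.searchsorted(arr, r.start - d)
        if i >= len(arr) or arr[i] > r.end - 1 + d:
            kept.append(r)
    return kept


# ---------------------------------------------------------------------------
# Atlas assembly
# ---------------------------------------------------------------------------


def _locate(regions: Sequence[GenomicRegion], chrom: str, position: int):
    """Binary-search the (sorted, disjoint) region list for a containing
    interval; None when absent."""
    lo, hi = 0, len(regions)
    while lo < hi:
        mid = (lo + hi) // 2
        r = regions[mid]
        if (r.chrom, r.start) <= (chrom, position):
            lo = mid + 1
        else:
            hi = mid
    if lo == 0:
        return None
    r = regions[lo - 1]
    return r if r.contains(chrom, position) else None


def build_atlas(
    enhancers: Sequence[Sequence[GenomicRegion]],
    open_chromatin: Sequence[Sequence[GenomicRegion]],
    manifest: Sequence[ProbeManifestRecord],
    tss: Sequence[TssRecord],
    params: AtlasParams | None = None,
) -> EnhancerProbeAtlas:
    """Assemble the enhancer-probe atlas.

    A probe enters the atlas iff its CpG coordinate falls inside the
    intersection of the merged enhancer and merged open-chromatin sets and
    it is TSS-distal.  Each atlas record keeps both containing intervals.
    """
    params = params or AtlasParams()
    enh = merge_with_support(enhancers, gap=params.merge_gap_bp,
                             min_support=params.min_dataset_support)
    oc = merge_with_support(open_chromatin, gap=params.merge_gap_bp,
                            min_support=params.min_dataset_support)
    both = intersect_regions(enh, oc)
    distal = exclude_tss_proximal(manifest, tss, params)
    probes: list[AtlasProbe] = []
    for p in distal:
        hit = _locate(both, p.chrom, p.position)
        if hit is None:
            continue
        enh_hit = _locate(enh, p.chrom, p.position)
        oc_hit = _locate(oc, p.chrom, p.position)
        probes.append(
            AtlasProbe(
                probe_id=p.probe_id,
                chrom=p.chrom,
                position=p.position,
                open_region=oc_hit,
                enhancer_region=enh_hit,
            )
        )
    if not probes:
        warnings.warn("enhancer-probe atlas is empty", stacklevel=2)
    return EnhancerProbeAtlas(
        probes=probes, enhancer_regions=enh, open_regions=oc, params=params
    )
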