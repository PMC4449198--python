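"""Trans-eQTL hotspot detection.

The observed coverage profile of eQTL support intervals is compared with a
null in which intervals of the same lengths are placed uniformly on a
single axis the size of the genome; regions whose observed coverage exceeds
the 95th percentile of the simulated per-iteration maximum coverage are
called clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval


@dataclass
class CoverageProfile:
    """Exact sweep-line coverage per chromosome.

    ``segments`` has columns chrom, start, end, depth; consecutive segments
    tile each chromosome from 0 to its length.
    """

    segments: pd.DataFrame
    genome: dict[str, float]
    unit: str = "Mb"

    def max_depth(self) -> int:
        return int(self.segments["depth"].max()) if len(self.segments) else 0

    def total_covered_mass(self) -> float:
        seg = self.segments
        return float(((seg["end"] - seg["start"]) * seg["depth"]).sum())

    def regions_above(self, threshold: float) -> list[GenomicInterval]:
        """Maximal regions with depth strictly above ``threshold``."""
        out = []
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            cur = None
            for _, row in sub.iterrows():
                if row["depth"] > threshold:
                    if cur is None:
                        cur = [row["start"], row["end"], row["depth"]]
                    elif np.isclose(row["start"], cur[1]):
                        cur[1] = row["end"]
                        cur[2] = max(cur[2], row["depth"])
                    else:
                        out.append((chrom, cur))
                        cur = [row["start"], row["end"], row["depth"]]
                else:
                    if cur is not None:
                        out.append((chrom, cur))
                        cur = None
            if cur is not None:
                out.append((chrom, cur))
        return [
            GenomicInterval(chrom, s, e, self.unit, "eqtl", label=f"depth{int(d)}")
            for chrom, (s, e, d) in out
        ]


def coverage(intervals: list[GenomicInterval], genome: dict[str, float]) -> CoverageProfile:
    """Exact interval coverage by sweep line, per chromosome."""
    rows = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r} ({iv.label!r})")
        if iv.end > genome[iv.chrom] + 1e-9:
            raise ValueError(
                f"interval {iv.label!r} ({iv.chrom}:{iv.start}-{iv.end}) exceeds "
                f"chromosome length {genome[iv.chrom]}"
            )
    for chrom, clen in genome.items():
        ivs = [iv for iv in intervals if iv.chrom == chrom]
        points = sorted({0.0, float(clen)} | {iv.start for iv in ivs} | {iv.end for iv in ivs})
        starts = np.array([iv.start for iv in ivs]) if ivs else np.empty(0)
        ends = np.array([iv.end for iv in ivs]) if ivs else np.empty(0)
        for a, b in zip(points[:-1], points[1:]):
            depth = int(np.sum((starts < b) & (ends > a))) if ivs else 0
            rows.append({"chrom": chrom, "start": a, "end": b, "depth": depth})
    unit = intervals[0].unit if intervals else "Mb"
    return CoverageProfile(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"]), dict(genome), unit
    )


def _max_coverage_1d(starts: np.ndarray, ends: np.ndarray) -> int:
    """Maximum overlap depth of intervals on one axis (event sweep)."""
    events = np.concatenate([starts, ends])
    deltas = np.concatenate([np.ones(len(starts)), -np.ones(len(ends))])
    order = np.lexsort((-deltas, events))  # starts before ends at ties
    return int(np.cumsum(deltas[order]).max())


def null_max_coverage(
    interval_lengths: np.ndarray,
    genome_length: float,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-iteration maximum coverage of uniformly placed intervals.

    Each iteration places every interval (preserving its observed length)
    with its start uniform on [0, genome_length - length] on one
    concatenated genome axis, and records the maximum overlap depth.
    """
    lengths = np.asarray(interval_lengths, dtype=float)
    if np.any(lengths >= genome_length):
        raise ValueError("every interval length must be smaller than the genome length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maxima = np.empty(n_iter, dtype=int)
    for b in range(n_iter):
        starts = rng.uniform(0.0, genome_length - lengths)
        maxima[b] = _max_coverage_1d(starts, starts + lengths)
    return maxima


@dataclass
class HotspotCall:
    region: GenomicInterval
    max_depth: int
    threshold: float
    overlapping_qtl: list[str]


def call_hotspots(
    observed: list[GenomicInterval],
    genome: dict[str, float],
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    qtl: list[GenomicInterval] | None = None,
) -> tuple[float, list[HotspotCall], np.ndarray]:
    """Empirical hotspot calls.

    Returns (threshold, calls, null maxima).  The threshold is the
    (1 - alpha) percentile of the simulated maximum coverage using the
    observed intervals' lengths; calls are maximal regions of the observed
    coverage profile with depth strictly above it.
    """
    lengths = np.array([iv.length for iv in observed], dtype=float)
    genome_length = float(sum(genome.values()))
    maxima = null_max_coverage(lengths, genome_length, n_iter=n_iter, seed=seed)
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    profile = coverage(observed, genome)
    calls = []
    for region in profile.regions_above(threshold):
        depth = int(region.label.replace("depth", ""))
        overlapping = []
        if qtl:
            for q in qtl:
                if q.chrom == region.chrom and q.start <= region.end and region.start <= q.end:
                    overlapping.append(q.label)
        calls.append(
            HotspotCall(
                region=region, max_depth=depth, threshold=threshold, overlapping_qtl=overlapping
            )
        )
    return threshold, calls, maxima


def read_chrom_sizes(path) -> dict[str, float]:
    """Two-column name/length file (chrom.sizes convention)."""
    genome = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, length = line.split()[:2]
            genome[name] = float(length)
    return genome
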