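"""Genome-wide SV characterization: window densities, GC, sizes, repeat overlap.

Windows tile each chromosome without overlap (default width 200 kb, the
terminal remainder included); an SV is assigned to the window containing
its start coordinate.  Overlap with repeats is counted at >= 1 shared bp,
with insertions represented by their 1-bp breakpoint interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from intervaltree import IntervalTree

from migrasv.io import GenomeLayout, RepeatAnnotation, SVRecord

__all__ = [
    "window_density",
    "gc_fraction",
    "spearman",
    "repeat_overlap",
    "size_spectrum",
    "RepeatOverlapSummary",
    "SizeSpectrum",
]


def window_density(
    loci: Sequence[SVRecord],
    layout: GenomeLayout,
    window: int = 200_000,
    with_gc: bool = False,
) -> pd.DataFrame:
    """Count SVs per non-overlapping window.

    Returns a frame with columns ``chrom, start, end, sv_count`` (plus
    ``gc_fraction`` when ``with_gc`` and the layout has sequence).  The sum
    of ``sv_count`` equals the number of loci (conservation).
    """
    starts_by_chrom: dict[str, list[int]] = {name: [] for name in layout.names}
    for rec in loci:
        layout.check_interval(rec.chrom, rec.start, rec.start + 1)
        starts_by_chrom[rec.chrom].append(rec.start)
    rows = []
    for chrom in layout.names:
        length = layout.length(chrom)
        edges = np.append(np.arange(0, length, window), length)
        counts, _ = np.histogram(starts_by_chrom[chrom], bins=edges)
        for i, count in enumerate(counts):
            row = {
                "chrom": chrom,
                "start": int(edges[i]),
                "end": int(edges[i + 1]),
                "sv_count": int(count),
            }
            if with_gc and layout.has_sequence:
                row["gc_fraction"] = gc_fraction(layout, chrom, int(edges[i]), int(edges[i + 1]))
            rows.append(row)
    return pd.DataFrame(rows)


def gc_fraction(layout: GenomeLayout, chrom: str, start: int, end: int) -> float:
    """(#G + #C) / (#A + #C + #G + #T) in the window; Ns excluded.

    Returns NaN for an all-N window.
    """
    seq = layout.sequence(chrom, start, end).upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    return gc / denom if denom else float("nan")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value.

    Pairs with a missing member are dropped; >= 4 complete pairs and
    non-constant vectors are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError("spearman needs >= 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class RepeatOverlapSummary:
    """Fraction of SVs touching a repeat, and per-class shares of the
    overlapping (SV, repeat element) pairs."""

    n_svs: int
    n_overlapping: int
    fraction_overlapping: float
    class_shares: dict[str, float]
    n_pairs: int


def repeat_overlap(loci: Sequence[SVRecord], repeats: RepeatAnnotation) -> RepeatOverlapSummary:
    """Overlap SVs with the repeat track (>= 1 shared bp, strand-agnostic).

    Each repeat element overlapping an SV counts once per SV in the
    per-class shares; the shares sum to 1 whenever any pair exists.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, g in repeats.table.groupby("chrom", sort=False):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e), cls)
            for s, e, cls in zip(g["start"], g["end"], g["repeat_class"])
        )
    n_overlapping = 0
    class_counts: dict[str, int] = {}
    for rec in loci:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        hits = tree.overlap(rec.start, rec.end)
        if hits:
            n_overlapping += 1
            for hit in hits:
                class_counts[hit.data] = class_counts.get(hit.data, 0) + 1
    n_pairs = sum(class_counts.values())
    shares = {cls: cnt / n_pairs for cls, cnt in sorted(class_counts.items())} if n_pairs else {}
    n = len(loci)
    return RepeatOverlapSummary(
        n_svs=n,
        n_overlapping=n_overlapping,
        fraction_overlapping=n_overlapping / n if n else float("nan"),
        class_shares=shares,
        n_pairs=n_pairs,
    )


@dataclass
class SizeSpectrum:
    """Per-SV-type length summaries (lower-median convention)."""

    lengths: dict[str, np.ndarray]
    summary: pd.DataFrame  # columns: svtype, n, median, min, max


def _lower_median(values: np.ndarray) -> int:
    ordered = np.sort(values)
    return int(ordered[(len(ordered) - 1) // 2])


def size_spectrum(loci: Sequence[SVRecord]) -> SizeSpectrum:
    """Length distribution per SV type; types without loci are omitted."""
    lengths: dict[str, list[int]] = {}
    for rec in loci:
        lengths.setdefault(rec.svtype, []).append(rec.length)
    arrays = {t: np.asarray(v) for t, v in sorted(lengths.items())}
    rows = [
        {
            "svtype": t,
            "n": len(v),
            "median": _lower_median(v),
            "min": int(v.min()),
            "max": int(v.max()),
        }
        for t, v in arrays.items()
    ]
    return SizeSpectrum(lengths=arrays, summary=pd.DataFrame(rows))
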