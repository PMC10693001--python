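"""Population-genetic statistics over the cohort dosage matrix.

Implements the folded allele-frequency spectrum, Tajima's D, the Hudson
FST estimator with ratio-of-averages genome-wide weighting, the
three-population branch statistic (PBS), outlier-gene extraction, LD decay
profiles inside inversions versus size-matched colinear controls, and a
smartpca-style PCA on standardized dosages.

Conventions
-----------
FST per locus uses the finite-sample Hudson estimator

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

with allele-copy counts n and alt frequencies p per population; loci with
den = 0 are flagged undefined (NaN).  Genome-wide FST is sum(num)/sum(den).
For PBS, per-locus FST is clamped to [0, 1-1e-12] and transformed to a
branch length T = -ln(1 - FST); the focal group's branch is
PBS_X = (T_XY + T_XZ - T_YZ) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from migrasv.io import MISSING, GeneAnnotation, GenomeLayout, SVRecord
from migrasv.svmerge import CohortSVMatrix

__all__ = [
    "AlleleCounts",
    "allele_counts",
    "FoldedAFS",
    "folded_afs",
    "svtype_categories",
    "tajimas_d",
    "hudson_fst",
    "fst_genomewide",
    "PBSResult",
    "pbs",
    "pbs_outlier_loci",
    "pbs_outlier_genes",
    "LDProfile",
    "ld_profile",
    "PCAResult",
    "pca",
]


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------


@dataclass
class AlleleCounts:
    """Per-locus allele-copy totals (n) and alt-allele copies (k)."""

    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.k > self.n) or np.any(self.k < 0):
            raise ValueError("allele counts require 0 <= k <= n")

    @property
    def p(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.k / np.maximum(self.n, 1), np.nan)


def allele_counts(
    matrix: CohortSVMatrix, groups: Mapping[str, Sequence[int]] | None = None
) -> dict[str, AlleleCounts]:
    """Alt-allele counts per population (column-index groups; default all)."""
    if groups is None:
        groups = {"all": list(range(matrix.n_individuals))}
    out = {}
    for name, idx in groups.items():
        sub = matrix.dosages[:, list(idx)]
        obs = sub != MISSING
        out[name] = AlleleCounts(
            n=2 * obs.sum(axis=1), k=np.where(obs, sub, 0).sum(axis=1)
        )
    return out


# ---------------------------------------------------------------------------
# folded AFS
# ---------------------------------------------------------------------------


@dataclass
class FoldedAFS:
    """Histogram of minor-allele copy counts for one locus category.

    ``bins[i]`` is the number of polymorphic loci whose minor allele is
    carried by ``i`` copies (``i`` runs 1..n_copies/2; index 0 unused).
    Loci at exactly frequency 0.5 fall in the top folded bin by the
    min(k, n-k) fold.  Monomorphic loci are excluded and counted.
    """

    category: str
    n_copies: int
    bins: np.ndarray
    n_monomorphic_excluded: int

    @property
    def n_polymorphic(self) -> int:
        return int(self.bins.sum())


def svtype_categories(loci: Sequence[SVRecord], pool_indels: bool = True) -> np.ndarray:
    """Per-locus category labels; insertions and deletions pool as INDEL."""
    return np.array(
        ["INDEL" if pool_indels and r.svtype in ("INS", "DEL") else r.svtype for r in loci]
    )


def folded_afs(
    matrix: CohortSVMatrix, categories: Sequence[str] | None = None
) -> dict[str, FoldedAFS]:
    """Folded AFS per locus category (all loci together when ``categories`` is None)."""
    if categories is None:
        categories = np.array(["all"] * matrix.n_loci)
    categories = np.asarray(categories)
    if categories.shape[0] != matrix.n_loci:
        raise ValueError("categories must assign one label per locus")
    obs = matrix.dosages != MISSING
    n = 2 * obs.sum(axis=1)
    k = np.where(obs, matrix.dosages, 0).sum(axis=1)
    minor = np.minimum(k, n - k)
    n_max = 2 * matrix.n_individuals
    out = {}
    for cat in sorted(set(categories.tolist())):
        sel = categories == cat
        m = minor[sel]
        poly = m > 0
        bins = np.bincount(m[poly], minlength=n_max // 2 + 1)
        out[cat] = FoldedAFS(
            category=str(cat),
            n_copies=n_max,
            bins=bins,
            n_monomorphic_excluded=int((~poly).sum()),
        )
    return out


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def tajimas_d(matrix: CohortSVMatrix | np.ndarray) -> float:
    """Tajima's D over the loci of the matrix.

    Loci with missing genotypes are dropped so the allele-copy count n is
    uniform; monomorphic loci do not contribute to S.  Uses the standard
    constants a1, a2, b1, b2, c1, c2, e1, e2 derived from n, with
    pi-hat = sum(2 p q) * n/(n-1) and theta_W = S / a1.
    """
    dosages = matrix.dosages if isinstance(matrix, CohortSVMatrix) else np.asarray(matrix)
    complete = ~(dosages == MISSING).any(axis=1)
    dosages = dosages[complete]
    n = 2 * dosages.shape[1]
    if n < 4:
        raise ValueError("Tajima's D needs >= 2 diploid individuals")
    k = dosages.sum(axis=1)
    poly = (k > 0) & (k < n)
    S = int(poly.sum())
    if S == 0:
        raise ValueError("Tajima's D undefined: no polymorphic loci")
    p = k[poly] / n
    pi_hat = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    theta_w = S / a1
    return (pi_hat - theta_w) / np.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# Hudson FST / PBS
# ---------------------------------------------------------------------------


def hudson_fst(
    c1: AlleleCounts, c2: AlleleCounts
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Hudson FST components ``(numerator, denominator, fst)``.

    Loci where the denominator is zero (both populations fixed for the
    same or opposite alleles ... only same-allele fixation) get NaN FST.
    """
    if np.any(c1.n < 2) or np.any(c2.n < 2):
        raise ValueError("Hudson FST needs >= 2 allele copies per population")
    p1, p2 = c1.p, c2.p
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (c1.n - 1) - p2 * (1 - p2) / (c2.n - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return num, den, fst


def fst_genomewide(num: np.ndarray, den: np.ndarray) -> float:
    """Ratio-of-averages genome-wide FST: sum(num) / sum(den)."""
    ok = np.isfinite(num) & np.isfinite(den)
    total_den = float(np.sum(den[ok]))
    if not ok.any() or total_den == 0:
        raise ValueError("genome-wide FST undefined: zero total denominator")
    return float(np.sum(num[ok]) / total_den)


@dataclass
class PBSResult:
    """Per-locus pairwise FST, branch lengths and PBS per focal group."""

    groups: tuple[str, str, str]
    locus_index: np.ndarray  # indices into the original locus list
    fst: dict[tuple[str, str], np.ndarray]
    branch_t: dict[tuple[str, str], np.ndarray]
    pbs: dict[str, np.ndarray]
    n_dropped_undefined: int

    def frame(self) -> pd.DataFrame:
        data = {"locus_index": self.locus_index}
        for pair, values in self.fst.items():
            data[f"fst_{pair[0]}_{pair[1]}"] = values
        for group, values in self.pbs.items():
            data[f"pbs_{group}"] = values
        return pd.DataFrame(data)


def pbs(counts: Mapping[str, AlleleCounts]) -> PBSResult:
    """Population branch statistic for three populations.

    Loci with any undefined pairwise FST are dropped (counted).  FST is
    clamped to [0, 1-1e-12] before T = -ln(1-FST), so branch lengths are
    non-negative; PBS itself may be negative.
    """
    if len(counts) != 3:
        raise ValueError("PBS requires exactly three populations")
    a, b, c = tuple(counts)
    pairs = [(a, b), (a, c), (b, c)]
    fst = {}
    for x, y in pairs:
        _, _, f = hudson_fst(counts[x], counts[y])
        fst[(x, y)] = f
    defined = np.ones(len(fst[(a, b)]), dtype=bool)
    for f in fst.values():
        defined &= np.isfinite(f)
    index = np.flatnonzero(defined)
    branch = {
        pair: -np.log1p(-np.clip(f[defined], 0.0, 1.0 - 1e-12))
        for pair, f in fst.items()
    }

    def t_of(x: str, y: str) -> np.ndarray:
        return branch[(x, y)] if (x, y) in branch else branch[(y, x)]

    pbs_values = {
        x: 0.5 * (t_of(x, y) + t_of(x, z) - t_of(y, z))
        for x, y, z in ((a, b, c), (b, a, c), (c, a, b))
    }
    return PBSResult(
        groups=(a, b, c),
        locus_index=index,
        fst={pair: f[defined] for pair, f in fst.items()},
        branch_t=branch,
        pbs=pbs_values,
        n_dropped_undefined=int((~defined).sum()),
    )


def pbs_outlier_loci(values: np.ndarray, quantile: float = 0.95) -> np.ndarray:
    """Boolean mask of loci at or above the empirical quantile (ties included)."""
    threshold = np.quantile(values, quantile, method="higher")
    return values >= threshold


def pbs_outlier_genes(
    result: PBSResult,
    loci: Sequence[SVRecord],
    genes: GeneAnnotation,
    quantile: float = 0.95,
) -> dict[str, list[str]]:
    """Genes overlapping (>= 1 bp) top-quantile PBS loci, per focal group."""
    trees: dict[str, IntervalTree] = {}
    for chrom, g in genes.table.groupby("chrom", sort=False):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e), gid)
            for s, e, gid in zip(g["start"], g["end"], g["gene_id"])
        )
    out: dict[str, list[str]] = {}
    for group, values in result.pbs.items():
        mask = pbs_outlier_loci(values, quantile)
        found: dict[str, None] = {}
        for li in result.locus_index[mask]:
            rec = loci[int(li)]
            tree = trees.get(rec.chrom)
            if tree is None:
                continue
            for hit in sorted(tree.overlap(rec.start, rec.end)):
                found.setdefault(hit.data, None)
        out[group] = list(found)
    return out


# ---------------------------------------------------------------------------
# LD inside inversions vs colinear controls
# ---------------------------------------------------------------------------


@dataclass
class LDProfile:
    """Binned mean r^2 against pairwise distance for one stratum."""

    stratum: str
    bin_edges: np.ndarray
    mean_r2: np.ndarray  # NaN where a bin holds no pair
    n_pairs: np.ndarray


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between locus rows (NaN for zero variance)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(dosages)
    return r**2


def _bin_r2(
    positions: np.ndarray, r2: np.ndarray, edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(len(positions), k=1)
    dist = np.abs(positions[iu[0]] - positions[iu[1]])
    vals = r2[iu]
    ok = np.isfinite(vals)
    dist, vals = dist[ok], vals[ok]
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    which = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, len(edges) - 2)
    np.add.at(sums, which, vals)
    np.add.at(counts, which, 1)
    return sums, counts


def sample_colinear_controls(
    inversions: Sequence[tuple[str, int, int]],
    layout: GenomeLayout,
    rng: np.random.Generator,
    n_control: int | None = None,
    max_attempts: int = 10_000,
) -> list[tuple[str, int, int]]:
    """Randomly place non-overlapping intervals size-matched to the inversions.

    Rejection sampling: a candidate overlapping an inversion or an already
    placed control is rejected; more than ``max_attempts`` rejections for
    one interval is an error.
    """
    lengths = [e - s for _, s, e in inversions]
    if n_control is not None:
        lengths = [lengths[i % len(lengths)] for i in range(n_control)]
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in inversions:
        forbidden.setdefault(chrom, []).append((s, e))
    chrom_names = list(layout.names)
    weights = np.array([layout.length(c) for c in chrom_names], dtype=float)
    weights /= weights.sum()
    controls: list[tuple[str, int, int]] = []
    for size in lengths:
        for attempt in range(max_attempts):
            chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
            limit = layout.length(chrom) - size
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + size
            clash = any(
                s < end and start < e for s, e in forbidden.get(chrom, [])
            )
            if not clash:
                controls.append((chrom, start, end))
                forbidden.setdefault(chrom, []).append((start, end))
                break
        else:
            raise RuntimeError("could not place a non-overlapping control region")
    return controls


def ld_profile(
    snp_matrix: CohortSVMatrix,
    inversions: Sequence[tuple[SVRecord, np.ndarray]],
    layout: GenomeLayout,
    n_control: int | None = None,
    seed: int = 0,
    bin_width: int = 500,
    max_dist: int = 10_000,
) -> list[LDProfile]:
    """LD decay inside inversions, stratified by inversion karyotype, vs controls.

    ``inversions`` pairs each inversion record with its per-individual
    dosage vector; individuals homozygous for the major (more frequent)
    arrangement form one stratum, minor homozygotes the other.  Controls
    are size-matched random colinear intervals evaluated on all
    individuals.  Pair distances are binned at ``bin_width`` up to
    ``max_dist`` (last bin open-ended).
    """
    edges = np.append(np.arange(0, max_dist, bin_width), np.inf)
    positions = np.array([r.start for r in snp_matrix.loci])
    chroms = np.array([r.chrom for r in snp_matrix.loci])
    dosages = snp_matrix.dosages.astype(float)
    dosages[snp_matrix.dosages == MISSING] = np.nan

    def region_snps(chrom: str, start: int, end: int) -> np.ndarray:
        return np.flatnonzero((chroms == chrom) & (positions >= start) & (positions < end))

    accum = {
        name: (np.zeros(len(edges) - 1), np.zeros(len(edges) - 1, dtype=int))
        for name in ("inversion-major-homozygotes", "inversion-minor-homozygotes", "colinear-control")
    }
    for rec, inv_dosage in inversions:
        inv_dosage = np.asarray(inv_dosage)
        p_alt = inv_dosage[inv_dosage != MISSING].mean() / 2 if (inv_dosage != MISSING).any() else 0.0
        major_hom, minor_hom = (0, 2) if p_alt <= 0.5 else (2, 0)
        idx = region_snps(rec.chrom, rec.start, rec.end)
        if len(idx) < 2:
            continue
        for stratum, hom in (
            ("inversion-major-homozygotes", major_hom),
            ("inversion-minor-homozygotes", minor_hom),
        ):
            cols = np.flatnonzero(inv_dosage == hom)
            if len(cols) < 2:
                warnings.warn(
                    f"inversion {rec.id}: < 2 individuals in {stratum}; stratum omitted",
                    stacklevel=2,
                )
                continue
            sub = dosages[np.ix_(idx, cols)]
            sub = np.where(np.isnan(sub), np.nanmean(sub, axis=1, keepdims=True), sub)
            sums, counts = _bin_r2(positions[idx], _pairwise_r2(sub), edges)
            accum[stratum] = (accum[stratum][0] + sums, accum[stratum][1] + counts)
    rng = np.random.default_rng(seed)
    intervals = [(rec.chrom, rec.start, rec.end) for rec, _ in inversions]
    for chrom, start, end in sample_colinear_controls(intervals, layout, rng, n_control):
        idx = region_snps(chrom, start, end)
        if len(idx) < 2:
            continue
        sub = dosages[idx]
        sub = np.where(np.isnan(sub), np.nanmean(sub, axis=1, keepdims=True), sub)
        sums, counts = _bin_r2(positions[idx], _pairwise_r2(sub), edges)
        accum["colinear-control"] = (
            accum["colinear-control"][0] + sums,
            accum["colinear-control"][1] + counts,
        )
    profiles = []
    for stratum, (sums, counts) in accum.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        profiles.append(
            LDProfile(stratum=stratum, bin_edges=edges, mean_r2=means, n_pairs=counts)
        )
    return profiles


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # non-increasing, >= 0
    scores: np.ndarray  # individuals x components
    individuals: list[str]


def pca(
    matrix: CohortSVMatrix,
    exclude_chroms: frozenset[str] | set[str] = frozenset(),
    min_maf: float = 0.05,
) -> PCAResult:
    """PCA on loci standardized to equal variance (smartpca-style).

    Loci on excluded chromosomes or below ``min_maf`` are removed, missing
    dosages are mean-imputed per locus, loci are centered and scaled by
    their sample standard deviation, and the individuals x individuals
    covariance ``Z Z^T / p`` is eigendecomposed.  Scores are
    ``U sqrt(lambda)``, matching the SVD of ``Z / sqrt(p)``.
    """
    keep = np.array(
        [r.chrom not in exclude_chroms for r in matrix.loci]
    ) & (np.nan_to_num(matrix.maf, nan=-1) >= min_maf)
    sub = matrix.subset_loci(keep)
    if sub.n_loci == 0:
        raise ValueError("no loci left for PCA")
    X = sub.dosages.astype(float).T  # individuals x loci
    X[sub.dosages.T == MISSING] = np.nan
    means = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), means, X) - means
    sd = X.std(axis=0, ddof=1)
    ok = sd > 0
    Z = X[:, ok] / sd[ok]
    p = Z.shape[1]
    cov = Z @ Z.T / p
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    scores = eigvec[:, order] * np.sqrt(eigval)
    return PCAResult(eigenvalues=eigval, scores=scores, individuals=list(matrix.individuals))
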