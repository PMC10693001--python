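"""Synthetic cohorts with known truth for every pipeline stage.

The generator emulates the study design this package targets: a few dozen
diploid birds in 3-4 migratory groups whose allele frequencies diverge
under a Balding-Nichols model with a small fixation index F, a handful of
branch-specific selected loci, three imperfect SV callers (breakpoint
jitter, dropout, genotype error), repeat/gene annotation tracks,
phenotypes built from genotypes with stated variance shares, and
constant-speed daily migration tracks with isotropic position noise.

Every function is deterministic given (seed, parameters).
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from migrasv.io import (
    MISSING,
    GeneAnnotation,
    GenomeLayout,
    RepeatAnnotation,
    SVRecord,
    TrackedBird,
    write_bed_repeats,
    write_gff_genes,
    write_phenotype_table,
    write_sv_vcf,
)
from migrasv.phenotypes import EARTH_RADIUS_KM, great_circle_distance
from migrasv.svmerge import CohortSVMatrix

__all__ = [
    "SimTruth",
    "TraitModel",
    "SizeLaw",
    "make_layout",
    "simulate_svs",
    "simulate_group_frequencies",
    "simulate_genotypes",
    "simulate_caller_callsets",
    "simulate_annotations",
    "simulate_phenotypes",
    "RouteSpec",
    "simulate_tracks",
    "rhumb_destination",
    "simulate_neutral_spectrum",
    "simulate_ld_cohort",
    "blackcap_profile",
]

#: per-type (median bp, lognormal sigma) echoing observed SV size spectra
DEFAULT_SIZE_LAW = {
    "DEL": (250, 1.0),
    "INS": (250, 1.0),
    "DUP": (272, 0.3),
    "INV": (2500, 0.8),
    "TRA": (10456, 0.5),
}

#: type mix echoing an indel-dominated SV landscape
DEFAULT_TYPE_MIX = {
    "DEL": 9341 / 15763,
    "INS": 6393 / 15763,
    "INV": 24 / 15763,
    "DUP": 4 / 15763,
    "TRA": 1 / 15763,
}

#: repeat-class mix echoing a songbird repeat library
DEFAULT_REPEAT_MIX = {
    "Simple": 0.478,
    "LTR": 0.255,
    "LINE/CR1": 0.175,
    "LowComplexity": 0.082,
    "DNA": 0.0079,
    "SINE": 0.0021,
}

MIN_TRUTH_SPACING = 2000  # bp between truth locus starts


@dataclass
class SizeLaw:
    """Log-normal SV length law with a per-type median, truncated at 52 bp."""

    params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_LAW)
    )
    min_length: int = 52

    def sample(self, svtype: str, rng: np.random.Generator, size: int) -> np.ndarray:
        median, sigma = self.params[svtype]
        draws = np.round(median * np.exp(sigma * rng.standard_normal(size)))
        return np.maximum(draws, self.min_length).astype(int)


@dataclass
class TraitModel:
    """Variance-share model for one trait.

    The trait is ``baseline + scale * (polygenic + focal + noise)`` where
    the polygenic term (Normal(0, sigma_g^2/p) effects on all standardized
    loci) is scaled to variance ``h2``, each focal locus to its configured
    share (sign carried separately), and the noise to
    ``1 - h2 - sum(shares)`` (overridable via ``noise_sd``).  All variance
    shares refer to the unit-variance core before ``scale`` is applied.
    """

    name: str
    h2: float = 0.0
    focal: Mapping[int, tuple[float, float]] = field(default_factory=dict)  # locus -> (share, sign)
    baseline: float | np.ndarray = 0.0
    scale: float = 1.0
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        total = self.h2 + sum(s for s, _ in self.focal.values())
        if total > 1.0 + 1e-9:
            raise ValueError("h2 + focal shares exceed 1")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")


@dataclass
class RouteSpec:
    """True migration route parameters for one bird."""

    bird_id: str
    sex: str
    breeding: tuple[float, float]
    wintering: tuple[float, float]
    depart_fall: _dt.date
    speed_km_per_day: float
    depart_spring: _dt.date | None = None


@dataclass
class SimTruth:
    """Everything the generator knows, for validating downstream answers."""

    layout: GenomeLayout
    loci: list[SVRecord] = field(default_factory=list)
    ancestral_p: np.ndarray | None = None
    group_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    selected: list[tuple[int, str, float]] = field(default_factory=list)
    matrix: CohortSVMatrix | None = None
    groups: dict[str, str] = field(default_factory=dict)  # bird -> group
    traits: pd.DataFrame | None = None
    trait_models: dict[str, TraitModel] = field(default_factory=dict)
    trait_effects: dict[str, dict[int, float]] = field(default_factory=dict)
    routes: dict[str, RouteSpec] = field(default_factory=dict)
    focal_id: str | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome, SVs, frequencies, genotypes
# ---------------------------------------------------------------------------


def make_layout(n_chrom: int = 28, scale_mb: float = 22.0) -> GenomeLayout:
    """A karyotype-like layout: lengths fall off as k^-1.1 from ``scale_mb``."""
    lengths = {
        f"chr{k}": int(scale_mb * 1e6 * k**-1.1) for k in range(1, n_chrom + 1)
    }
    return GenomeLayout(lengths)


def simulate_svs(
    layout: GenomeLayout,
    n_loci: int,
    type_mix: Mapping[str, float] | None = None,
    size_law: SizeLaw | None = None,
    seed: int = 0,
) -> list[SVRecord]:
    """Truth SV set: uniform positions with >= 2 kb start spacing,
    log-normal lengths per type."""
    type_mix = dict(type_mix or DEFAULT_TYPE_MIX)
    if abs(sum(type_mix.values()) - 1.0) > 1e-6:
        raise ValueError("type_mix must sum to 1")
    size_law = size_law or SizeLaw()
    rng = np.random.default_rng(seed)
    capacity = {c: layout.length(c) // MIN_TRUTH_SPACING for c in layout.names}
    total_capacity = sum(capacity.values())
    if total_capacity < n_loci:
        raise ValueError("layout too small for requested loci at 2 kb spacing")
    # allocate loci to chromosomes proportionally to capacity (largest remainder)
    raw = {c: n_loci * cap / total_capacity for c, cap in capacity.items()}
    alloc = {c: min(int(raw[c]), capacity[c]) for c in raw}
    short = n_loci - sum(alloc.values())
    for c in sorted(raw, key=lambda c: raw[c] - int(raw[c]), reverse=True):
        if short == 0:
            break
        if alloc[c] < capacity[c]:
            alloc[c] += 1
            short -= 1
    types = list(type_mix)
    records: list[SVRecord] = []
    idx = 0
    for chrom in layout.names:
        k = alloc.get(chrom, 0)
        if k == 0:
            continue
        grid = rng.choice(capacity[chrom], size=k, replace=False)
        offset = int(rng.integers(0, MIN_TRUTH_SPACING // 2))
        starts = np.sort(grid) * MIN_TRUTH_SPACING + offset
        chosen = rng.choice(len(types), size=k, p=[type_mix[t] for t in types])
        for start, ti in zip(starts, chosen):
            svtype = types[ti]
            length = int(size_law.sample(svtype, rng, 1)[0])
            chrom_len = layout.length(chrom)
            start = int(min(start, chrom_len - 2))
            if svtype == "INS":
                end = start + 1
            else:
                end = min(start + length, chrom_len)
                length = end - start
                if length < size_law.min_length:
                    start = max(0, end - size_law.min_length)
                    length = end - start
            records.append(
                SVRecord(
                    id=f"truth{idx:05d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    length=length,
                    genotype=MISSING,
                    partner=f"{layout.names[0]}:1000" if svtype == "TRA" else None,
                )
            )
            idx += 1
    return records


def simulate_group_frequencies(
    n_loci: int,
    groups: Sequence[str],
    F: float | Mapping[str, float] = 0.02,
    selected: Sequence[tuple[int, str, float]] = (),
    seed: int = 0,
    ancestral_p: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Balding-Nichols per-group frequencies around a shared ancestral p.

    Each group's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F); ``selected``
    loci are then shifted toward alt fixation in their group by the stated
    amount (clamped to [0, 1]).
    """
    rng = np.random.default_rng(seed)
    if ancestral_p is None:
        ancestral_p = rng.uniform(0.05, 0.95, size=n_loci)
    ancestral_p = np.asarray(ancestral_p, dtype=float)
    F_map = {g: (F[g] if isinstance(F, Mapping) else F) for g in groups}
    freqs: dict[str, np.ndarray] = {}
    for g in groups:
        f = F_map[g]
        if not 0.0 <= f < 1.0:
            raise ValueError("F must lie in [0, 1)")
        if f == 0.0:
            freqs[g] = ancestral_p.copy()
        else:
            a = ancestral_p * (1 - f) / f
            b = (1 - ancestral_p) * (1 - f) / f
            freqs[g] = rng.beta(a, b)
    for locus, group, shift in selected:
        freqs[group][locus] = float(np.clip(freqs[group][locus] + shift, 0.0, 1.0))
    return ancestral_p, freqs


def simulate_genotypes(
    loci: Sequence[SVRecord],
    freqs: Mapping[str, np.ndarray],
    group_sizes: Mapping[str, int],
    seed: int = 0,
) -> tuple[CohortSVMatrix, dict[str, str]]:
    """Hardy-Weinberg dosages (Binomial(2, p_group)) per individual.

    Returns the truth cohort matrix and the bird -> group map; individual
    ids are ``bird001`` ... in group order.
    """
    rng = np.random.default_rng(seed)
    individuals: list[str] = []
    groups_of: dict[str, str] = {}
    columns = []
    for group, size in group_sizes.items():
        if size < 2:
            raise ValueError("each group needs >= 2 individuals")
        p = np.asarray(freqs[group])
        columns.append(rng.binomial(2, p[:, None], size=(len(p), size)))
        for _ in range(size):
            name = f"bird{len(individuals) + 1:03d}"
            individuals.append(name)
            groups_of[name] = group
    dosages = np.concatenate(columns, axis=1).astype(np.int16)
    return CohortSVMatrix(list(loci), individuals, dosages), groups_of


# ---------------------------------------------------------------------------
# noisy caller emulation
# ---------------------------------------------------------------------------


def simulate_caller_callsets(
    loci: Sequence[SVRecord],
    dosages: np.ndarray,
    individuals: Sequence[str],
    jitter_sd: float = 150.0,
    dropout: float | Sequence[float] = 0.2,
    genotype_error: float = 0.02,
    n_callers: int = 3,
    seed: int = 0,
    layout: GenomeLayout | None = None,
) -> dict[str, dict[str, list[SVRecord]]]:
    """Emulate imperfect callers on the truth genotypes.

    Each caller sees only the variants an individual carries (dosage >= 1),
    drops each independently with its dropout probability, shifts both
    breakpoints by the same rounded Normal(0, jitter_sd) offset (so length
    is noise-free) and flips the genotype 1 <-> 2 with probability
    ``genotype_error``.  Returns ``{individual: {caller: [records]}}``.
    """
    if jitter_sd > 300:
        raise ValueError("jitter_sd must stay below 300 bp (merge radius safety)")
    rng = np.random.default_rng(seed)
    dropout_per = (
        list(dropout) if isinstance(dropout, (list, tuple, np.ndarray)) else [dropout] * n_callers
    )
    if len(dropout_per) != n_callers:
        raise ValueError("one dropout rate per caller required")
    callers = [f"caller{k + 1}" for k in range(n_callers)]
    n_loci, n_ind = dosages.shape
    out: dict[str, dict[str, list[SVRecord]]] = {ind: {} for ind in individuals}
    for k, caller in enumerate(callers):
        drop = rng.random((n_loci, n_ind)) < dropout_per[k]
        shift = np.round(rng.normal(0.0, jitter_sd, size=(n_loci, n_ind))).astype(int)
        flip = rng.random((n_loci, n_ind)) < genotype_error
        for j, ind in enumerate(individuals):
            calls: list[SVRecord] = []
            carriers = np.flatnonzero((dosages[:, j] >= 1) & ~drop[:, j])
            for li in carriers:
                rec = loci[li]
                span = rec.end - rec.start
                s = max(0, rec.start + int(shift[li, j]))
                if layout is not None:
                    s = min(s, layout.length(rec.chrom) - span)
                gt = int(dosages[li, j])
                if flip[li, j]:
                    gt = 3 - gt  # 1 <-> 2
                calls.append(
                    replace(rec, id=f"{rec.id}.{caller}", start=s, end=s + span,
                            genotype=gt, caller=caller)
                )
            out[ind][caller] = calls
    return out


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------


def simulate_annotations(
    layout: GenomeLayout,
    repeat_density: float = 0.08,
    classes_mix: Mapping[str, float] | None = None,
    n_genes: int = 400,
    seed: int = 0,
) -> tuple[RepeatAnnotation, GeneAnnotation]:
    """Non-overlapping repeat intervals (class labels from the mix) and
    non-overlapping gene intervals."""
    classes_mix = dict(classes_mix or DEFAULT_REPEAT_MIX)
    total = sum(classes_mix.values())
    if abs(total - 1.0) > 1e-6:
        classes_mix = {k: v / total for k, v in classes_mix.items()}
    if not 0.0 < repeat_density < 0.5:
        raise ValueError("repeat_density must lie in (0, 0.5)")
    rng = np.random.default_rng(seed)
    classes = list(classes_mix)
    probs = [classes_mix[c] for c in classes]
    rep_rows = []
    mean_len = 400.0
    for chrom in layout.names:
        L = layout.length(chrom)
        pos = 0
        while True:
            gap = rng.exponential(mean_len * (1 - repeat_density) / repeat_density)
            length = max(30, int(round(mean_len * np.exp(0.7 * rng.standard_normal()))))
            start = pos + int(gap)
            end = start + length
            if end >= L:
                break
            rep_rows.append(
                {"chrom": chrom, "start": start, "end": end,
                 "repeat_class": classes[rng.choice(len(classes), p=probs)]}
            )
            pos = end
    repeats = RepeatAnnotation(pd.DataFrame(rep_rows))
    # genes: grid placement, ~20 kb each, proportional to chromosome length
    gene_rows = []
    gene_len = 20_000
    spacing = max(gene_len * 2, int(layout.total_length / (n_genes * 1.25)))
    gid = 0
    for chrom in layout.names:
        L = layout.length(chrom)
        n_here = max(0, (L - gene_len) // spacing)
        for k in range(int(n_here)):
            if gid >= n_genes:
                break
            start = k * spacing + int(rng.integers(0, spacing - gene_len))
            gene_rows.append(
                {"gene_id": f"gene{gid:04d}", "chrom": chrom, "start": start,
                 "end": start + gene_len, "strand": "+" if rng.random() < 0.5 else "-"}
            )
            gid += 1
    if gid < n_genes:
        raise ValueError("layout too small for requested gene count")
    genes = GeneAnnotation(pd.DataFrame(gene_rows))
    return repeats, genes


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    matrix: CohortSVMatrix,
    models: Sequence[TraitModel],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, dict[int, float]]]:
    """Generate traits from genotypes with configured variance shares.

    Components are scaled empirically so the realized cohort variance of
    each matches its configured share.  Returns the trait table and, per
    trait, the realized per-allele effect of each focal locus.
    """
    rng = np.random.default_rng(seed)
    n = matrix.n_individuals
    Z = matrix.dosages.astype(float).T
    Z[matrix.dosages.T == MISSING] = np.nan
    mu = np.nanmean(Z, axis=0)
    Z = np.where(np.isnan(Z), mu, Z) - mu
    sd = Z.std(axis=0, ddof=1)
    ok = sd > 0
    Zs = np.zeros_like(Z)
    Zs[:, ok] = Z[:, ok] / sd[ok]
    data: dict[str, np.ndarray] = {}
    effects: dict[str, dict[int, float]] = {}
    for model in models:
        core = np.zeros(n)
        if model.h2 > 0:
            g = Zs @ rng.normal(0.0, 1.0, size=matrix.n_loci)
            gv = g.var(ddof=1)
            if gv > 0:
                core += g * math.sqrt(model.h2 / gv)
        eff: dict[int, float] = {}
        for locus, (share, sign) in model.focal.items():
            x = Z[:, locus]
            xv = x.var(ddof=1)
            if xv <= 0:
                raise ValueError(f"focal locus {locus} is monomorphic")
            coef = math.copysign(math.sqrt(share / xv), sign)
            core += coef * x
            eff[locus] = coef * model.scale
        noise_sd = (
            model.noise_sd
            if model.noise_sd is not None
            else math.sqrt(max(0.0, 1.0 - model.h2 - sum(s for s, _ in model.focal.values())))
        )
        core += rng.normal(0.0, 1.0, size=n) * noise_sd
        data[model.name] = np.asarray(model.baseline) + model.scale * core
        effects[model.name] = eff
    table = pd.DataFrame(data)
    table.insert(0, "bird_id", matrix.individuals)
    return table, effects


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def rhumb_destination(
    origin: tuple[float, float], bearing_deg: float, distance_km: float
) -> tuple[float, float]:
    """Forward loxodrome: destination after ``distance_km`` on a constant bearing."""
    lat1, lon1 = origin
    theta = math.radians(bearing_deg)
    delta = distance_km / EARTH_RADIUS_KM
    phi1 = math.radians(lat1)
    dphi = delta * math.cos(theta)
    phi2 = phi1 + dphi
    dpsi = math.log(
        math.tan(math.pi / 4 + phi2 / 2) / math.tan(math.pi / 4 + phi1 / 2)
    )
    q = dphi / dpsi if abs(dpsi) > 1e-12 else math.cos(phi1)
    dlam = delta * math.sin(theta) / q
    lon2 = math.degrees(math.radians(lon1) + dlam)
    return math.degrees(phi2), (lon2 + 180.0) % 360.0 - 180.0


def _to_xyz(lat: float, lon: float) -> np.ndarray:
    phi, lam = math.radians(lat), math.radians(lon)
    return np.array(
        [math.cos(phi) * math.cos(lam), math.cos(phi) * math.sin(lam), math.sin(phi)]
    )


def _from_xyz(v: np.ndarray) -> tuple[float, float]:
    lat = math.degrees(math.asin(max(-1.0, min(1.0, v[2]))))
    lon = math.degrees(math.atan2(v[1], v[0]))
    return lat, lon


def _gc_interpolate(a: tuple[float, float], b: tuple[float, float], f: float) -> tuple[float, float]:
    va, vb = _to_xyz(*a), _to_xyz(*b)
    omega = math.acos(max(-1.0, min(1.0, float(va @ vb))))
    if omega < 1e-12:
        return a
    v = (math.sin((1 - f) * omega) * va + math.sin(f * omega) * vb) / math.sin(omega)
    return _from_xyz(v / np.linalg.norm(v))


def simulate_tracks(
    routes: Sequence[RouteSpec],
    position_noise_km: float = 0.0,
    stationary_days: int = 4,
    seed: int = 0,
) -> list[TrackedBird]:
    """Constant-speed daily positions along the great circle, plus noise.

    Each leg starts with ``stationary_days`` days at the origin and ends
    with the same at the destination; the spring leg (reverse route) is
    generated when ``depart_spring`` is set.
    """
    rng = np.random.default_rng(seed)
    birds = []
    for spec in routes:
        gc_dist = great_circle_distance(spec.breeding, spec.wintering)
        travel_days = max(1, math.ceil(gc_dist / spec.speed_km_per_day - 1e-9))
        positions: list[tuple[_dt.date, float, float]] = []

        def leg(origin, dest, depart: _dt.date):
            day = depart - _dt.timedelta(days=stationary_days)
            for _ in range(stationary_days):
                positions.append((day, *origin))
                day += _dt.timedelta(days=1)
            for k in range(travel_days + 1):
                lat, lon = _gc_interpolate(origin, dest, k / travel_days)
                positions.append((day, lat, lon))
                day += _dt.timedelta(days=1)
            for _ in range(stationary_days):
                positions.append((day, *dest))
                day += _dt.timedelta(days=1)

        leg(spec.breeding, spec.wintering, spec.depart_fall)
        if spec.depart_spring is not None:
            leg(spec.wintering, spec.breeding, spec.depart_spring)
        if position_noise_km > 0:
            noisy = []
            for d, lat, lon in positions:
                dlat = rng.normal(0.0, position_noise_km) / 111.2
                dlon = rng.normal(0.0, position_noise_km) / (
                    111.2 * max(0.2, math.cos(math.radians(lat)))
                )
                noisy.append((d, max(-89.9, min(89.9, lat + dlat)), lon + dlon))
            positions = noisy
        birds.append(
            TrackedBird(
                bird_id=spec.bird_id,
                sex=spec.sex,
                breeding=spec.breeding,
                wintering=spec.wintering,
                daily_positions=positions,
            )
        )
    return birds


# ---------------------------------------------------------------------------
# purpose-built small simulators for estimator checks
# ---------------------------------------------------------------------------


def simulate_neutral_spectrum(
    n_individuals: int, n_loci: int, seed: int = 0
) -> CohortSVMatrix:
    """Dosage matrix whose allele counts follow the neutral 1/i law.

    The derived-allele copy count i of each locus is drawn with
    probability proportional to 1/i (i = 1..2n-1) and the i copies are
    assigned to random chromosomes, as in an equilibrium constant-size
    population sample.
    """
    rng = np.random.default_rng(seed)
    n2 = 2 * n_individuals
    i_vals = np.arange(1, n2)
    probs = (1.0 / i_vals) / np.sum(1.0 / i_vals)
    counts = rng.choice(i_vals, size=n_loci, p=probs)
    # place each locus' i derived copies on a uniform random subset of the
    # 2n chromosomes: rank a random matrix row-wise
    ranks = np.argsort(rng.random((n_loci, n2)), axis=1).argsort(axis=1)
    carried = ranks < counts[:, None]
    dosages = (carried[:, 0::2].astype(np.int16) + carried[:, 1::2])
    loci = [
        SVRecord(id=f"snp{li:05d}", chrom="chr1", start=1000 * li, end=1000 * li + 1,
                 svtype="INS", length=100)
        for li in range(n_loci)
    ]
    return CohortSVMatrix(loci, [f"ind{j:03d}" for j in range(n_individuals)], dosages)


def simulate_ld_cohort(
    n_individuals: int = 50,
    n_inversions: int = 4,
    inversion_length: int = 4000,
    snp_spacing: int = 150,
    chrom_length: int = 400_000,
    copy_scale: float = 500.0,
    hap_noise: float = 0.01,
    seed: int = 0,
) -> tuple[CohortSVMatrix, list[tuple[SVRecord, np.ndarray]], GenomeLayout]:
    """SNP cohort with non-recombining inversion haplotypes and a
    recombining colinear background.

    Colinear SNP haplotypes follow a haplotype-copy Markov model: each
    haplotype copies its previous allele with probability
    ``exp(-distance/copy_scale)`` and otherwise redraws it, so r^2 decays
    on the ``copy_scale``.  Inside each inversion, the two arrangements
    each carry a two-haplotype pool with perfectly associated SNP alleles
    (flip noise ``hap_noise``), so LD stays near 1 at any distance within
    an arrangement.
    """
    rng = np.random.default_rng(seed)
    layout = GenomeLayout({"chr1": chrom_length})
    # place inversions evenly, away from each other
    inv_gap = chrom_length // (n_inversions + 1)
    inv_intervals = [
        (k * inv_gap, k * inv_gap + inversion_length) for k in range(1, n_inversions + 1)
    ]
    positions = np.arange(snp_spacing, chrom_length - snp_spacing, snp_spacing)
    n_snps = len(positions)
    n_hap = 2 * n_individuals
    freqs = rng.uniform(0.2, 0.8, size=n_snps)
    hap = np.zeros((n_hap, n_snps), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < freqs[0]
    copy_prob = np.exp(-np.diff(positions) / copy_scale)
    for s in range(1, n_snps):
        fresh = rng.random(n_hap) >= copy_prob[s - 1]
        hap[:, s] = np.where(fresh, rng.random(n_hap) < freqs[s], hap[:, s - 1])
    # inversion genotypes and arrangement-pool haplotypes
    inversions: list[tuple[SVRecord, np.ndarray]] = []
    for k, (s, e) in enumerate(inv_intervals):
        inv_dosage = rng.binomial(2, 0.5, size=n_individuals).astype(np.int16)
        arrangement = np.zeros(n_hap, dtype=np.int8)  # per haplotype copy
        for j in range(n_individuals):
            g = inv_dosage[j]
            arrangement[2 * j] = 1 if g >= 1 else 0
            arrangement[2 * j + 1] = 1 if g == 2 else 0
        pool = rng.random(n_hap) < 0.5  # which pool member within the arrangement
        in_region = (positions >= s) & (positions < e)
        for col in np.flatnonzero(in_region):
            base = pool.astype(np.int8)  # same split at every SNP -> full LD
            noise = rng.random(n_hap) < hap_noise
            hap[:, col] = base ^ noise
        rec = SVRecord(id=f"inv{k}", chrom="chr1", start=int(s), end=int(e),
                       svtype="INV", length=int(e - s))
        inversions.append((rec, inv_dosage))
    dosages = (hap[0::2] + hap[1::2]).T.astype(np.int16)  # snps x individuals
    loci = [
        SVRecord(id=f"snp{i:05d}", chrom="chr1", start=int(p), end=int(p) + 1,
                 svtype="INS", length=100)
        for i, p in enumerate(positions)
    ]
    matrix = CohortSVMatrix(loci, [f"ind{j:03d}" for j in range(n_individuals)], dosages)
    return matrix, inversions, layout


# ---------------------------------------------------------------------------
# the full study-shaped profile
# ---------------------------------------------------------------------------

GROUP_SIZES = {"NW": 19, "SW": 28, "SE": 12, "S": 20}
#: mean fall bearing per group, chosen so that rhumb destinations from the
#: Austrian breeding area land in each group's classification region; the
#: SE mean is the pre-focal baseline (the focal deletion pulls SE carriers
#: further east, i.e. to smaller bearings)
GROUP_DIRECTION = {"NW": 310.0, "SW": 227.0, "SE": 158.0, "S": 183.0}
GROUP_DISTANCE = {"NW": 1300.0, "SW": 1700.0, "SE": 2100.0, "S": 1500.0}


def blackcap_profile(
    seed: int = 0,
    n_loci: int = 15_000,
    group_sizes: Mapping[str, int] | None = None,
    out_dir: str | Path | None = None,
    jitter_sd: float = 150.0,
    dropout: float = 0.2,
    genotype_error: float = 0.02,
    position_noise_km: float = 50.0,
    fst_target: float = 0.02,
) -> SimTruth:
    """The study-shaped cohort: 79 birds in four migratory groups,
    ~15,000 truth SVs, a 710-bp focal deletion on chr27 nearly fixed in
    SE migrants and driving migratory direction, three noisy callers,
    annotation tracks, phenotypes and geolocator-like tracks.

    When ``out_dir`` is given, writes all pipeline inputs there:
    ``chroms.tsv``, ``calls/<bird>/<caller>.vcf``, ``repeats.bed``,
    ``genes.gff3``, ``birds.csv``, ``tracks.csv`` and ``truth.json``.
    """
    group_sizes = dict(group_sizes or GROUP_SIZES)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(10)]
    rng = np.random.default_rng(seeds[0])
    layout = make_layout()
    loci = simulate_svs(layout, n_loci, seed=seeds[1])
    # focal deletion: 710 bp on chr27, SE-shifted, direction-driving
    chr27 = [i for i, r in enumerate(loci) if r.chrom == "chr27"]
    if not chr27:
        raise RuntimeError("profile layout produced no chr27 loci")
    focal = chr27[len(chr27) // 2]
    rec = loci[focal]
    end = min(rec.start + 710, layout.length("chr27"))
    loci[focal] = replace(rec, svtype="DEL", end=end, length=end - rec.start)
    groups = list(group_sizes)
    ancestral = np.random.default_rng(seeds[2]).uniform(0.05, 0.95, size=len(loci))
    # The focal deletion follows the direction cline: near-fixed in SE
    # (alt allele pulls bearings east), depleted in NW, so genotype tracks
    # direction across all groups, not just through SE membership.
    ancestral[focal] = 0.30
    selected = [(focal, "SE", 0.65), (focal, "NW", -0.2)]
    _, freqs = simulate_group_frequencies(
        len(loci), groups, F=fst_target, selected=selected,
        seed=seeds[3], ancestral_p=ancestral,
    )
    matrix, groups_of = simulate_genotypes(loci, freqs, group_sizes, seed=seeds[4])
    individuals = matrix.individuals
    group_arr = np.array([groups_of[i] for i in individuals])
    sexes = np.where(rng.random(len(individuals)) < 0.5, "F", "M")
    baseline = np.array([GROUP_DIRECTION[g] for g in group_arr])
    models = [
        TraitModel(
            name="direction",
            h2=0.2,
            focal={focal: (0.5, -1.0)},
            baseline=baseline,
            scale=8.0,
        ),
        TraitModel(
            name="distance",
            h2=0.3,
            baseline=np.array([GROUP_DISTANCE[g] for g in group_arr]),
            scale=120.0,
        ),
    ]
    traits, effects = simulate_phenotypes(matrix, models, seed=seeds[5])
    traits["group"] = group_arr
    traits["sex"] = sexes
    # routes: wintering from the generated direction/distance traits
    route_rng = np.random.default_rng(seeds[6])
    routes: dict[str, RouteSpec] = {}
    for i, bird in enumerate(individuals):
        breeding = (
            float(np.clip(route_rng.normal(48.5, 1.2), 45.5, 52.5)),
            float(np.clip(route_rng.normal(13.0, 1.5), 8.0, 17.0)),
        )
        direction = float(traits.loc[i, "direction"])
        distance = float(max(600.0, traits.loc[i, "distance"]))
        wintering = rhumb_destination(breeding, direction, distance)
        depart = _dt.date(2020, 9, 1) + _dt.timedelta(days=int(route_rng.integers(0, 20)))
        spring = _dt.date(2021, 4, 1) + _dt.timedelta(days=int(route_rng.integers(0, 15)))
        routes[bird] = RouteSpec(
            bird_id=bird,
            sex=str(sexes[i]),
            breeding=breeding,
            wintering=wintering,
            depart_fall=depart,
            speed_km_per_day=float(route_rng.normal(105.0, 12.0)),
            depart_spring=spring,
        )
    birds = simulate_tracks(list(routes.values()), position_noise_km=position_noise_km,
                            seed=seeds[7])
    callsets = simulate_caller_callsets(
        loci, matrix.dosages, individuals,
        jitter_sd=jitter_sd, dropout=dropout, genotype_error=genotype_error,
        seed=seeds[8], layout=layout,
    )
    repeats, genes = simulate_annotations(layout, seed=seeds[9])
    truth = SimTruth(
        layout=layout,
        loci=loci,
        ancestral_p=ancestral,
        group_freqs=freqs,
        selected=selected,
        matrix=matrix,
        groups=groups_of,
        traits=traits,
        trait_models={m.name: m for m in models},
        trait_effects=effects,
        routes=routes,
        focal_id=loci[focal].id,
        params={
            "seed": seed,
            "n_loci": n_loci,
            "jitter_sd": jitter_sd,
            "dropout": dropout,
            "genotype_error": genotype_error,
            "position_noise_km": position_noise_km,
            "fst_target": fst_target,
        },
    )
    if out_dir is not None:
        _write_profile(truth, callsets, birds, repeats, genes, Path(out_dir))
    truth.params["callsets"] = callsets
    truth.params["birds"] = birds
    truth.params["repeats"] = repeats
    truth.params["genes"] = genes
    return truth


def _write_profile(
    truth: SimTruth,
    callsets: Mapping[str, Mapping[str, list[SVRecord]]],
    birds: Sequence[TrackedBird],
    repeats: RepeatAnnotation,
    genes: GeneAnnotation,
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    truth.layout.to_table(out_dir / "chroms.tsv")
    order = {name: i for i, name in enumerate(truth.layout.names)}
    calls_dir = out_dir / "calls"
    for ind, per_caller in callsets.items():
        (calls_dir / ind).mkdir(parents=True, exist_ok=True)
        for caller, records in per_caller.items():
            records = sorted(records, key=lambda r: (order[r.chrom], r.start))
            write_sv_vcf(records, truth.layout, calls_dir / ind / f"{caller}.vcf", sample=ind)
    write_bed_repeats(repeats, out_dir / "repeats.bed")
    write_gff_genes(genes, out_dir / "genes.gff3")
    write_phenotype_table(birds, out_dir / "birds.csv", tracks_path=out_dir / "tracks.csv")
    meta = {
        "focal_id": truth.focal_id,
        "selected": [
            {"locus_id": truth.loci[i].id, "group": g, "shift": s}
            for i, g, s in truth.selected
        ],
        "groups": truth.groups,
        "params": {k: v for k, v in truth.params.items() if isinstance(v, (int, float, str))},
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
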