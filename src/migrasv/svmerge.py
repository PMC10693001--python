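"""Multi-caller consensus genotyping and cross-cohort merging of SVs.

The filter chain mirrors SURVIVOR-style breakpoint clustering: within an
individual, calls from different callers are clustered when both
breakpoints fall within ``max_dist`` and a cluster is kept only when at
least two callers agree on the genotype.  Consensus calls are then merged
across individuals (same SV type, breakpoints within ``max_dist``) and a
locus is retained when enough individuals support it.  Individuals without
a call at a retained locus are coded as homozygous reference (dosage 0),
which is the closure that lets cohort minor-allele frequencies and AFS be
computed from merged calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from migrasv.io import MISSING, SVRecord

__all__ = [
    "ConsensusCall",
    "CohortSVMatrix",
    "consensus_individual",
    "filter_n_runs",
    "merge_cohort",
    "maf_filter",
]


@dataclass
class ConsensusCall:
    """An SV supported by >= 2 callers with matching genotypes."""

    record: SVRecord  # representative call (median start among supporters)
    supporting_callers: frozenset[str]
    genotype: int

    def __post_init__(self) -> None:
        if len(self.supporting_callers) < 2:
            raise ValueError("a consensus call needs >= 2 supporting callers")


class CohortSVMatrix:
    """Merged loci x individuals dosage matrix with locus metadata.

    ``dosages`` holds alt-allele counts in {0, 1, 2} with :data:`MISSING`
    (-1) for missing genotypes.  Loci are sorted by (chromosome order as
    first seen, start).  ``maf`` is the per-locus minor-allele frequency
    over non-missing entries.
    """

    def __init__(
        self,
        loci: Sequence[SVRecord],
        individuals: Sequence[str],
        dosages: np.ndarray,
    ):
        dosages = np.asarray(dosages, dtype=np.int16)
        if dosages.shape != (len(loci), len(individuals)):
            raise ValueError("dosage matrix shape mismatch")
        self.loci = list(loci)
        self.individuals = list(individuals)
        self.dosages = dosages

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def alt_freq(self) -> np.ndarray:
        """Per-locus alt-allele frequency over non-missing genotypes."""
        obs = self.dosages != MISSING
        copies = 2 * obs.sum(axis=1)
        alt = np.where(obs, self.dosages, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)

    @property
    def maf(self) -> np.ndarray:
        p = self.alt_freq
        return np.minimum(p, 1.0 - p)

    def subset_loci(self, index: np.ndarray) -> "CohortSVMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CohortSVMatrix(
            [self.loci[i] for i in index], self.individuals, self.dosages[index]
        )

    def subset_individuals(self, index: Sequence[int]) -> "CohortSVMatrix":
        idx = list(index)
        return CohortSVMatrix(
            self.loci, [self.individuals[i] for i in idx], self.dosages[:, idx]
        )


# ---------------------------------------------------------------------------
# within-individual consensus
# ---------------------------------------------------------------------------


def _cluster(
    calls: list[tuple[object, SVRecord]],
    max_dist: int,
) -> list[list[tuple[object, SVRecord]]]:
    """Greedy breakpoint clustering of (source, record) pairs on one chromosome.

    Calls are processed in (start, end, source, id) order; each call joins
    the open cluster whose seed has both breakpoints within ``max_dist``
    and which holds no call from the same source yet, preferring the
    nearest breakpoints (ties: smaller seed start).  Sorting makes the
    result invariant to the order in which sources were supplied.
    """
    calls = sorted(calls, key=lambda t: (t[1].start, t[1].end, str(t[0]), t[1].id))
    clusters: list[dict] = []
    open_from = 0
    out: list[list[tuple[object, SVRecord]]] = []
    for source, rec in calls:
        # retire clusters that can no longer match (starts are sorted)
        while open_from < len(clusters) and clusters[open_from]["seed"].start < rec.start - max_dist:
            out.append(clusters[open_from]["members"])
            open_from += 1
        best = None
        for cl in clusters[open_from:]:
            seed = cl["seed"]
            ds, de = abs(rec.start - seed.start), abs(rec.end - seed.end)
            if ds <= max_dist and de <= max_dist and source not in cl["sources"]:
                key = (ds + de, seed.start)
                if best is None or key < best[0]:
                    best = (key, cl)
        if best is None:
            clusters.append({"seed": rec, "sources": {source}, "members": [(source, rec)]})
        else:
            best[1]["sources"].add(source)
            best[1]["members"].append((source, rec))
    out.extend(cl["members"] for cl in clusters[open_from:])
    return out


def _median_start_record(records: Sequence[SVRecord]) -> SVRecord:
    """Representative = call with lower-median start."""
    ordered = sorted(records, key=lambda r: (r.start, r.end, r.id))
    return ordered[(len(ordered) - 1) // 2]


def consensus_individual(
    callsets: Mapping[str, Sequence[SVRecord]],
    max_dist: int = 1000,
    min_size: int = 50,
    require_type_match: bool = False,
) -> list[ConsensusCall]:
    """Within-individual consensus across callers.

    Calls shorter than ``min_size`` are dropped before clustering; a
    cluster becomes a consensus call when >= 2 distinct callers agree on
    the genotype.  When several genotypes each reach two supporters, the
    best-supported one wins (ties: smaller dosage).
    """
    if len(callsets) < 2:
        raise ValueError("consensus requires call sets from >= 2 callers")
    for caller, calls in callsets.items():
        ids = [c.id for c in calls]
        if len(set(ids)) != len(ids):
            raise ValueError(f"caller {caller!r} emitted duplicate record ids")
    by_key: dict[tuple, list[tuple[str, SVRecord]]] = {}
    for caller, calls in callsets.items():
        for rec in calls:
            if rec.length < min_size:
                continue
            key = (rec.chrom, rec.svtype) if require_type_match else (rec.chrom,)
            by_key.setdefault(key, []).append((caller, rec))
    consensus: list[ConsensusCall] = []
    for key in sorted(by_key):
        for members in _cluster(by_key[key], max_dist):
            by_gt: dict[int, list[tuple[str, SVRecord]]] = {}
            for caller, rec in members:
                if rec.genotype != MISSING:
                    by_gt.setdefault(rec.genotype, []).append((caller, rec))
            eligible = {
                gt: m for gt, m in by_gt.items() if len({c for c, _ in m}) >= 2
            }
            if not eligible:
                continue
            gt = min(eligible, key=lambda g: (-len({c for c, _ in eligible[g]}), g))
            supporters = eligible[gt]
            rep = _median_start_record([rec for _, rec in supporters])
            consensus.append(
                ConsensusCall(
                    record=replace(rep, genotype=gt),
                    supporting_callers=frozenset(c for c, _ in supporters),
                    genotype=gt,
                )
            )
    consensus.sort(key=lambda c: (c.record.chrom, c.record.start, c.record.id))
    return consensus


def filter_n_runs(calls: Sequence, max_run: int = 10) -> list:
    """Drop calls whose alt sequence contains a run of more than ``max_run`` Ns.

    Accepts :class:`SVRecord` or :class:`ConsensusCall` items; calls
    without an alt sequence are retained (vacuous condition).
    """
    needle = "N" * (max_run + 1)
    kept = []
    for call in calls:
        rec = call.record if isinstance(call, ConsensusCall) else call
        seq = rec.alt_seq
        if seq is not None and needle in seq.upper():
            continue
        kept.append(call)
    return kept


# ---------------------------------------------------------------------------
# cohort merge
# ---------------------------------------------------------------------------


def merge_cohort(
    consensus: Mapping[str, Sequence[ConsensusCall]],
    max_dist: int = 1000,
    min_support_individuals: int = 4,
    min_size: int = 50,
    chrom_order: Sequence[str] | None = None,
) -> CohortSVMatrix:
    """Merge per-individual consensus calls into a cohort dosage matrix.

    Calls of the same SV type are clustered across individuals when both
    breakpoints are within ``max_dist``; clusters supported by at least
    ``min_support_individuals`` individuals are retained.  The
    representative locus is the member with lower-median start.
    Individuals without a call at a retained locus get dosage 0.  Loci
    come out sorted by (chromosome, start); chromosomes follow
    ``chrom_order`` when given, else lexicographic name order.
    """
    if not consensus:
        raise ValueError("no individuals supplied")
    if len(consensus) < min_support_individuals:
        raise ValueError(
            f"need >= {min_support_individuals} individuals, got {len(consensus)}"
        )
    individuals = list(consensus)
    ind_index = {name: i for i, name in enumerate(individuals)}
    by_key: dict[tuple, list[tuple[str, SVRecord]]] = {}
    for ind, calls in consensus.items():
        for call in calls:
            rec = replace(call.record, genotype=call.genotype)
            if rec.length < min_size:
                continue
            by_key.setdefault((rec.chrom, rec.svtype), []).append((ind, rec))
    if chrom_order is None:
        rank = {c: i for i, c in enumerate(sorted({c for c, _ in by_key}))}
    else:
        rank = {c: i for i, c in enumerate(chrom_order)}
        unknown = {c for c, _ in by_key} - set(rank)
        if unknown:
            raise ValueError(f"calls on chromosomes outside chrom_order: {sorted(unknown)}")
    loci: list[SVRecord] = []
    rows: list[np.ndarray] = []
    n_ind = len(individuals)
    for key in sorted(by_key, key=lambda k: (rank[k[0]], k[1])):
        for members in _cluster(by_key[key], max_dist):
            # one call per individual: _cluster already refuses same-source repeats
            if len(members) < min_support_individuals:
                continue
            rep = _median_start_record([rec for _, rec in members])
            row = np.zeros(n_ind, dtype=np.int16)
            for ind, rec in members:
                row[ind_index[ind]] = rec.genotype
            loci.append(replace(rep, genotype=MISSING, caller=""))
            rows.append(row)
    if loci:
        order = np.lexsort(
            (
                np.array([r.start for r in loci]),
                np.array([rank[r.chrom] for r in loci]),
            )
        )
        loci = [loci[i] for i in order]
        dosages = np.stack([rows[i] for i in order])
    else:
        dosages = np.zeros((0, n_ind), dtype=np.int16)
    return CohortSVMatrix(loci, individuals, dosages)


def maf_filter(matrix: CohortSVMatrix, min_maf: float = 0.05) -> CohortSVMatrix:
    """Keep loci with minor-allele frequency >= ``min_maf`` (boundary kept)."""
    maf = matrix.maf
    keep = np.nan_to_num(maf, nan=-1.0) >= min_maf
    if not keep.any():
        warnings.warn("MAF filter removed all loci", stacklevel=2)
    return matrix.subset_loci(keep)
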