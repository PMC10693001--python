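"""Readers and writers for the standard formats the pipeline touches.

Every interval held in memory is 0-based, half-open.  The converters in
this module are the only place where coordinate arithmetic between
conventions (1-based VCF POS, 1-based closed GFF3) happens.

Insertions occupy a 1-bp breakpoint interval ``[start, start+1)``; their
inserted length is carried in :attr:`SVRecord.length`.  Translocations are
stored with the source interval only so that interval analyses always have
one locatable span.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

#: dosage code for a missing genotype
MISSING = -1

SVTYPES = ("DEL", "INS", "DUP", "INV", "TRA")

REPEAT_CLASSES = ("Simple", "LTR", "LINE/CR1", "LowComplexity", "DNA", "SINE", "Other")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class GenomeLayout:
    """Chromosome names and lengths, with an optional sequence handle.

    Parameters
    ----------
    chrom_lengths
        Mapping of chromosome name to length in bp, in the order the
        chromosomes should be written to output files.
    fasta
        Optional path to an indexed FASTA used for GC computations.
    """

    def __init__(self, chrom_lengths: dict[str, int], fasta: str | Path | None = None):
        names = list(chrom_lengths)
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        self.names: list[str] = names
        self._fasta_path = Path(fasta) if fasta is not None else None
        self._fasta = None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Fetch sequence for ``[start, end)``; requires a FASTA handle."""
        if self._fasta_path is None:
            raise ValueError("layout has no sequence handle")
        if self._fasta is None:
            self._fasta = pysam.FastaFile(str(self._fasta_path))
        return self._fasta.fetch(chrom, start, end)

    @property
    def has_sequence(self) -> bool:
        return self._fasta_path is not None

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.chrom_lengths[chrom]:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {self.chrom_lengths[chrom]})"
            )

    @classmethod
    def from_table(cls, path: str | Path, fasta: str | Path | None = None) -> "GenomeLayout":
        """Read a two-column (name, length) TSV, e.g. the first columns of a .fai."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["name", "length"])
        return cls(dict(zip(df["name"].astype(str), df["length"].astype(int))), fasta=fasta)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.names:
                fh.write(f"{name}\t{self.chrom_lengths[name]}\n")


@dataclass
class SVRecord:
    """One structural variant with a single-individual genotype dosage.

    ``start``/``end`` are 0-based half-open.  ``length`` equals
    ``end - start`` for DEL/INV/DUP and the inserted length for INS
    (whose interval is the 1-bp breakpoint).  ``genotype`` is an alt-allele
    dosage in {0, 1, 2} or :data:`MISSING`.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    genotype: int = MISSING
    caller: str = ""
    alt_seq: str | None = None
    partner: str | None = None  # TRA only: partner breakpoint, "chrom:pos"

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown SV type {self.svtype!r} for record {self.id!r}")
        if self.end < self.start:
            raise ValueError(f"record {self.id!r}: end < start")
        if self.length < 1:
            raise ValueError(f"record {self.id!r}: length must be >= 1")
        if self.svtype == "INS":
            if self.end != self.start + 1:
                raise ValueError(f"INS record {self.id!r} must span a 1-bp breakpoint")
        elif self.svtype != "TRA" and self.length != self.end - self.start:
            raise ValueError(f"record {self.id!r}: length != end - start")
        if self.genotype not in (0, 1, 2, MISSING):
            raise ValueError(f"record {self.id!r}: bad dosage {self.genotype}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class RepeatAnnotation:
    """Repeat intervals with class labels, 0-based half-open."""

    table: pd.DataFrame  # columns: chrom, start, end, repeat_class

    def __len__(self) -> int:
        return len(self.table)

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.table.groupby("chrom", sort=False)}


@dataclass
class GeneAnnotation:
    """Gene intervals with ids and strand, 0-based half-open."""

    table: pd.DataFrame  # columns: gene_id, chrom, start, end, strand

    def __len__(self) -> int:
        return len(self.table)


def _norm_lon(lon: float) -> float:
    """Normalize a longitude to (-180, 180]."""
    lon = (lon + 180.0) % 360.0 - 180.0
    return 180.0 if lon == -180.0 else lon


@dataclass
class TrackedBird:
    """A geolocator-tracked individual with breeding/wintering sites."""

    bird_id: str
    sex: str  # "M", "F" or "unknown"
    breeding: tuple[float, float]  # (lat N, lon E)
    wintering: tuple[float, float]
    daily_positions: list[tuple[_dt.date, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "unknown"):
            raise ValueError(f"bird {self.bird_id!r}: sex must be M, F or unknown")
        for lat, lon in (self.breeding, self.wintering):
            if abs(lat) > 90:
                raise ValueError(f"bird {self.bird_id!r}: |lat| > 90")
        self.breeding = (self.breeding[0], _norm_lon(self.breeding[1]))
        self.wintering = (self.wintering[0], _norm_lon(self.wintering[1]))
        dates = [d for d, _, _ in self.daily_positions]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"bird {self.bird_id!r}: dates not strictly increasing")
        self.daily_positions = [
            (d, lat, _norm_lon(lon)) for d, lat, lon in self.daily_positions
        ]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _info_opt(info, key):
    """INFO lookup tolerant of keys absent from the header (pysam raises)."""
    try:
        return info.get(key)
    except (KeyError, ValueError):
        return None


_GT_TO_DOSAGE = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 0): 1,
    (1, 1): 2,
    (None, None): MISSING,
    (None,): MISSING,
}


def read_sv_vcf(path: str | Path, caller_label: str | None = None) -> list[SVRecord]:
    """Read a single-sample SV VCF into :class:`SVRecord` objects.

    VCF POS (1-based) becomes the 0-based ``start``; a missing END is
    reconstructed from SVLEN.  Records with an SVTYPE outside
    ``{DEL, INS, DUP, INV, TRA}`` are skipped and counted in a single
    warning.  The caller label is taken from the INFO ``CALLER`` tag when
    present, else from ``caller_label``.
    """
    records: list[SVRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        if len(vcf.header.samples) < 1:
            raise ValueError(f"{path}: VCF has no sample column (GT required)")
        for rec in vcf:
            info = rec.info
            svtype = _info_opt(info, "SVTYPE")
            if svtype not in SVTYPES:
                skipped += 1
                continue
            rid = rec.id if rec.id is not None else f"{rec.chrom}:{rec.pos}"
            start = rec.pos - 1
            svlen = _info_opt(info, "SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            svlen = abs(int(svlen)) if svlen is not None else None
            if svtype == "INS":
                if svlen is None:
                    raise ValueError(f"{path}: INS record {rid!r} lacks SVLEN")
                end, length = start + 1, svlen
            else:
                # pysam folds INFO END into rec.stop; with no END it derives
                # stop from SVLEN as pos + SVLEN (one past our half-open end)
                if svlen is not None and rec.stop == rec.pos + svlen:
                    end = start + svlen
                elif rec.stop > start + 1:
                    end = rec.stop
                elif svlen is not None:
                    end = start + svlen
                else:
                    raise ValueError(f"{path}: record {rid!r} has neither END nor SVLEN")
                length = svlen if svtype == "TRA" and svlen is not None else end - start
            sample = rec.samples[0]
            if "GT" not in sample:
                raise ValueError(f"{path}: record {rid!r} has no GT field")
            gt = tuple(sample["GT"])
            if gt not in _GT_TO_DOSAGE:
                raise ValueError(f"{path}: record {rid!r} has unsupported GT {gt!r}")
            seq = _info_opt(info, "SEQ")
            partner = _info_opt(info, "PARTNER")
            records.append(
                SVRecord(
                    id=str(rid),
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    svtype=str(svtype),
                    length=int(length),
                    genotype=_GT_TO_DOSAGE[gt],
                    caller=str(_info_opt(info, "CALLER") or caller_label or ""),
                    alt_seq=str(seq) if seq is not None else None,
                    partner=str(partner) if partner is not None else None,
                )
            )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} record(s) with unknown SVTYPE", stacklevel=2)
    return records


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_VCF_HEADER_META = (
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End of the variant (1-based inclusive)">\n'
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n'
    '##INFO=<ID=SEQ,Number=1,Type=String,Description="Inserted/alt sequence">\n'
    '##INFO=<ID=CALLER,Number=1,Type=String,Description="Originating caller">\n'
    '##INFO=<ID=PARTNER,Number=1,Type=String,Description="Partner breakpoint (TRA)">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_sv_vcf(
    records: Sequence[SVRecord],
    layout: GenomeLayout,
    path: str | Path,
    sample: str = "sample",
) -> None:
    """Write records to a VCF 4.2 file (symbolic ALT, INFO SVTYPE/END/SVLEN).

    Records must be sorted by the layout's chromosome order and start.
    ``read_sv_vcf(write_sv_vcf(x))`` round-trips all fields.
    """
    order = {name: i for i, name in enumerate(layout.names)}
    last: tuple[int, int] | None = None
    lines: list[str] = []
    for rec in records:
        if rec.chrom not in order:
            raise ValueError(f"record {rec.id!r}: unknown chromosome {rec.chrom!r}")
        if rec.end > layout.length(rec.chrom):
            raise ValueError(f"record {rec.id!r} extends beyond chromosome {rec.chrom!r}")
        key = (order[rec.chrom], rec.start)
        if last is not None and key < last:
            raise ValueError("records not sorted by layout chromosome order and start")
        last = key
        info = [f"SVTYPE={rec.svtype}", f"END={rec.end}", f"SVLEN={rec.length}"]
        if rec.alt_seq:
            info.append(f"SEQ={rec.alt_seq}")
        if rec.caller:
            info.append(f"CALLER={rec.caller}")
        if rec.partner:
            info.append(f"PARTNER={rec.partner}")
        lines.append(
            f"{rec.chrom}\t{rec.start + 1}\t{rec.id}\tN\t<{rec.svtype}>\t.\tPASS\t"
            f"{';'.join(info)}\tGT\t{_DOSAGE_TO_GT[rec.genotype]}\n"
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in layout.names:
            fh.write(f"##contig=<ID={name},length={layout.chrom_lengths[name]}>\n")
        fh.write(_VCF_HEADER_META)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# BED / GFF3 / phenotype CSV
# ---------------------------------------------------------------------------


def read_bed_repeats(path: str | Path, layout: GenomeLayout | None = None) -> RepeatAnnotation:
    """Read a BED4 repeat track (0-based half-open; 4th column = class)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "repeat_class"],
        dtype={"chrom": str, "repeat_class": str},
    )
    if df["repeat_class"].isna().any():
        raise ValueError(f"{path}: BED4 requires a repeat class in column 4")
    df["repeat_class"] = df["repeat_class"].where(
        df["repeat_class"].isin(REPEAT_CLASSES), "Other"
    )
    if layout is not None:
        for chrom, g in df.groupby("chrom"):
            if chrom not in layout:
                raise ValueError(f"{path}: unknown chromosome {chrom!r}")
            if (g["start"] < 0).any() or (g["end"] > layout.length(str(chrom))).any():
                raise ValueError(f"{path}: interval outside chromosome {chrom!r}")
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: empty or inverted BED interval")
    return RepeatAnnotation(df.reset_index(drop=True))


def write_bed_repeats(annotation: RepeatAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", header=False, index=False)


def read_gff_genes(path: str | Path, layout: GenomeLayout | None = None) -> GeneAnnotation:
    """Read gene features from a GFF3 file (1-based closed -> half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=[
            "chrom", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes",
        ],
        dtype={"chrom": str},
    )
    genes = df[df["type"] == "gene"].copy()
    gene_ids = genes["attributes"].str.extract(r"ID=([^;]+)", expand=False)
    if gene_ids.isna().any():
        raise ValueError(f"{path}: gene feature without an ID attribute")
    out = pd.DataFrame(
        {
            "gene_id": gene_ids.values,
            "chrom": genes["chrom"].values,
            "start": genes["start"].values - 1,  # GFF3 is 1-based closed
            "end": genes["end"].values,
            "strand": genes["strand"].values,
        }
    )
    if layout is not None:
        for chrom, g in out.groupby("chrom"):
            if chrom not in layout:
                raise ValueError(f"{path}: unknown chromosome {chrom!r}")
            if (g["start"] < 0).any() or (g["end"] > layout.length(str(chrom))).any():
                raise ValueError(f"{path}: gene outside chromosome {chrom!r}")
    return GeneAnnotation(out.reset_index(drop=True))


def write_gff_genes(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.table.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tmigrasv\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_phenotype_table(
    path: str | Path, tracks_path: str | Path | None = None
) -> list[TrackedBird]:
    """Read the bird table (one row per bird) and optional daily tracks.

    The bird CSV must have columns ``bird_id, sex, breeding_lat,
    breeding_lon, wintering_lat, wintering_lon``; the tracks CSV has
    ``bird_id, date, lat, lon`` with ISO-8601 dates.
    """
    birds_df = pd.read_csv(path, dtype={"bird_id": str})
    required = {
        "bird_id", "sex", "breeding_lat", "breeding_lon", "wintering_lat", "wintering_lon",
    }
    missing = required - set(birds_df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if birds_df["bird_id"].duplicated().any():
        dup = birds_df.loc[birds_df["bird_id"].duplicated(), "bird_id"].iloc[0]
        raise ValueError(f"{path}: duplicate bird_id {dup!r}")
    tracks: dict[str, list[tuple[_dt.date, float, float]]] = {}
    if tracks_path is not None:
        tr = pd.read_csv(tracks_path, dtype={"bird_id": str})
        tr["date"] = pd.to_datetime(tr["date"]).dt.date
        for bird_id, g in tr.groupby("bird_id", sort=False):
            g = g.sort_values("date")
            tracks[str(bird_id)] = list(
                zip(g["date"], g["lat"].astype(float), g["lon"].astype(float))
            )
    birds = []
    for row in birds_df.itertuples(index=False):
        birds.append(
            TrackedBird(
                bird_id=str(row.bird_id),
                sex=str(row.sex),
                breeding=(float(row.breeding_lat), float(row.breeding_lon)),
                wintering=(float(row.wintering_lat), float(row.wintering_lon)),
                daily_positions=tracks.get(str(row.bird_id), []),
            )
        )
    return birds


def write_phenotype_table(
    birds: Iterable[TrackedBird], path: str | Path, tracks_path: str | Path | None = None
) -> None:
    birds = list(birds)
    rows = [
        {
            "bird_id": b.bird_id,
            "sex": b.sex,
            "breeding_lat": b.breeding[0],
            "breeding_lon": b.breeding[1],
            "wintering_lat": b.wintering[0],
            "wintering_lon": b.wintering[1],
        }
        for b in birds
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    if tracks_path is not None:
        track_rows = []
        for b in birds:
            for d, lat, lon in b.daily_positions:
                track_rows.append({"bird_id": b.bird_id, "date": d.isoformat(), "lat": lat, "lon": lon})
        pd.DataFrame(track_rows).to_csv(tracks_path, index=False)
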