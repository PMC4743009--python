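"""Reading and writing of junction tables, genomes and branchpoint catalogues.

Coordinate conventions used throughout the package:

* Genomic intervals are 0-based, half-open (BED native). A junction's intron
  is ``[intron_start, intron_end)``.
* Positions around a splice site are *transcript oriented*: ``+1`` is the
  first exonic base, ``-1`` the last intronic base (the G of the acceptor
  AG). There is no position 0. Minus-strand arithmetic is confined to this
  module; everything downstream works in transcript orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Junction",
    "SampleSheet",
    "AcceptorSite",
    "ParseError",
    "WindowError",
    "read_junction_bed",
    "write_junction_bed",
    "junctions_to_frame",
    "frame_to_junctions",
    "acceptor_of",
    "donor_of",
    "extract_window",
    "fetch",
    "reverse_complement",
    "read_branchpoint_catalogue",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


class ParseError(ValueError):
    """A malformed record in an input file."""


class WindowError(ValueError):
    """A requested sequence window falls outside its contig."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Junction:
    """One intron observed in RNA-seq with per-sample read support."""

    id: str
    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValueError(
                f"{self.id}: intron_start {self.intron_start} must be < "
                f"intron_end {self.intron_end}"
            )
        if self.strand not in "+-":
            raise ParseError(f"{self.id}: unknown strand {self.strand!r}")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.id}: negative count")

    @property
    def donor_pos(self) -> int:
        """Genomic coordinate identifying the donor (5'ss) end."""
        return self.intron_start if self.strand == "+" else self.intron_end

    @property
    def acceptor_pos(self) -> int:
        """Genomic coordinate identifying the acceptor (3'ss) end."""
        return self.intron_end if self.strand == "+" else self.intron_start


@dataclass(frozen=True)
class SampleSheet:
    """Cohort description: ordered sample ids, MUT/WT labels, optional f_mut."""

    ids: tuple[str, ...]
    groups: tuple[str, ...]
    mutant_fraction: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sample ids must be unique")
        if len(self.groups) != len(self.ids):
            raise ValueError("groups length must match ids")
        bad = set(self.groups) - {"MUT", "WT"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.mutant_fraction is not None:
            if len(self.mutant_fraction) != len(self.ids):
                raise ValueError("mutant_fraction length must match ids")
            if any(not (0.0 <= f <= 1.0) for f in self.mutant_fraction):
                raise ValueError("mutant_fraction values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_mut(self) -> np.ndarray:
        return np.array([g == "MUT" for g in self.groups])

    def fraction_of(self, sample: str) -> float:
        try:
            i = self.ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None
        if self.mutant_fraction is not None:
            return self.mutant_fraction[i]
        return 1.0 if self.groups[i] == "MUT" else 0.0


@dataclass(frozen=True)
class AcceptorSite:
    """A 3' splice site anchored so transcript positions map to the genome.

    ``anchor`` is the genomic coordinate such that position -1 (the G of the
    AG) is the base at ``anchor - 1`` on the plus strand, or at ``anchor`` on
    the minus strand. For a plus-strand junction the anchor is ``intron_end``
    (the first exonic base); for minus strand it is ``intron_start``.
    """

    chrom: str
    strand: str
    anchor: int

    def genomic(self, pos: int) -> int:
        """Genomic coordinate of transcript-oriented position ``pos`` (no 0)."""
        if pos == 0:
            raise ValueError("position 0 does not exist (+1/-1 convention)")
        if self.strand == "+":
            return self.anchor + pos if pos < 0 else self.anchor + pos - 1
        return self.anchor - 1 - pos if pos < 0 else self.anchor - pos

    @property
    def exon_start(self) -> int:
        """Genomic coordinate of the first exonic base (+1)."""
        return self.genomic(1)


def acceptor_of(junction: Junction) -> AcceptorSite:
    anchor = junction.intron_end if junction.strand == "+" else junction.intron_start
    return AcceptorSite(junction.chrom, junction.strand, anchor)


def donor_of(junction: Junction) -> AcceptorSite:
    """The donor end, with the same anchoring convention mirrored 5'-wards.

    Position -1 of the returned site is the last base of the *upstream exon*
    and +1 the first intronic base, i.e. positions increase 5'->3' along the
    transcript into the intron.
    """
    anchor = junction.intron_start if junction.strand == "+" else junction.intron_end
    return AcceptorSite(junction.chrom, junction.strand, anchor)


# ---------------------------------------------------------------------------
# FASTA access


def read_fasta(path: str | Path):
    """Open an indexed FASTA with pyfaidx."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


def write_fasta(contigs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in contigs:
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _contig_names(genome) -> list[str]:
    return list(genome.keys())


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Plus-strand sequence of ``[start, end)``; errors on out-of-bounds.

    ``genome`` may be a pyfaidx ``Fasta`` or any mapping of name -> string.
    """
    try:
        record = genome[chrom]
    except KeyError:
        raise KeyError(
            f"contig {chrom!r} not in genome; available: {_contig_names(genome)}"
        ) from None
    length = len(record)
    if start < 0 or end > length:
        raise WindowError(
            f"window [{start}, {end}) outside contig {chrom} of length {length}"
        )
    piece = record[start:end]
    return str(piece).upper()


def extract_window(genome, site: AcceptorSite, intron_flank: int, exon_flank: int) -> str:
    """Transcript-oriented window around a splice site.

    The returned string has length ``intron_flank + exon_flank`` and covers
    positions ``-intron_flank .. -1, +1 .. +exon_flank``; for genuine
    acceptors the AG dinucleotide sits at string indices ``intron_flank - 2``
    and ``intron_flank - 1``.
    """
    if site.strand == "+":
        start = site.anchor - intron_flank
        end = site.anchor + exon_flank
        return fetch(genome, site.chrom, start, end)
    start = site.anchor - exon_flank
    end = site.anchor + intron_flank
    return reverse_complement(fetch(genome, site.chrom, start, end))


# ---------------------------------------------------------------------------
# Junction tables

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_junction_bed(
    path: str | Path,
    dialect: str = "intron-bed6",
    sample_sheet: SampleSheet | None = None,
) -> list[Junction]:
    """Read a junction BED file.

    ``dialect`` is one of:

    * ``"tophat-bed12"`` — TopHat ``junctions.bed``: each record spans the two
      anchoring read blocks; the intron is the gap between them
      (``[chromStart + blockSize0, chromEnd - blockSize1)``). The score column
      is used as the (single) count.
    * ``"intron-bed6"`` — intron coordinates given directly; extra columns
      beyond the sixth are per-sample counts in sample-sheet order. Without
      extra columns the score column is the count.
    """
    if dialect not in ("tophat-bed12", "intron-bed6"):
        raise ValueError(f"unknown dialect {dialect!r}")
    junctions: list[Junction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if dialect == "tophat-bed12":
                    j = _parse_bed12(fields, lineno)
                else:
                    j = _parse_intron_bed6(fields, lineno, sample_sheet)
            except ParseError:
                raise
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if j is not None:
                junctions.append(j)
    return junctions


def _parse_bed12(fields: Sequence[str], lineno: int) -> Junction | None:
    if len(fields) < 12:
        raise ParseError(f"line {lineno}: BED12 record needs >=12 columns")
    chrom, start, end, name, score, strand = fields[:6]
    block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    if len(block_sizes) != 2:
        warnings.warn(
            f"line {lineno}: record {name!r} has {len(block_sizes)} blocks, "
            "expected 2; rejected",
            stacklevel=3,
        )
        return None
    intron_start = int(start) + block_sizes[0]
    intron_end = int(end) - block_sizes[1]
    return Junction(
        id=name,
        chrom=chrom,
        intron_start=intron_start,
        intron_end=intron_end,
        strand=strand,
        counts=(int(float(score)),),
    )


def _parse_intron_bed6(
    fields: Sequence[str], lineno: int, sheet: SampleSheet | None
) -> Junction:
    if len(fields) < 6:
        raise ParseError(f"line {lineno}: intron BED6 record needs >=6 columns")
    chrom, start, end, name, score, strand = fields[:6]
    extra = fields[6:]
    if extra:
        counts = tuple(int(float(x)) for x in extra)
        if sheet is not None and len(counts) != sheet.n:
            raise ParseError(
                f"line {lineno}: {len(counts)} count columns but sample sheet "
                f"has {sheet.n} samples"
            )
    else:
        counts = (int(float(score)),)
    return Junction(
        id=name,
        chrom=chrom,
        intron_start=int(start),
        intron_end=int(end),
        strand=strand,
        counts=counts,
    )


def write_junction_bed(
    junctions: Iterable[Junction],
    path: str | Path,
    sample_sheet: SampleSheet | None = None,
) -> None:
    """Write the canonical intron-BED6+counts TSV (commented header line)."""
    junctions = list(junctions)
    with open(path, "w") as fh:
        header = _BED_COLUMNS.copy()
        if sample_sheet is not None:
            header += list(sample_sheet.ids)
        elif junctions and len(junctions[0].counts) > 1:
            header += [f"s{i}" for i in range(len(junctions[0].counts))]
        fh.write("#" + "\t".join(header) + "\n")
        for j in junctions:
            total = int(sum(j.counts))
            row = [j.chrom, str(j.intron_start), str(j.intron_end), j.id, str(total), j.strand]
            if sample_sheet is not None or len(j.counts) > 1:
                row += [str(c) for c in j.counts]
            fh.write("\t".join(row) + "\n")


def junctions_to_frame(
    junctions: Iterable[Junction], sample_sheet: SampleSheet | None = None
) -> pd.DataFrame:
    """Tabular view: one row per junction, count columns per sample."""
    junctions = list(junctions)
    cols = (
        list(sample_sheet.ids)
        if sample_sheet is not None
        else [f"s{i}" for i in range(len(junctions[0].counts))]
    )
    rows = []
    for j in junctions:
        rows.append(
            {
                "id": j.id,
                "chrom": j.chrom,
                "start": j.intron_start,
                "end": j.intron_end,
                "strand": j.strand,
                **dict(zip(cols, j.counts)),
            }
        )
    df = pd.DataFrame(rows)
    return df.set_index("id", drop=False)


def frame_to_junctions(df: pd.DataFrame, sample_ids: Sequence[str]) -> list[Junction]:
    out = []
    for _, row in df.iterrows():
        out.append(
            Junction(
                id=row["id"],
                chrom=row["chrom"],
                intron_start=int(row["start"]),
                intron_end=int(row["end"]),
                strand=row["strand"],
                counts=tuple(int(row[s]) for s in sample_ids),
            )
        )
    return out


def merge_junction_files(
    paths: Sequence[str | Path], sample_ids: Sequence[str], dialect: str = "tophat-bed12"
) -> list[Junction]:
    """Merge one-BED-per-sample inputs on exact (chrom, start, end, strand).

    Junctions absent from a sample get count 0 there. Chromosome names are
    matched verbatim — ``chr1`` and ``1`` never merge.
    """
    if len(paths) != len(sample_ids):
        raise ValueError("one path per sample id required")
    table: dict[tuple, list[int]] = {}
    names: dict[tuple, str] = {}
    for s, path in enumerate(paths):
        for j in read_junction_bed(path, dialect=dialect):
            key = (j.chrom, j.intron_start, j.intron_end, j.strand)
            if key not in table:
                table[key] = [0] * len(sample_ids)
                names[key] = j.id
            table[key][s] += j.counts[0]
    out = []
    for key in sorted(table):
        chrom, start, end, strand = key
        out.append(
            Junction(
                id=names[key],
                chrom=chrom,
                intron_start=start,
                intron_end=end,
                strand=strand,
                counts=tuple(table[key]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Branchpoint catalogue and sample sheets


def read_branchpoint_catalogue(path: str | Path) -> list[tuple[str, int, str]]:
    """BED-like catalogue of experimentally mapped branchpoint adenosines.

    Returns ``(chrom, position, strand)`` tuples with 0-based positions.
    Intervals longer than one base are reduced to their midpoint with a
    warning.
    """
    out: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: need >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 else "+"
            if end - start != 1:
                warnings.warn(
                    f"{path}:{lineno}: interval length {end - start} != 1; "
                    "taking midpoint",
                    stacklevel=2,
                )
                pos = (start + end - 1) // 2
            else:
                pos = start
            out.append((chrom, pos, strand))
    return out


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    frac = None
    if "mutant_fraction" in df.columns:
        frac = tuple(float(x) for x in df["mutant_fraction"])
    return SampleSheet(
        ids=tuple(df["sample"].astype(str)),
        groups=tuple(df["group"].astype(str)),
        mutant_fraction=frac,
    )


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        cols = ["sample", "group"]
        if sheet.mutant_fraction is not None:
            cols.append("mutant_fraction")
        fh.write("#" + "\t".join(cols) + "\n")
        for i, sid in enumerate(sheet.ids):
            row = [sid, sheet.groups[i]]
            if sheet.mutant_fraction is not None:
                row.append(repr(float(sheet.mutant_fraction[i])))
            fh.write("\t".join(row) + "\n")
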