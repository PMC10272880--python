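"""Domain containers and plain-text I/O.

Shared types for the pipeline — an annotated bacterial genome, a probe-level
enrichment-ratio track — together with readers and writers for the standard
text formats they travel in (FASTA, GFF3, operon TSV, bedGraph).  All genomic
coordinates held in memory are 1-based inclusive, matching GFF3; bedGraph's
0-based half-open intervals are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class ParseError(ValueError):
    """A text input file is malformed; message carries the line number."""


# ---------------------------------------------------------------------------
# Annotated genome
# ---------------------------------------------------------------------------

STRANDS = ("+", "-")


@dataclass(frozen=True)
class Gene:
    """A protein-coding (or RNA) gene: closed 1-based interval plus strand."""

    id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.id!r}: strand must be + or -, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"gene {self.id!r}: invalid interval [{self.start}, {self.end}]"
            )

    @property
    def tss(self) -> int:
        """Position of the 5' end (transcription start side) of the gene."""
        return self.start if self.strand == "+" else self.end

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class AnnotatedGenome:
    """A genome with gene and operon annotation; sequence is optional.

    ``operons`` lists co-transcribed gene ids in transcription order
    (5' -> 3' of the unit), e.g. ``("lldP", "lldR", "lldD")``.
    """

    length: int
    genes: tuple[Gene, ...]
    operons: tuple[tuple[str, ...], ...] = ()
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"genome length must be positive, got {self.length}")
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValidationError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            if g.end > self.length:
                raise ValidationError(
                    f"gene {g.id!r} extends to {g.end}, beyond genome length {self.length}"
                )
        by_id = {g.id: g for g in self.genes}
        in_operon: set[str] = set()
        for unit in self.operons:
            if len(unit) < 1:
                raise ValidationError("empty operon")
            strands = set()
            for gid in unit:
                if gid not in by_id:
                    raise ValidationError(f"operon references unknown gene {gid!r}")
                if gid in in_operon:
                    raise ValidationError(f"gene {gid!r} assigned to more than one operon")
                in_operon.add(gid)
                strands.add(by_id[gid].strand)
            if len(strands) != 1:
                raise ValidationError(f"operon {unit} mixes strands")
            starts = [by_id[gid].start for gid in unit]
            ordered = starts == sorted(starts) if strands == {"+"} else starts == sorted(
                starts, reverse=True
            )
            if not ordered:
                raise ValidationError(
                    f"operon {unit} is not listed in transcription order"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"sequence length {len(self.sequence)} != genome length {self.length}"
            )

    # -- lookups -----------------------------------------------------------

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise ValidationError(f"unknown gene id {gene_id!r}")

    def genes_by_start(self) -> tuple[Gene, ...]:
        return tuple(sorted(self.genes, key=lambda g: (g.start, g.end)))

    def operon_of(self, gene_id: str) -> tuple[str, ...] | None:
        self.gene(gene_id)  # raise on unknown id
        for unit in self.operons:
            if gene_id in unit:
                return unit
        return None

    def subsequence(self, start: int, end: int) -> str:
        """1-based inclusive slice of the genome sequence (clipped to bounds)."""
        if self.sequence is None:
            raise ValidationError("genome has no sequence")
        start = max(1, start)
        end = min(self.length, end)
        return self.sequence[start - 1 : end]


# ---------------------------------------------------------------------------
# Probe-ratio track
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeTrack:
    """Sorted probe centres and their enrichment ratios over one genome.

    The ratio is a dimensionless Cy3/Cy5-style enrichment value with a
    baseline near 1; a binding site appears as a local excursion above it.
    """

    positions: np.ndarray  # int64, strictly increasing, 1-based bp
    ratios: np.ndarray  # float64, >= 0
    genome_length: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        rat = np.asarray(self.ratios, dtype=np.float64)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "ratios", rat)
        if pos.shape != rat.shape or pos.ndim != 1:
            raise ValidationError("positions and ratios must be equal-length 1-D arrays")
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValidationError("probe positions must be strictly increasing")
        if np.any(rat < 0):
            raise ValidationError("ratios must be non-negative")
        if pos.size and (pos[0] < 1 or pos[-1] > self.genome_length):
            raise ValidationError("probe positions outside genome bounds")

    def __len__(self) -> int:
        return int(self.positions.size)

    def median_spacing(self) -> float:
        if len(self) < 2:
            return float("nan")
        return float(np.median(np.diff(self.positions)))

    def __eq__(self, other: object) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, ProbeTrack):
            return NotImplemented
        return (
            self.genome_length == other.genome_length
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.ratios, other.ratios)
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

DEFAULT_SEQID = "chr"


def write_fasta(genome: AnnotatedGenome, path: str | Path, seqid: str = DEFAULT_SEQID) -> None:
    if genome.sequence is None:
        raise ValidationError("cannot write FASTA: genome has no sequence")
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(genome.sequence), id=seqid, description="")
    seqio_write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> str:
    """Read a single-record FASTA into an uppercase DNA string."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return str(records[0].seq).upper()


def read_fasta_regions(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA of region sequences, keyed by record id."""
    from Bio import SeqIO

    regions: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in regions:
            raise ParseError(f"{path}: duplicate region id {rec.id!r}")
        regions[rec.id] = str(rec.seq).upper()
    return regions


# ---------------------------------------------------------------------------
# GFF3 + operon TSV
# ---------------------------------------------------------------------------


def write_gff3(genome: AnnotatedGenome, path: str | Path, seqid: str = DEFAULT_SEQID) -> None:
    lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {genome.length}"]
    for g in genome.genes_by_start():
        lines.append(
            "\t".join(
                [seqid, "regulonmap", "gene", str(g.start), str(g.end), ".", g.strand, ".",
                 f"ID={g.id};Name={g.id}"]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, operons: Sequence[Sequence[str]] = (),
              sequence: str | None = None) -> AnnotatedGenome:
    """Load gene annotation from GFF3 (via gffutils) into an AnnotatedGenome.

    Genome length is taken from the ``##sequence-region`` directive, or from
    the supplied sequence, or from the rightmost feature end as a fallback.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    length = 0
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            length = int(parts[3])
    genes = []
    for feat in db.features_of_type("gene", order_by="start"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(Gene(id=gid, start=feat.start, end=feat.end, strand=feat.strand))
    if sequence is not None:
        length = len(sequence)
    if not length:
        length = max((g.end for g in genes), default=1)
    return AnnotatedGenome(
        length=length,
        genes=tuple(genes),
        operons=tuple(tuple(u) for u in operons),
        sequence=sequence,
    )


def write_operons(genome: AnnotatedGenome, path: str | Path) -> None:
    """Operon table: one row per unit — operon_id, comma-joined ordered gene ids."""
    lines = ["operon_id\tgenes"]
    for i, unit in enumerate(genome.operons, start=1):
        lines.append(f"TU{i:03d}\t{','.join(unit)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_operons(path: str | Path) -> tuple[tuple[str, ...], ...]:
    units: list[tuple[str, ...]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("operon_id"):
            raise ParseError(f"{path}:1: expected header 'operon_id\\tgenes'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            units.append(tuple(fields[1].split(",")))
    return tuple(units)


# ---------------------------------------------------------------------------
# bedGraph track I/O
# ---------------------------------------------------------------------------


def write_track(track: ProbeTrack, path: str | Path, span: int | None = None,
                seqid: str = DEFAULT_SEQID) -> None:
    """Write a probe track as bedGraph.

    Each probe becomes a 0-based half-open interval of width ``span`` centred
    on the probe position (default: the track's median probe spacing, so a
    regular grid tiles the genome without gaps).
    """
    if span is None:
        med = track.median_spacing()
        span = int(med) if np.isfinite(med) else 1
    if span < 1:
        raise ValidationError(f"span must be positive, got {span}")
    if len(track) >= 2:
        span = min(span, int(np.min(np.diff(track.positions))))
    lines = []
    for pos, ratio in zip(track.positions, track.ratios):
        p = int(pos)
        # interval [s, s+w) reads back as centre s + w//2 + 1 == p
        w = max(1, min(span, 2 * (p - 1)))
        s = p - 1 - w // 2
        lines.append(f"{seqid}\t{s}\t{s + w}\t{float(ratio)!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_track(path: str | Path, genome_length: int | None = None) -> ProbeTrack:
    """Read a bedGraph file into a ProbeTrack.

    The probe centre is the interval midpoint, converted to 1-based
    coordinates.  Intervals must be sorted and non-overlapping; violations
    raise :class:`ParseError` with the offending line number.
    """
    positions: list[int] = []
    ratios: list[float] = []
    prev_end = -1
    seqids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            seqid, s, e, v = fields
            seqids.add(seqid)
            if len(seqids) > 1:
                raise ParseError(f"{path}:{lineno}: multiple sequence names; one expected")
            try:
                start0, end0, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if end0 <= start0:
                raise ParseError(f"{path}:{lineno}: empty or inverted interval")
            if start0 < prev_end:
                raise ParseError(f"{path}:{lineno}: unsorted or overlapping interval")
            prev_end = end0
            positions.append((start0 + end0) // 2 + 1)  # midpoint, 1-based
            ratios.append(value)
    if genome_length is None:
        genome_length = (positions[-1] + 1) if positions else 1
    return ProbeTrack(
        positions=np.asarray(positions, dtype=np.int64),
        ratios=np.asarray(ratios, dtype=np.float64),
        genome_length=genome_length,
    )
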