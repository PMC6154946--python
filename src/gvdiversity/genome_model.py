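"""Reference genome and ORF annotation model.

Granulovirus genomes are single circular dsDNA molecules of roughly 100 kb,
densely packed with coding sequence (~94% coding). Everything downstream —
read mapping, pileups, variant calls, codon effects — shares the coordinate
frame defined here: 0-based, half-open intervals on the forward strand.
Origin-spanning features are represented with ``end > genome length`` and
resolved modulo the length.

Annotated ORF intervals include the stop codon (GenBank CDS convention), so
coding lengths are multiples of 3 and the minimum ORF size of 150 bp counts
the stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlphabetError, AnnotationError, GenomeFormatError

ALPHABET = frozenset("ACGTN")
CATEGORIES = ("AUX", "MOD", "REP", "STR", "TRA", "UNK")
MIN_ORF_LEN = 150

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceGenome:
    """A single circular (or linear) nucleotide sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeFormatError(f"genome {self.id!r} has empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise AlphabetError(
                f"genome {self.id!r} contains illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def wrap(self, position: int) -> int:
        """Reduce a position into [0, length)."""
        return position % len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Circular slice: ``end`` may exceed the genome length (wraps) and
        ``start`` may be negative. On a linear genome out-of-range access is
        an error."""
        n = len(self.sequence)
        if not self.circular:
            if start < 0 or end > n:
                raise IndexError(f"[{start}, {end}) outside linear genome of {n} bp")
            return self.sequence[start:end]
        if end - start > n:
            raise IndexError(f"slice [{start}, {end}) longer than genome ({n} bp)")
        length = end - start
        start %= n
        end = start + length
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass(frozen=True)
class OrfAnnotation:
    """A strand-aware coding interval with functional metadata.

    ``end`` is exclusive and may exceed the genome length to represent an
    origin-wrapping ORF. ``category`` is one of the six functional labels
    (AUX auxiliary, MOD host modulation, REP replication, STR structural,
    TRA transcription, UNK unknown); ``is_core`` flags membership in the set
    of genes shared by all baculoviruses.
    """

    gene_id: str
    name: str
    start: int
    end: int
    strand: str
    category: str
    is_core: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, genome_length: int, min_len: int = MIN_ORF_LEN) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.category not in CATEGORIES:
            raise AnnotationError(
                f"{self.gene_id}: unknown category {self.category!r} "
                f"(expected one of {CATEGORIES})"
            )
        if self.length < min_len:
            raise AnnotationError(
                f"{self.gene_id}: coding length {self.length} bp below the "
                f"{min_len} bp minimum"
            )
        if self.length % 3 != 0:
            raise AnnotationError(
                f"{self.gene_id}: coding length {self.length} not a multiple of 3"
            )
        if not (0 <= self.start < genome_length):
            raise AnnotationError(
                f"{self.gene_id}: start {self.start} outside genome of "
                f"{genome_length} bp"
            )
        if self.length > genome_length:
            raise AnnotationError(f"{self.gene_id}: ORF longer than the genome")

    def contains(self, position: int, genome_length: int) -> bool:
        """Whether a (wrapped) reference position falls in this interval."""
        p = position % genome_length
        if self.start <= p < self.end:
            return True
        # origin-wrapping interval: also test the shifted copy
        return self.end > genome_length and p + genome_length < self.end

    def offset_of(self, position: int, genome_length: int) -> int:
        """Forward-strand offset of ``position`` within the interval."""
        p = position % genome_length
        if self.start <= p < self.end:
            return p - self.start
        if self.end > genome_length and p + genome_length < self.end:
            return p + genome_length - self.start
        raise ValueError(f"position {position} not inside {self.gene_id}")

    def coding_sequence(self, genome: ReferenceGenome) -> str:
        """The ORF sequence on its coding strand (starts with the start codon)."""
        s = genome.fetch(self.start, self.end)
        return s if self.strand == "+" else revcomp(s)


def load_reference(path: str | Path, circular: bool = True) -> ReferenceGenome:
    """Load a single-record FASTA file as a :class:`ReferenceGenome`.

    Lowercase input is accepted and uppercased. Zero or multiple records is
    a format error; characters outside {A,C,G,T,N} an alphabet error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GenomeFormatError(
            f"{path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    return ReferenceGenome(id=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_reference(genome: ReferenceGenome, path: str | Path) -> None:
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(path), "fasta")


_TSV_COLUMNS = ["gene_id", "name", "start", "end", "strand", "category", "is_core"]


def load_annotations(path: str | Path, genome: ReferenceGenome,
                     min_len: int = MIN_ORF_LEN) -> list[OrfAnnotation]:
    """Load ORF annotations from GFF3 (type CDS) or 7-column TSV.

    Every record is validated against the :class:`OrfAnnotation` invariants;
    overlapping ORFs are permitted and preserved. TSV coordinates are 0-based
    half-open; GFF3 follows its 1-based inclusive standard.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        annotations = _parse_gff3(path)
    else:
        annotations = _parse_tsv(path)
    seen: set[str] = set()
    for ann in annotations:
        if ann.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {ann.gene_id!r}")
        seen.add(ann.gene_id)
        ann.validate(len(genome), min_len=min_len)
    return annotations


def _parse_tsv(path: Path) -> list[OrfAnnotation]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing TSV columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(OrfAnnotation(
            gene_id=row.gene_id,
            name=row.name,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            category=row.category,
            is_core=str(row.is_core).strip().lower() in ("1", "true", "yes"),
        ))
    return out


def _parse_gff3(path: Path) -> list[OrfAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}: malformed GFF3 line: {line!r}")
            _, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype != "CDS":
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            out.append(OrfAnnotation(
                gene_id=attr.get("ID", ""),
                name=attr.get("Name", attr.get("ID", "")),
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                category=attr.get("category", "UNK"),
                is_core=attr.get("core", "false").lower() in ("1", "true", "yes"),
            ))
    return out


def write_annotations(annotations: Sequence[OrfAnnotation], path: str | Path) -> None:
    """Write annotations as the 7-column TSV dialect (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for a in annotations:
            fh.write("\t".join([
                a.gene_id, a.name, str(a.start), str(a.end), a.strand,
                a.category, "true" if a.is_core else "false",
            ]) + "\n")


def write_annotations_gff3(annotations: Sequence[OrfAnnotation],
                           genome: ReferenceGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for a in annotations:
            attrs = (f"ID={a.gene_id};Name={a.name};category={a.category};"
                     f"core={'true' if a.is_core else 'false'}")
            fh.write("\t".join([
                genome.id, "gvdiversity", "CDS", str(a.start + 1), str(a.end),
                ".", a.strand, "0", attrs,
            ]) + "\n")


def orf_scan(genome: ReferenceGenome, min_len: int = MIN_ORF_LEN) -> list[tuple[int, int, str]]:
    """All maximal ATG→stop open reading frames of length >= min_len.

    Scans six frames on both strands. "Maximal" means the first ATG after the
    previous in-frame stop; the returned interval includes the stop codon.
    On a circular genome the scan honors origin wrap: returned intervals may
    have ``end > length`` and are reported as ``(start, end, strand)`` with
    ``start`` in [0, length), sorted by start.
    """
    n = len(genome)
    if min_len > n:
        return []
    found: set[tuple[int, int, str]] = set()
    # circular: scan three copies and keep only middle-copy starts, so every
    # reported ORF is judged maximal with a full genome of upstream context
    # (a seam-truncated context can promote an internal in-frame ATG)
    scan_seq = genome.sequence * 3 if genome.circular else genome.sequence

    def scan(seq: str, strand: str) -> None:
        m = len(seq)
        for frame in range(3):
            atg = -1
            for i in range(frame, m - 2, 3):
                codon = seq[i:i + 3]
                if codon in STOP_CODONS:
                    if atg >= 0:
                        _record(atg, i + 3, strand)
                    atg = -1
                elif codon == START_CODON and atg < 0:
                    atg = i

    def _record(a: int, b: int, strand: str) -> None:
        length = b - a
        if length < min_len or length > n:
            return
        if strand == "+":
            start = a
        else:
            # coords on reverse-complement of scan_seq: map back to forward
            start = len(scan_seq) - b
        if genome.circular:
            if not n <= start < 2 * n:
                return
            start -= n
        found.add((start, start + length, strand))

    scan(scan_seq, "+")
    scan(revcomp(scan_seq), "-")
    return sorted(found)


def coding_fraction(genome: ReferenceGenome,
                    annotations: Iterable[OrfAnnotation]) -> float:
    """Fraction of genome positions covered by at least one ORF (union)."""
    n = len(genome)
    covered = np.zeros(n, dtype=bool)
    for ann in annotations:
        idx = np.arange(ann.start, ann.end) % n
        covered[idx] = True
    return float(covered.sum()) / n


def find_homopolymer_runs(genome: ReferenceGenome, min_len: int = 3) -> list[tuple[int, int, str]]:
    """Maximal single-base runs of length >= min_len, as (start, end, base).

    On a circular genome a run spanning the origin is reported once, with
    ``end > length``. These intervals drive pyrosequencing homopolymer
    error correction downstream.
    """
    s = genome.sequence
    n = len(s)
    runs: list[tuple[int, int, str]] = []
    i = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j, s[i]))
        i = j
    if genome.circular and n > 1 and s[0] == s[-1]:
        # a run crossing the origin may be built from two sub-threshold
        # pieces, so it is recomputed from the raw head/tail lengths
        head = 0
        while head < n and s[head] == s[0]:
            head += 1
        tail = n
        while tail > 0 and s[tail - 1] == s[-1]:
            tail -= 1
        if head < n and tail > 0:  # not a single-base genome
            span = (n - tail) + head
            if span >= min_len:
                runs = [r for r in runs
                        if not (r[0] == 0 and r[1] == head)
                        and not (r[0] == tail and r[1] == n)]
                runs.append((tail, n + head, s[0]))
    return sorted(runs)
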