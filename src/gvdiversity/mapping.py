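"""Read mapping, pileups and majority-rule consensus.

The mapper is a deliberately simple seed-and-extend aligner adequate for
near-identical viral reads: exact k-mer seeds against a circular index (the
reference doubled, positions reduced modulo length), diagonal voting, then
banded global extension with unit mismatch/gap costs (edit distance, via
edlib). Reads whose best alignment falls below ``min_identity`` or whose
best location is ambiguous (a tie between distinct loci) are discarded, so
variant frequencies stay unbiased. Reverse-complement orientation is tried
for every read; reads may span the origin without being split.

Pileups are per-position base/deletion counts with insertions recorded at
the column preceding the inserted sequence. The consensus caller is
majority-rule with ties broken toward the reference.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import pysam

from .errors import DataError
from .genome_model import ReferenceGenome, revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDMS])")

# ops that consume query / reference, SAM semantics
_CONSUMES_QUERY = {"M": True, "=": True, "X": True, "I": True, "S": True, "D": False}
_CONSUMES_REF = {"M": True, "=": True, "X": True, "I": False, "S": False, "D": True}


@dataclass
class AlignedRead:
    """One read placed on the reference.

    ``query`` is the read sequence in reference-forward orientation (already
    reverse-complemented for '-' strand reads). ``cigar`` uses M/I/D with
    SAM semantics; M spans both matches and mismatches. ``ref_start`` is a
    0-based position in [0, genome length); alignments may wrap the origin.
    """
    read_id: str
    ref_start: int
    strand: str
    cigar: list[tuple[str, int]]
    query: str
    identity: float
    edit_distance: int = 0

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if _CONSUMES_QUERY[op])
        if qlen != len(self.query):
            raise DataError(
                f"{self.read_id}: cigar consumes {qlen} query bases but query "
                f"is {len(self.query)} bp")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if _CONSUMES_REF[op])


@dataclass
class PileupColumn:
    """Observation counts at one reference position."""
    position: int
    ref_base: str
    base_counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys("ACGTN", 0))
    del_count: int = 0
    insertions: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.del_count


class Pileup:
    """Sparse per-position pileup over a reference genome."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.columns: dict[int, PileupColumn] = {}

    def column(self, position: int) -> PileupColumn:
        position %= len(self.genome)
        col = self.columns.get(position)
        if col is None:
            col = PileupColumn(position=position,
                               ref_base=self.genome.sequence[position])
            self.columns[position] = col
        return col

    def get(self, position: int) -> PileupColumn | None:
        return self.columns.get(position % len(self.genome))

    def __iter__(self):
        return iter(sorted(self.columns.values(), key=lambda c: c.position))

    def __len__(self) -> int:
        return len(self.columns)

    def total_mass(self) -> int:
        """Sum of base + deletion observations (mass-conservation checks)."""
        return sum(c.depth for c in self.columns.values())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tref\tA\tC\tG\tT\tN\tdel\tdepth\tinsertions\n")
            for c in self:
                ins = ",".join(f"{s}:{n}" for s, n in sorted(c.insertions.items()))
                fh.write(f"{c.position}\t{c.ref_base}\t"
                         + "\t".join(str(c.base_counts[b]) for b in "ACGTN")
                         + f"\t{c.del_count}\t{c.depth}\t{ins}\n")


def _parse_edlib_cigar(cigar: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for n, op in _CIGAR_RE.findall(cigar):
        op = "M" if op in "=X" else op
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + int(n))
        else:
            out.append((op, int(n)))
    return out


def _alignment_columns(cigar: str) -> int:
    return sum(int(n) for n, _ in _CIGAR_RE.findall(cigar))


class MappingStats:
    def __init__(self) -> None:
        self.mapped = 0
        self.unmapped = 0
        self.ambiguous = 0
        self.low_identity = 0


def map_reads(
    reads: Iterable,
    genome: ReferenceGenome,
    k: int = 15,
    band: int = 16,
    min_identity: float = 0.90,
    stats: MappingStats | None = None,
) -> list[AlignedRead]:
    """Map reads (objects with ``read_id``/``sequence``, or Biopython
    SeqRecords) to a circular reference.

    Seeds are exact k-mers looked up in an index of the doubled reference;
    candidate start diagonals are voted on, the best few are extended with
    edlib (unit-cost banded alignment in an infix window padded by ``band``),
    and the single best-scoring location wins. Ties between distinct loci,
    or identity < ``min_identity``, discard the read.
    """
    stats = stats if stats is not None else MappingStats()
    n = len(genome)
    doubled = genome.sequence * 2 if genome.circular else genome.sequence
    index: dict[str, list[int]] = defaultdict(list)
    limit = n if genome.circular else max(0, len(doubled) - k + 1)
    for i in range(limit):
        index[doubled[i:i + k]].append(i)

    out: list[AlignedRead] = []
    for read in reads:
        read_id, seq = _read_fields(read)
        best = None          # (distance, ref_start, strand, cigar, columns)
        best_tie = False
        for strand in "+-":
            q = seq if strand == "+" else revcomp(seq)
            votes: Counter[int] = Counter()
            stride = max(1, k // 2)
            for off in range(0, max(1, len(q) - k + 1), stride):
                for pos in index.get(q[off:off + k], ()):
                    votes[(pos - off) % n] += 1
            if not votes:
                continue
            top = votes.most_common(4)
            seen_starts: set[int] = set()
            for diag, _count in top:
                ws = diag - band
                wrap_ws = ws % n if genome.circular else max(0, ws)
                window = _window(doubled, n, wrap_ws, len(q) + 2 * band,
                                 genome.circular)
                res = edlib.align(q, window, mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                ref_start = (wrap_ws + loc[0]) % n if genome.circular \
                    else wrap_ws + loc[0]
                if ref_start in seen_starts:
                    continue
                seen_starts.add(ref_start)
                cols = _alignment_columns(res["cigar"])
                cand = (res["editDistance"], ref_start, strand,
                        res["cigar"], cols)
                if best is None or cand[0] < best[0]:
                    best = cand
                    best_tie = False
                elif cand[0] == best[0] and (cand[1], cand[2]) != (best[1], best[2]):
                    best_tie = True
        if best is None:
            stats.unmapped += 1
            continue
        if best_tie:
            stats.ambiguous += 1
            continue
        distance, ref_start, strand, cigar, cols = best
        identity = (cols - distance) / cols if cols else 0.0
        if identity < min_identity:
            stats.low_identity += 1
            continue
        q = seq if strand == "+" else revcomp(seq)
        out.append(AlignedRead(
            read_id=read_id, ref_start=ref_start, strand=strand,
            cigar=_parse_edlib_cigar(cigar), query=q,
            identity=identity, edit_distance=distance))
        stats.mapped += 1
    return out


def _window(doubled: str, n: int, start: int, length: int, circular: bool) -> str:
    if not circular:
        return doubled[start:start + length]
    end = start + length
    if end <= len(doubled):
        return doubled[start:end]
    # extremely short genome relative to read: tile as needed
    reps = doubled
    while len(reps) < end:
        reps += doubled[:n]
    return reps[start:end]


def _read_fields(read) -> tuple[str, str]:
    if hasattr(read, "sequence"):
        return read.read_id, read.sequence
    if hasattr(read, "seq"):  # Biopython SeqRecord
        return read.id, str(read.seq).upper()
    raise DataError(f"cannot interpret read object {read!r}")


def build_pileup(alignments: Iterable[AlignedRead],
                 genome: ReferenceGenome) -> Pileup:
    """Accumulate alignments into per-position columns.

    M ops contribute base counts, D ops deletion counts; an I op records the
    inserted sequence at the column preceding the insertion point. Columns
    never touched by a read are simply absent (depth 0 omitted).
    """
    pile = Pileup(genome)
    n = len(genome)
    for aln in alignments:
        qpos = 0
        rpos = aln.ref_start
        for op, ln in aln.cigar:
            if op in ("M", "=", "X"):
                for i in range(ln):
                    base = aln.query[qpos + i]
                    col = pile.column(rpos + i)
                    col.base_counts[base] = col.base_counts.get(base, 0) + 1
                qpos += ln
                rpos += ln
            elif op == "D":
                for i in range(ln):
                    pile.column(rpos + i).del_count += 1
                rpos += ln
            elif op == "I":
                ins = aln.query[qpos:qpos + ln]
                col = pile.column(rpos - 1)
                col.insertions[ins] = col.insertions.get(ins, 0) + 1
                qpos += ln
            elif op == "S":
                qpos += ln
            else:
                raise DataError(f"{aln.read_id}: unsupported cigar op {op!r}")
    return pile


def consensus_from_pileup(pileup: Pileup, genome: ReferenceGenome,
                          min_depth: int = 5) -> ReferenceGenome:
    """Majority-rule consensus: per column the most frequent base, ties
    broken in favor of the reference; columns below ``min_depth`` keep the
    reference base; a deletion wins only when it outnumbers every base."""
    low_depth: list[int] = []
    chars: list[str] = []
    for pos in range(len(genome)):
        ref_base = genome.sequence[pos]
        col = pileup.get(pos)
        if col is None or col.depth < min_depth:
            low_depth.append(pos)
            chars.append(ref_base)
            continue
        best_base, best_count = ref_base, col.base_counts.get(ref_base, 0)
        for base in "ACGT":
            if col.base_counts.get(base, 0) > best_count:
                best_base, best_count = base, col.base_counts[base]
        if col.del_count > max(col.base_counts.values()):
            continue  # deletion beats all bases: drop the position
        chars.append(best_base)
    return ReferenceGenome(id=f"{genome.id}_consensus", sequence="".join(chars),
                           circular=genome.circular)


# ---------------------------------------------------------------------------
# SAM I/O (plain text SAM; alignments produced elsewhere can enter here)
# ---------------------------------------------------------------------------

def write_sam(alignments: Sequence[AlignedRead], genome: ReferenceGenome,
              path: str | Path) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": genome.id, "LN": len(genome)}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for aln in alignments:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = aln.read_id
            a.query_sequence = aln.query
            a.reference_id = 0
            a.reference_start = aln.ref_start
            a.mapping_quality = 60
            a.cigartuples = [(_SAM_OP[op], ln) for op, ln in aln.cigar]
            a.flag = 0 if aln.strand == "+" else 16
            a.set_tag("NM", aln.edit_distance)
            fh.write(a)


_SAM_OP = {"M": 0, "I": 1, "D": 2, "S": 4, "=": 7, "X": 8}
_SAM_OP_REV = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}


def ingest_sam(path: str | Path, genome: ReferenceGenome) -> list[AlignedRead]:
    """Read externally produced alignments from a plain SAM file.

    Only M/I/D/S/=/X operations are supported; hard clips are rejected.
    Unmapped records are skipped.
    """
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            cigar: list[tuple[str, int]] = []
            for op, ln in rec.cigartuples:
                if op == 5:
                    raise DataError(f"{rec.query_name}: hard clips unsupported")
                if op not in _SAM_OP_REV:
                    raise DataError(f"{rec.query_name}: unsupported cigar op {op}")
                sym = _SAM_OP_REV[op]
                if cigar and cigar[-1][0] == sym:
                    cigar[-1] = (sym, cigar[-1][1] + ln)
                else:
                    cigar.append((sym, ln))
            query = rec.query_sequence or ""
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            cols = sum(ln for op, ln in cigar if op != "S")
            identity = (cols - nm) / cols if cols else 0.0
            out.append(AlignedRead(
                read_id=rec.query_name, ref_start=rec.reference_start,
                strand="-" if rec.is_reverse else "+", cigar=cigar,
                query=query.upper(), identity=identity, edit_distance=int(nm)))
    return out
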