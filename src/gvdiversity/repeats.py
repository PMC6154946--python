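"""Tandem direct repeats (drs) and large inter-genome indels.

In granulovirus field isolates, large indels (roughly 12-88 bp) concentrate
in tandem direct-repeat arrays, where unit copy-number variation between
isolates changes the array length by whole units. This module detects
perfect tandem arrays on a reference, counts tandem motif copies in protein
or nucleotide sequences, and localizes large indels between two
near-identical genomes relative to the repeat annotation.

Detection is restricted to perfect repeats: copy-number gains/losses of
whole units are exactly what perfect arrays capture, and degenerate repeats
are a documented limitation. The default minimum unit of 6 bp excludes
homopolymers, which belong to the sequencing-error correction stage instead.
Indels are left-aligned (VCF convention) so coordinates inside repeat
arrays are reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .errors import DataError
from .genome_model import ReferenceGenome


@dataclass(frozen=True)
class DirectRepeat:
    """A maximal perfect tandem array: ``unit_seq`` repeated ``copy_number``
    times (fractional final copies allowed) spanning [start, end). The unit
    is reported as the lexicographically minimal rotation of itself."""
    dr_id: str
    start: int
    end: int
    unit_length: int
    unit_seq: str
    copy_number: float


@dataclass(frozen=True)
class IndelEvent:
    """A large indel between two genomes, on the first genome's coordinates.

    ``kind`` 'deletion' means sequence present in genome A and absent in B;
    'insertion' the converse. ``in_dr`` names the direct repeat of genome A
    the event intersects, if any."""
    ref_start: int
    length: int
    kind: str
    sequence: str
    in_dr: str | None = None


def _minimal_rotation(s: str) -> str:
    return min(s[i:] + s[:i] for i in range(len(s)))


def find_direct_repeats(
    genome: ReferenceGenome | str,
    min_unit: int = 6,
    max_unit: int = 64,
    min_copies: float = 2.0,
    min_span: int = 18,
) -> list[DirectRepeat]:
    """Maximal perfect tandem arrays satisfying the thresholds.

    For each unit length u, positions where ``s[i] == s[i+u]`` are scanned;
    a maximal stretch of m such matches starting at i is a tandem span of
    m + u bp with (m + u)/u copies. Overlapping reports (e.g. the same
    array found at a multiple of its true period) are merged to the longest
    span; surviving intervals never overlap. Deterministic order by start.
    """
    s = genome.sequence if isinstance(genome, ReferenceGenome) else genome
    circular = isinstance(genome, ReferenceGenome) and genome.circular
    n = len(s)
    scan = s + s[: min(n, max_unit * 8)] if circular else s
    candidates: list[tuple[int, int, int]] = []  # (start, end, unit_len)
    for u in range(min_unit, min(max_unit, len(scan) // 2) + 1):
        i = 0
        m = len(scan) - u
        while i < m:
            if scan[i] != scan[i + u]:
                i += 1
                continue
            j = i
            while j < m and scan[j] == scan[j + u]:
                j += 1
            span = (j - i) + u
            if span >= min_span and span / u >= min_copies:
                unit = scan[i:i + u]
                # skip non-primitive units; the primitive period reports it
                if (unit + unit).find(unit, 1) == u:
                    candidates.append((i, i + span, u))
            i = j + 1
    # drop duplicates arising from the circular extension; keep start < n
    dedup = set()
    for a, b, u in candidates:
        if a >= n:
            continue
        dedup.add((a, min(b, a + n), u))
    cands = sorted(dedup, key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
    kept: list[tuple[int, int, int]] = []
    for a, b, u in cands:
        if any(_intervals_overlap(a, b, ka, kb, n) for ka, kb, _ in kept):
            continue
        kept.append((a, b, u))
    kept.sort()
    out = []
    for idx, (a, b, u) in enumerate(kept, start=1):
        unit = scan[a:a + u] if a + u <= len(scan) else (s + s)[a:a + u]
        out.append(DirectRepeat(
            dr_id=f"dr{idx:02d}", start=a, end=b, unit_length=u,
            unit_seq=_minimal_rotation(unit), copy_number=(b - a) / u))
    return out


def _intervals_overlap(a1: int, b1: int, a2: int, b2: int, n: int) -> bool:
    def spans(a, b):
        if b <= n:
            return [(a, b)]
        return [(a, n), (0, b - n)]
    for x1, y1 in spans(a1, b1):
        for x2, y2 in spans(a2, b2):
            if x1 < y2 and x2 < y1:
                return True
    return False


def count_motif_copies(sequence: str, motif: str) -> int:
    """Length of the longest run of exact, adjacent (non-overlapping)
    copies of ``motif``; 0 when absent."""
    if not motif:
        raise DataError("motif must be non-empty")
    m = len(motif)
    best = 0
    i = 0
    n = len(sequence)
    while i < n:
        if sequence.startswith(motif, i):
            count = 1
            j = i + m
            while sequence.startswith(motif, j):
                count += 1
                j += m
            best = max(best, count)
            i += 1
        else:
            i += 1
    return best


def repeats_to_bed(drs: Sequence[DirectRepeat], chrom: str, path) -> None:
    """BED with name=dr_id and score=copy_number x 10."""
    with open(path, "w") as fh:
        for d in drs:
            fh.write(f"{chrom}\t{d.start}\t{d.end}\t{d.dr_id}\t"
                     f"{int(round(d.copy_number * 10))}\t+\n")


# ---------------------------------------------------------------------------
# inter-genome indel localization
# ---------------------------------------------------------------------------

def _unique_kmers(s: str, k: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for i in range(len(s) - k + 1):
        counts[s[i:i + k]] += 1
    pos = {}
    for i in range(len(s) - k + 1):
        kmer = s[i:i + k]
        if counts[kmer] == 1:
            pos[kmer] = i
    return pos


def _chain_anchors(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest colinear chain (strictly increasing in both coordinates),
    classic patience algorithm on the second coordinate."""
    import bisect
    anchors.sort()
    tails: list[int] = []
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for i, (_a, b) in enumerate(anchors):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(anchors[i])
        i = parent[i]
    return chain[::-1]


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -2
_aligner.open_gap_score = -4
_aligner.extend_gap_score = -0.5


def locate_indels(
    genome_a: ReferenceGenome | str,
    genome_b: ReferenceGenome | str,
    drs_a: Sequence[DirectRepeat] = (),
    min_report: int = 10,
    k: int = 21,
) -> list[IndelEvent]:
    """Indels of length >= ``min_report`` between two near-identical genomes.

    Shared unique k-mers are chained colinearly; the sequence between
    consecutive anchors is aligned globally with affine gap penalties, and
    gaps are emitted as indel events, left-aligned, with coordinates on
    genome A. Each event is annotated with the genome-A direct repeat it
    intersects, if any. Raises when anchors cover less than half of either
    genome (the inputs are then not near-identical).
    """
    a = genome_a.sequence if isinstance(genome_a, ReferenceGenome) else genome_a
    b = genome_b.sequence if isinstance(genome_b, ReferenceGenome) else genome_b
    ka = _unique_kmers(a, k)
    kb = _unique_kmers(b, k)
    anchors = [(pa, kb[kmer]) for kmer, pa in ka.items() if kmer in kb]
    if not anchors:
        raise DataError("no shared unique anchors; genomes too divergent")
    chain = _chain_anchors(anchors)
    # consecutive anchors must not overlap: junction k-mers reaching into a
    # repeat array can sit < k apart on shifted diagonals, which would make
    # the inter-anchor slice collapse and swallow the length difference
    spaced: list[tuple[int, int]] = []
    for pa, pb in chain:
        if not spaced or (pa >= spaced[-1][0] + k and pb >= spaced[-1][1] + k):
            spaced.append((pa, pb))
    chain = spaced
    cov_a = _anchor_coverage(chain, k, 0)
    cov_b = _anchor_coverage(chain, k, 1)
    if cov_a < 0.5 * len(a) or cov_b < 0.5 * len(b):
        raise DataError(
            f"anchors cover only {cov_a}/{len(a)} and {cov_b}/{len(b)} bp; "
            "inputs are not near-identical")
    events: list[IndelEvent] = []
    for (pa1, pb1), (pa2, pb2) in zip(chain, chain[1:]):
        ga = a[pa1 + k: pa2]
        gb = b[pb1 + k: pb2]
        if ga == gb:
            continue
        events.extend(_gap_indels(ga, gb, pa1 + k, a))
    events = [e for e in events if e.length >= min_report]
    events = [_annotate_dr(_left_align(e, a), drs_a) for e in events]
    return sorted(events, key=lambda e: (e.ref_start, e.kind))


def _anchor_coverage(chain: list[tuple[int, int]], k: int, which: int) -> int:
    covered = 0
    prev_end = -1
    for anchor in chain:
        p = anchor[which]
        start = max(p, prev_end)
        end = p + k
        if end > start:
            covered += end - start
        prev_end = max(prev_end, end)
    return covered


def _gap_indels(ga: str, gb: str, offset_a: int, a: str) -> list[IndelEvent]:
    if not ga and gb:
        return [IndelEvent(ref_start=offset_a, length=len(gb),
                           kind="insertion", sequence=gb)]
    if ga and not gb:
        return [IndelEvent(ref_start=offset_a, length=len(ga),
                           kind="deletion", sequence=ga)]
    alignment = _aligner.align(ga, gb)[0]
    events: list[IndelEvent] = []
    blocks_a, blocks_b = alignment.aligned
    prev_a = prev_b = 0
    for (sa, ea), (sb, eb) in zip(blocks_a.tolist(), blocks_b.tolist()):
        if sa > prev_a:  # gap in b: deletion from a
            events.append(IndelEvent(ref_start=offset_a + prev_a,
                                     length=sa - prev_a, kind="deletion",
                                     sequence=ga[prev_a:sa]))
        if sb > prev_b:  # gap in a: insertion from b
            events.append(IndelEvent(ref_start=offset_a + sa,
                                     length=sb - prev_b, kind="insertion",
                                     sequence=gb[prev_b:sb]))
        prev_a, prev_b = ea, eb
    if len(ga) > prev_a:
        events.append(IndelEvent(ref_start=offset_a + prev_a,
                                 length=len(ga) - prev_a, kind="deletion",
                                 sequence=ga[prev_a:]))
    if len(gb) > prev_b:
        events.append(IndelEvent(ref_start=offset_a + len(ga),
                                 length=len(gb) - prev_b, kind="insertion",
                                 sequence=gb[prev_b:]))
    return events


def _left_align(event: IndelEvent, a: str) -> IndelEvent:
    p = event.ref_start
    seq = event.sequence
    if event.kind == "deletion":
        while p > 0 and a[p - 1] == a[p + len(seq) - 1]:
            p -= 1
        seq = a[p:p + len(seq)]
    else:
        while p > 0 and seq[-1] == a[p - 1]:
            seq = a[p - 1] + seq[:-1]
            p -= 1
    return IndelEvent(ref_start=p, length=event.length, kind=event.kind,
                      sequence=seq, in_dr=event.in_dr)


def _annotate_dr(event: IndelEvent, drs: Sequence[DirectRepeat]) -> IndelEvent:
    span_end = event.ref_start + (event.length if event.kind == "deletion" else 1)
    for d in drs:
        if event.ref_start < d.end and d.start < span_end:
            return IndelEvent(ref_start=event.ref_start, length=event.length,
                              kind=event.kind, sequence=event.sequence,
                              in_dr=d.dr_id)
    return IndelEvent(ref_start=event.ref_start, length=event.length,
                      kind=event.kind, sequence=event.sequence, in_dr=None)


def indels_to_tsv(events: Sequence[IndelEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_start\tlength\tkind\tin_dr\tsequence\n")
        for e in events:
            fh.write(f"{e.ref_start}\t{e.length}\t{e.kind}\t"
                     f"{e.in_dr or '.'}\t{e.sequence}\n")
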