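"""Shared fixtures: toy genomes and independent brute-force oracles."""

from __future__ import annotations

import re

import pytest

from gvdiversity.genome_model import revcomp
from gvdiversity.synth import SimulationConfig, generate_toy_genome


@pytest.fixture(scope="session")
def toy():
    """Default toy genome (10 kb, 8 ORFs incl. one overlapping pair, four
    direct repeats, planted homopolymer runs)."""
    return generate_toy_genome(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_config():
    """A smaller, faster simulation for read-level tests."""
    return SimulationConfig(seed=13, genome_length=4000, n_orfs=4,
                            orf_len_range=(150, 300), depth=30.0,
                            dr_specs=(), homopolymer_runs=(("A", 5),),
                            hp_indel_rate=0.0, sub_error_rate=0.0)


@pytest.fixture(scope="session")
def small_toy(small_config):
    return generate_toy_genome(small_config)


_ORF_RE = re.compile(r"(?=(ATG(?:[ACGT]{3})*?(?:TAA|TAG|TGA)))")


def brute_orf_scan(sequence: str, circular: bool, min_len: int):
    """Regex-based six-frame ORF oracle, independent of the codon-walk
    implementation: lazy ATG...stop matches give first-stop ORFs, then
    non-maximal ones (an ORF sharing its stop with a longer one) are
    discarded."""
    n = len(sequence)
    found = set()
    scan = sequence * 2 if circular else sequence
    for strand in "+-":
        s = scan if strand == "+" else revcomp(scan)
        for m in _ORF_RE.finditer(s):
            a = m.start(1)
            b = a + len(m.group(1))
            length = b - a
            if length < min_len or length > n:
                continue
            start = a if strand == "+" else len(s) - b
            if circular:
                start %= n
            found.add((start, start + length, strand))
    # maximality: drop ORFs whose stop is shared with a longer ORF
    maximal = set()
    for start, end, strand in found:
        length = end - start
        stop_key = (end % n if circular else end) if strand == "+" else \
                   (start % n if circular else start)
        longer = [o for o in found if o[2] == strand and o != (start, end, strand)
                  and ((strand == "+" and (o[1] % n if circular else o[1]) == stop_key)
                       or (strand == "-" and (o[0] % n if circular else o[0]) == stop_key))
                  and o[1] - o[0] > length]
        if not longer:
            maximal.add((start, end, strand))
    return maximal


def brute_tandem_arrays(s: str, min_unit: int, max_unit: int,
                        min_copies: float, min_span: int):
    """Quadratic tandem-array oracle: for every (start, unit) directly count
    how far the periodicity extends."""
    n = len(s)
    arrays = set()
    for u in range(min_unit, max_unit + 1):
        for i in range(n - 2 * u + 1):
            if s[i - 1] == s[i + u - 1] if i > 0 else False:
                continue  # not maximal on the left
            j = i + u
            while j < n and s[j] == s[j - u]:
                j += 1
            span = j - i
            if span >= min_span and span / u >= min_copies:
                arrays.add((i, j))
    return arrays
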