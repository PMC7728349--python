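"""Shared oracles and random-instance helpers for the test suite.

The interval-algebra tests validate the sweep implementations against
two independent oracles:

* a per-base boolean bitmap on a toy genome (coverage semantics), and
* a quadratic all-pairs comparison (overlap-count semantics).

Both are deliberately naive so they cannot share bugs with the
implementations under test.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from cobindkit.intervals import GenomicInterval, IntervalSet, normalize

Triple = Tuple[str, int, int]


def bitmap_of(intervals: Sequence[Triple], genome: Dict[str, int]) -> Dict[str, np.ndarray]:
    """Per-base boolean coverage arrays, one per chromosome."""
    maps = {c: np.zeros(length, dtype=bool) for c, length in genome.items()}
    for chrom, start, end in intervals:
        maps[chrom][start:end] = True
    return maps


def intervals_from_bitmap(maps: Dict[str, np.ndarray]) -> List[Triple]:
    """Maximal runs of True, per chromosome — the normalized covered set."""
    out: List[Triple] = []
    for chrom in sorted(maps):
        bits = maps[chrom]
        padded = np.concatenate(([False], bits, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append((chrom, int(s), int(e)))
    return out


def as_triples(s: IntervalSet) -> List[Triple]:
    return [(iv.chrom, iv.start, iv.end) for iv in s]


def allpairs_counts(query: Sequence[Triple], subject: Sequence[Triple]) -> List[int]:
    """Brute-force overlap counts under half-open semantics."""
    counts = []
    for qc, qs, qe in query:
        counts.append(
            sum(1 for sc, ss, se in subject if sc == qc and ss < qe and se > qs)
        )
    return counts


def random_triples(
    rng: np.random.Generator,
    genome: Dict[str, int],
    n_max: int = 40,
    w_max: int = 400,
) -> List[Triple]:
    """Random (possibly overlapping) intervals on a toy genome."""
    chroms = sorted(genome)
    n = int(rng.integers(0, n_max + 1))
    out: List[Triple] = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        w = int(rng.integers(1, w_max + 1))
        start = int(rng.integers(0, max(1, genome[chrom] - w)))
        out.append((chrom, start, start + w))
    return out


@pytest.fixture
def toy_genome() -> Dict[str, int]:
    return {"chr1": 10_000, "chr2": 6_000}
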