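"""Replicate consensus peaks, CTCF overlap percentages and chromatin states.

The co-occupancy analysis proceeds in three stages:

1. **Consensus** — for every factor with replicated ChIP-seq tracks, the
   consensus peaks are the genomic regions common to all replicates
   (iterated interval intersection); with a single replicate the peaks
   are used as-is. Regions narrower than 5 bp are removed from every
   consensus list.
2. **Overlap percentage** — the fraction of a factor's consensus peaks
   that overlap any CTCF consensus peak, each peak counted once
   regardless of how many CTCF peaks it touches.
3. **Chromatin states** — five region classes are derived from histone
   modification consensus peaks (active promoter H3K4me3; active
   enhancer H3K27ac ∩ H3K4me1; gene body H3K36me3 ∩ H3K79me2; inactive
   enhancer H3K9me3; inactive promoter H3K27me3), and the CTCF-overlapping
   peaks of a factor are scored against each state independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .intervals import (
    IntervalSet,
    count_overlaps,
    filter_min_width,
    intersect,
    overlapping_subset,
)

__all__ = [
    "DEFAULT_MIN_WIDTH",
    "CHROMATIN_STATES",
    "REQUIRED_MARKS",
    "FactorPeaks",
    "OverlapReport",
    "ChromatinStateMap",
    "UndefinedPercentageError",
    "MissingMarkError",
    "build_consensus",
    "percent_overlap",
    "define_chromatin_states",
    "state_cooccupancy",
]

#: Consensus regions narrower than this many bases are discarded.
DEFAULT_MIN_WIDTH = 5

#: The five chromatin states and the histone marks that define them.
#: Single-mark states use the mark's consensus peaks directly; two-mark
#: states use the common genomic regions of the pair.
CHROMATIN_STATES: Dict[str, Sequence[str]] = {
    "active_promoter": ("H3K4me3",),
    "active_enhancer": ("H3K27ac", "H3K4me1"),
    "gene_body": ("H3K36me3", "H3K79me2"),
    "inactive_enhancer": ("H3K9me3",),
    "inactive_promoter": ("H3K27me3",),
}

REQUIRED_MARKS = tuple(
    sorted({m for marks in CHROMATIN_STATES.values() for m in marks})
)


class UndefinedPercentageError(ValueError):
    """An overlap percentage was requested for an empty peak set."""


class MissingMarkError(KeyError):
    """A required histone mark is absent from the marks mapping."""


@dataclass
class FactorPeaks:
    """A ChIP-seq factor with its replicate peak sets and derived consensus."""

    name: str
    replicates: List[IntervalSet]
    consensus: IntervalSet = field(init=False)
    min_width: int = DEFAULT_MIN_WIDTH

    def __post_init__(self) -> None:
        self.consensus = build_consensus(self.replicates, self.min_width)


@dataclass(frozen=True)
class OverlapReport:
    """Overlap of one factor's consensus peaks with CTCF consensus peaks."""

    factor: str
    n_consensus: int
    n_overlapping_ctcf: int
    percent: float  # full precision; round only when printing

    @property
    def percent_rounded(self) -> int:
        return int(round(self.percent))


# a ChromatinStateMap is a plain dict state-name -> IntervalSet
ChromatinStateMap = Dict[str, IntervalSet]


def build_consensus(
    replicates: Sequence[IntervalSet], min_width: int = DEFAULT_MIN_WIDTH
) -> IntervalSet:
    """Regions common to all replicates, width-filtered.

    A single replicate yields its own (width-filtered) peaks. The fold of
    pairwise intersections is order-invariant and monotone: adding a
    replicate can only shrink the covered-base set.

    Raises
    ------
    ValueError
        If no replicates are given.
    """
    if len(replicates) == 0:
        raise ValueError("build_consensus requires at least one replicate")
    acc = replicates[0]
    if not acc.normalized:
        raise ValueError("replicates must be normalized IntervalSets")
    for rep in replicates[1:]:
        acc = intersect(acc, rep)
    return filter_min_width(acc, min_width)


def percent_overlap(
    factor: IntervalSet, ctcf: IntervalSet, name: str = "factor"
) -> OverlapReport:
    """Percentage of factor consensus peaks overlapping any CTCF peak.

    The denominator is the number of the factor's consensus peaks; a
    peak overlapping several CTCF peaks counts once.
    """
    n = len(factor)
    if n == 0:
        raise UndefinedPercentageError(
            f"percent_overlap undefined for empty peak set {name!r}"
        )
    k = len(overlapping_subset(factor, ctcf))
    return OverlapReport(
        factor=name, n_consensus=n, n_overlapping_ctcf=k, percent=100.0 * k / n
    )


def define_chromatin_states(marks: Mapping[str, IntervalSet]) -> ChromatinStateMap:
    """Derive the five chromatin states from histone-mark consensus peaks.

    Raises
    ------
    MissingMarkError
        Naming the first required mark absent from ``marks``.
    """
    for mark in REQUIRED_MARKS:
        if mark not in marks:
            raise MissingMarkError(
                f"chromatin-state definition requires mark {mark!r}"
            )
    states: ChromatinStateMap = {}
    for state, state_marks in CHROMATIN_STATES.items():
        acc = marks[state_marks[0]]
        for mark in state_marks[1:]:
            acc = intersect(acc, marks[mark])
        states[state] = acc
    return states


def state_cooccupancy(
    factor_ctcf_peaks: IntervalSet, states: ChromatinStateMap
) -> Dict[str, float]:
    """Per-state percentage of CTCF-overlapping factor peaks in that state.

    ``factor_ctcf_peaks`` is the unique subset of a factor's consensus
    peaks that overlap CTCF. Each state is evaluated independently (a
    peak can sit in several states), so percentages need not sum to 100.
    """
    n = len(factor_ctcf_peaks)
    if n == 0:
        raise UndefinedPercentageError(
            "state co-occupancy undefined for an empty peak set"
        )
    out: Dict[str, float] = {}
    for state, regions in states.items():
        counts = count_overlaps(factor_ctcf_peaks, regions)
        out[state] = 100.0 * int(np.count_nonzero(counts)) / n
    return out
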