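"""Synthetic data with ground truth for every analysis stage.

Three generator families provide inputs whose true parameters are known,
so each pipeline can be tested as a recovery problem:

* **Peaks** — non-overlapping ChIP-seq-like peak sets on a toy genome,
  replicate copies with boundary jitter and dropout, and cofactor peak
  sets built to overlap a controlled fraction *f* of a base set
  (ground truth for overlap percentages).
* **PSMs** — target/decoy score tables drawn from a two-component
  mixture: decoys and incorrect targets share a Gaussian null, correct
  targets are shifted upward by the effect size (in null-sd units).
  Per-target truth labels allow empirical false-discovery proportions
  to be measured against nominal q-value cutoffs.
* **BLI** — 1:1 Langmuir association/dissociation interferograms with
  concentration-proportional blank background and Gaussian noise
  (ground truth for equilibrium K_D recovery).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .bli import Interferogram
from .intervals import IntervalSet, normalize

__all__ = [
    "PeakSimConfig",
    "PsmSimConfig",
    "BliSimConfig",
    "InfeasiblePlacementError",
    "simulate_peakset",
    "simulate_replicates",
    "simulate_cofactor",
    "simulate_psms",
    "simulate_bli",
]


class InfeasiblePlacementError(RuntimeError):
    """Peak placement failed repeatedly; the genome is too crowded."""


@dataclass
class PeakSimConfig:
    """Peak-set generator settings.

    Defaults emulate transcription-factor ChIP-seq peak lists: ~150-500 bp
    peaks placed uniformly on a 100 Mb toy chromosome, replicate boundary
    jitter of 10 bp and 5% replicate dropout.
    """

    genome: Dict[str, int] = field(default_factory=lambda: {"chr1": 100_000_000})
    n_peaks: int = 10_000
    width_min: int = 150
    width_max: int = 500
    jitter_sd: float = 10.0
    dropout: float = 0.05
    overlap_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must lie in [0, 1]")
        if self.width_min < 1 or self.width_max < self.width_min:
            raise ValueError("need 1 <= width_min <= width_max")
        mean_w = 0.5 * (self.width_min + self.width_max)
        if self.n_peaks * mean_w > 0.5 * sum(self.genome.values()):
            raise InfeasiblePlacementError(
                "n_peaks x mean width exceeds half the genome; placement infeasible"
            )


@dataclass
class PsmSimConfig:
    """Target/decoy score-mixture settings.

    ``pi0`` is the fraction of *incorrect* target PSMs, drawn from the
    same N(0, 1) null as the decoys; correct targets are drawn from
    N(shift, 1), so ``shift`` is the effect size in null-sd units. A
    light-tailed null is used deliberately: it gives the strict-FDR
    regime a stable operating point, whereas an exponential-tailed null
    puts a floor of about (n_decoys / n_correct) * exp(-shift) under
    the estimated FDR curve, below which acceptance collapses onto the
    few scores above the top decoy. ``noise_sd`` adds extra Gaussian
    score noise (0 by default; the null spread is the score noise).
    """

    n_targets: int = 5000
    n_decoys: int = 5000
    pi0: float = 0.3
    shift: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must lie in [0, 1]")
        if self.n_targets <= 0 or self.n_decoys < 0:
            raise ValueError("counts must be positive")


@dataclass
class BliSimConfig:
    """1:1 binding interferogram settings.

    Defaults reproduce a micromolar-affinity equilibrium series: true
    K_D 2.3 uM probed at 0.5-3.0 uM with a saturation response of 1 nm,
    5% noise, a 30 s baseline, 120 s association (so the 150 s plateau
    read falls at end of association) and 120 s dissociation. The
    nanomolar series (K_D 95 nM at 10-200 nM) is obtained by overriding
    ``kd`` and ``concentrations``.
    """

    kd: float = 2.3e-6  # molar
    bmax: float = 1.0  # nm
    k_obs: float = 0.08  # 1/s; fast enough to plateau within 120 s
    concentrations: Tuple[float, ...] = (0.5e-6, 1.0e-6, 1.5e-6, 2.0e-6, 2.5e-6, 3.0e-6)
    baseline_s: float = 30.0
    association_s: float = 120.0
    dissociation_s: float = 120.0
    noise_sd: float = 0.05  # nm; 5% of the default bmax
    blank_slope: float = 0.0  # nm per molar of analyte
    seed: int = 0
    analyte: str = "analyte"

    def __post_init__(self) -> None:
        if min(self.kd, self.bmax, self.k_obs) <= 0:
            raise ValueError("kd, bmax and k_obs must be positive")


# ---------------------------------------------------------------------------
# peak generators
# ---------------------------------------------------------------------------


class _Occupancy:
    """Sorted per-chromosome bookkeeping for disjoint placement.

    A candidate is accepted only if, padded by one base on each side, it
    misses every accepted interval — so the final sets are disjoint and
    never book-ended (normalization cannot merge peaks away).
    """

    def __init__(self) -> None:
        self._starts: Dict[str, List[int]] = {}
        self._ends: Dict[str, List[int]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return True
        ends = self._ends[chrom]
        i = bisect_left(starts, end + 1)  # candidates with start <= end
        if i > 0 and ends[i - 1] + 1 > start:
            return False
        if i < len(starts) and starts[i] < end + 1:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


def _chrom_choice(
    rng: np.random.Generator, genome: Dict[str, int], n: int
) -> np.ndarray:
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    return rng.choice(len(chroms), size=n, p=lengths / lengths.sum())


def simulate_peakset(cfg: PeakSimConfig) -> IntervalSet:
    """Place ``n_peaks`` mutually disjoint peaks uniformly on the toy genome."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_peaks == 0:
        return normalize([])
    chroms = sorted(cfg.genome)
    occ = _Occupancy()
    placed = []
    attempts = 0
    max_attempts = 200 * cfg.n_peaks + 1000
    while len(placed) < cfg.n_peaks:
        if attempts >= max_attempts:
            raise InfeasiblePlacementError(
                f"placed only {len(placed)}/{cfg.n_peaks} peaks after "
                f"{attempts} attempts"
            )
        attempts += 1
        ci = int(_chrom_choice(rng, cfg.genome, 1)[0])
        chrom = chroms[ci]
        w = int(rng.integers(cfg.width_min, cfg.width_max + 1))
        if cfg.genome[chrom] < w:
            continue
        start = int(rng.integers(0, cfg.genome[chrom] - w + 1))
        if occ.is_free(chrom, start, start + w):
            occ.add(chrom, start, start + w)
            placed.append((chrom, start, start + w))
    return normalize(placed)


def simulate_replicates(
    base: IntervalSet, cfg: PeakSimConfig, n_replicates: int = 2
) -> List[IntervalSet]:
    """Replicate copies of a peak set with boundary jitter and dropout.

    Each replicate jitters every peak boundary by a rounded Gaussian of
    sd ``jitter_sd`` bp (widths clamped to >= 1, starts to >= 0) and
    drops peaks independently with probability ``dropout``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    peaks = base.to_intervals()
    reps: List[IntervalSet] = []
    for _ in range(n_replicates):
        kept = []
        for iv in peaks:
            if rng.random() < cfg.dropout:
                continue
            ds, de = np.round(rng.normal(0.0, cfg.jitter_sd, size=2)).astype(int)
            s = max(0, iv.start + int(ds))
            e = iv.end + int(de)
            if e <= s:
                e = s + 1
            kept.append((iv.chrom, s, e))
        reps.append(normalize(kept))
    return reps


def simulate_cofactor(
    base: IntervalSet, cfg: PeakSimConfig
) -> Tuple[IntervalSet, np.ndarray]:
    """Cofactor peaks overlapping a Bernoulli(``overlap_fraction``) share of
    distinct base peaks.

    Each cofactor peak is labelled overlapping with probability *f*
    (binomial sampling, so the realized fraction varies with binomial
    spread around *f*). Overlapping peaks are placed inside a distinct
    base peak; the remainder are placed disjoint from the base set and
    from each other. Returns the cofactor set and the per-peak truth
    labels (True = planted to overlap).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    base_peaks = base.to_intervals()
    n = cfg.n_peaks
    labels = rng.random(n) < cfg.overlap_fraction
    n_overlap = int(labels.sum())
    if n_overlap > len(base_peaks):
        raise InfeasiblePlacementError(
            f"{n_overlap} overlapping cofactor peaks requested but the base "
            f"set has only {len(base_peaks)} peaks"
        )

    occ = _Occupancy()
    for iv in base_peaks:  # keep non-overlap peaks clear of the base set
        occ.add(iv.chrom, iv.start, iv.end)

    placed: List[Tuple[str, int, int]] = []
    # overlapping peaks: inside distinct, randomly chosen base peaks, so
    # they are disjoint from each other by construction
    anchors = rng.permutation(len(base_peaks))[:n_overlap]
    for j in anchors:
        anchor = base_peaks[int(j)]
        w = min(int(rng.integers(cfg.width_min, cfg.width_max + 1)), anchor.width)
        start = anchor.start + int(rng.integers(0, anchor.width - w + 1))
        placed.append((anchor.chrom, start, start + w))

    chroms = sorted(cfg.genome)
    attempts = 0
    max_attempts = 200 * n + 1000
    n_disjoint = n - n_overlap
    disjoint_placed = 0
    while disjoint_placed < n_disjoint:
        if attempts >= max_attempts:
            raise InfeasiblePlacementError(
                "could not place disjoint cofactor peaks; genome too crowded"
            )
        attempts += 1
        ci = int(_chrom_choice(rng, cfg.genome, 1)[0])
        chrom = chroms[ci]
        w = int(rng.integers(cfg.width_min, cfg.width_max + 1))
        start = int(rng.integers(0, cfg.genome[chrom] - w + 1))
        if occ.is_free(chrom, start, start + w):
            occ.add(chrom, start, start + w)
            placed.append((chrom, start, start + w))
            disjoint_placed += 1
    return normalize(placed), labels


# ---------------------------------------------------------------------------
# PSM generator
# ---------------------------------------------------------------------------


def simulate_psms(cfg: PsmSimConfig) -> pd.DataFrame:
    """Target/decoy PSM table with per-target truth labels.

    Decoy scores and incorrect-target scores are N(0, 1); correct
    targets are N(shift, 1). The returned frame carries the PSM schema
    columns plus ``is_correct`` (False for decoys and incorrect
    targets).
    """
    rng = np.random.default_rng(cfg.seed)
    n_t, n_d = cfg.n_targets, cfg.n_decoys
    correct = rng.random(n_t) >= cfg.pi0
    t_scores = rng.normal(0.0, 1.0, size=n_t)
    t_scores[correct] = rng.normal(cfg.shift, 1.0, size=int(correct.sum()))
    d_scores = rng.normal(0.0, 1.0, size=n_d)
    if cfg.noise_sd > 0:
        t_scores = t_scores + rng.normal(0.0, cfg.noise_sd, size=n_t)
        d_scores = d_scores + rng.normal(0.0, cfg.noise_sd, size=n_d)

    n = n_t + n_d
    frame = pd.DataFrame(
        {
            "spectrum_id": [f"spec{i:07d}" for i in range(n)],
            "peptide": [f"PEPTIDE{i:07d}" for i in range(n)],
            "accession": [f"P{i // 5:06d}" for i in range(n)],
            "score": np.concatenate([t_scores, d_scores]),
            "delta_cn": 0.0,
            "is_decoy": np.concatenate(
                [np.zeros(n_t, dtype=bool), np.ones(n_d, dtype=bool)]
            ),
            "sample": "benzonase",
            "replicate": 1,
            "is_correct": np.concatenate(
                [correct, np.zeros(n_d, dtype=bool)]
            ),
        }
    )
    return frame


# ---------------------------------------------------------------------------
# BLI generator
# ---------------------------------------------------------------------------


def simulate_bli(
    cfg: BliSimConfig,
) -> Tuple[List[Interferogram], List[Interferogram]]:
    """Signal and matched blank interferograms on a 1 s grid.

    The specific component follows the 1:1 Langmuir model: zero during
    the baseline, ``B_eq * (1 - exp(-k_obs * t))`` during association
    with ``B_eq = B_max * c / (K_D + c)``, exponential decay at rate
    ``k_obs`` during dissociation. A concentration-proportional blank
    background (``blank_slope * c`` after the baseline) is added to the
    raw signal and returned separately as the matched blank trace.
    Gaussian noise of sd ``noise_sd`` is added to both.
    """
    rng = np.random.default_rng(cfg.seed)
    t_end = cfg.baseline_s + cfg.association_s + cfg.dissociation_s
    t = np.arange(0.0, t_end + 1.0, 1.0)
    assoc = (t >= cfg.baseline_s) & (t <= cfg.baseline_s + cfg.association_s)
    dissoc = t > cfg.baseline_s + cfg.association_s

    signals: List[Interferogram] = []
    blanks: List[Interferogram] = []
    for c in cfg.concentrations:
        b_eq = cfg.bmax * c / (cfg.kd + c)
        y = np.zeros_like(t)
        y[assoc] = b_eq * (1.0 - np.exp(-cfg.k_obs * (t[assoc] - cfg.baseline_s)))
        t1 = cfg.baseline_s + cfg.association_s
        y_end = b_eq * (1.0 - np.exp(-cfg.k_obs * cfg.association_s))
        y[dissoc] = y_end * np.exp(-cfg.k_obs * (t[dissoc] - t1))

        background = np.where(t >= cfg.baseline_s, cfg.blank_slope * c, 0.0)
        noise_sig = rng.normal(0.0, cfg.noise_sd, size=t.size) if cfg.noise_sd else 0.0
        noise_blk = rng.normal(0.0, cfg.noise_sd, size=t.size) if cfg.noise_sd else 0.0
        signals.append(
            Interferogram(cfg.analyte, c, t.copy(), y + background + noise_sig)
        )
        blanks.append(
            Interferogram(cfg.analyte, c, t.copy(), background + noise_blk)
        )
    return signals, blanks
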