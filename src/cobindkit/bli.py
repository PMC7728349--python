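"""Biolayer interferometry (BLI): blank subtraction, plateau read, K_D fit.

A BLI interferogram records the optical-thickness shift (nm) on a sensor
tip over time as an analyte at a fixed concentration associates with the
immobilized ligand. The equilibrium analysis implemented here is:

1. **Blank subtraction** — subtract the trace measured with the carrier
   protein alone (e.g. free MBP) at the same concentration, removing
   non-specific background.
2. **Plateau extraction** — read the corrected shift at the end of the
   association phase (default t = 150 s on the absolute time axis),
   linearly interpolating between bracketing samples.
3. **One-site fit** — fit the equilibrium binding isotherm (one binding
   site hyperbola)

       B(c) = B_max * c / (K_D + c)

   to the (concentration, plateau shift) pairs by unweighted nonlinear
   least squares, giving the dissociation constant K_D (molar) and the
   saturation response B_max (nm).

Kinetic (k_on/k_off) fitting is deliberately out of scope: K_D comes
from equilibrium plateaus only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "Interferogram",
    "BindingCurve",
    "BindingFitResult",
    "DegenerateFitError",
    "PairingError",
    "KD_BOUNDS",
    "one_site",
    "subtract_blank",
    "extract_plateau",
    "fit_one_site",
    "build_binding_curve",
]

#: Plausible K_D range in molar; estimates at these bounds flag non-convergence.
KD_BOUNDS = (1e-12, 1e-2)

#: Default plateau read time (s), the end of the association phase.
DEFAULT_PLATEAU_TIME = 150.0


class PairingError(ValueError):
    """Signal and blank traces do not refer to the same concentration."""


class DegenerateFitError(ValueError):
    """The binding curve carries no signal to fit (all shifts zero)."""


@dataclass
class Interferogram:
    """One BLI time course at a single analyte concentration."""

    analyte: str
    concentration: float  # molar
    time: np.ndarray  # seconds, strictly increasing
    shift: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.shift.shape:
            raise ValueError("time and shift must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("an interferogram needs >= 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class BindingCurve:
    """Equilibrium responses: plateau shift (nm) per analyte concentration (M)."""

    analyte: str
    concentrations: np.ndarray  # molar, > 0
    responses: np.ndarray  # nm
    blank_corrected: bool = True

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses differ in length")
        if np.any(self.concentrations <= 0):
            raise ValueError("analyte concentrations must be positive")
        if np.unique(self.concentrations).size < 3:
            raise ValueError("fitting needs >= 3 distinct concentrations")


@dataclass
class BindingFitResult:
    """One-site hyperbola fit: K_D and B_max with uncertainty diagnostics."""

    analyte: str
    kd: float  # molar
    bmax: float  # nm
    kd_se: float
    bmax_se: float
    rss: float
    converged: bool
    n_points: int = 0


def one_site(c: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    """Equilibrium one-site binding isotherm B(c) = B_max * c / (K_D + c)."""
    c = np.asarray(c, dtype=float)
    return bmax * c / (kd + c)


def subtract_blank(signal: Interferogram, blank: Interferogram) -> Interferogram:
    """Pointwise signal minus blank on the signal's time grid.

    The blank is linearly interpolated when its grid differs from the
    signal's. Both traces must refer to the same analyte concentration
    (the blank is the carrier protein at that concentration) and the
    blank's time range must cover the signal's.
    """
    if not math.isclose(
        signal.concentration, blank.concentration, rel_tol=1e-9, abs_tol=0.0
    ):
        raise PairingError(
            f"concentration mismatch: signal {signal.concentration} M "
            f"vs blank {blank.concentration} M"
        )
    if blank.time[0] > signal.time[0] or blank.time[-1] < signal.time[-1]:
        raise ValueError(
            "blank time range does not cover the signal trace; cannot subtract"
        )
    blank_on_grid = np.interp(signal.time, blank.time, blank.shift)
    return Interferogram(
        analyte=signal.analyte,
        concentration=signal.concentration,
        time=signal.time.copy(),
        shift=signal.shift - blank_on_grid,
    )


def extract_plateau(
    trace: Interferogram, t_plateau: float = DEFAULT_PLATEAU_TIME
) -> float:
    """Shift (nm) at the plateau time, linearly interpolated."""
    if not (trace.time[0] <= t_plateau <= trace.time[-1]):
        raise ValueError(
            f"plateau time {t_plateau} s outside trace span "
            f"[{trace.time[0]}, {trace.time[-1]}] s"
        )
    return float(np.interp(t_plateau, trace.time, trace.shift))


def build_binding_curve(
    signals: Sequence[Interferogram],
    blanks: Sequence[Interferogram],
    t_plateau: float = DEFAULT_PLATEAU_TIME,
) -> BindingCurve:
    """Blank-subtract each trace and collect plateau responses per concentration.

    Blanks are matched to signals by concentration; every signal needs
    exactly one matching blank.
    """
    by_conc = {b.concentration: b for b in blanks}
    concs: List[float] = []
    resp: List[float] = []
    analyte = signals[0].analyte if signals else "analyte"
    for sig in signals:
        blank = by_conc.get(sig.concentration)
        if blank is None:
            raise PairingError(
                f"no blank trace at concentration {sig.concentration} M"
            )
        corrected = subtract_blank(sig, blank)
        concs.append(sig.concentration)
        resp.append(extract_plateau(corrected, t_plateau))
    return BindingCurve(
        analyte=analyte,
        concentrations=np.array(concs),
        responses=np.array(resp),
        blank_corrected=True,
    )


def _initial_guesses(curve: BindingCurve) -> List[Tuple[float, float]]:
    """Multi-start initializations: half-max heuristic plus jittered restarts."""
    bmax0 = float(np.max(curve.responses))
    if bmax0 <= 0:
        bmax0 = 1.0
    half = bmax0 / 2.0
    above = curve.responses >= half
    kd0 = float(curve.concentrations[above][0]) if above.any() else float(
        np.median(curve.concentrations)
    )
    return [(bmax0, kd0), (bmax0, kd0 * 0.3), (bmax0, kd0 * 3.0)]


def fit_one_site(curve: BindingCurve) -> BindingFitResult:
    """Unweighted least-squares fit of the one-site hyperbola.

    Uses three deterministic starts (half-max K_D guess and x0.3 / x3
    jitters) and keeps the solution with the lowest residual sum of
    squares. ``converged`` is False when every start fails or the K_D
    estimate sits at the plausibility bounds (1 pM .. 10 mM).
    """
    if not curve.blank_corrected:
        raise ValueError("fit requires a blank-corrected binding curve")
    if np.allclose(curve.responses, 0.0):
        raise DegenerateFitError(
            f"all responses are zero for {curve.analyte!r}; nothing to fit"
        )
    # fit in dimensionless units so the optimizer's path is invariant to
    # the measurement scales (nM vs uM concentrations, nm response size)
    c_ref = float(np.max(curve.concentrations))
    y_ref = float(np.max(np.abs(curve.responses)))
    c = curve.concentrations / c_ref
    y = curve.responses / y_ref

    best: Tuple[float, np.ndarray, np.ndarray] | None = None  # (rss, popt, pcov)
    bounds = ([0.0, KD_BOUNDS[0] / c_ref], [10.0, KD_BOUNDS[1] / c_ref])
    for bmax0, kd0 in _initial_guesses(curve):
        p0 = (
            min(max(bmax0 / y_ref, 1e-12), 10.0),
            min(max(kd0 / c_ref, bounds[0][1]), bounds[1][1]),
        )
        try:
            popt, pcov = curve_fit(
                one_site, c, y, p0=p0, bounds=bounds, maxfev=10000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14, x_scale="jac",
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - one_site(c, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)

    if best is None:
        logger.warning("one-site fit failed to converge for %s", curve.analyte)
        return BindingFitResult(
            curve.analyte, math.nan, math.nan, math.nan, math.nan, math.nan,
            converged=False, n_points=c.size,
        )

    rss, popt, pcov = best
    bmax, kd = float(popt[0]) * y_ref, float(popt[1]) * c_ref
    rss *= y_ref**2
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov)) * np.array([y_ref, c_ref])
    at_bounds = not (KD_BOUNDS[0] * 1.01 < kd < KD_BOUNDS[1] * 0.99)
    if at_bounds:
        logger.warning(
            "K_D estimate %.3g M at plausibility bound for %s", kd, curve.analyte
        )
    return BindingFitResult(
        analyte=curve.analyte,
        kd=kd,
        bmax=bmax,
        kd_se=float(perr[1]),
        bmax_se=float(perr[0]),
        rss=rss,
        converged=not at_bounds,
        n_points=int(c.size),
    )
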