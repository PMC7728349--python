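"""Equilibrium K_D from biolayer interferometry interferograms.

Simulates noisy 1:1 binding traces for a nanomolar-affinity analyte
(true K_D 95 nM) with a concentration-proportional blank background,
then runs the full pipeline: blank subtraction, plateau read at 150 s,
one-site hyperbola fit.
"""

from cobindkit import BliSimConfig, build_binding_curve, fit_one_site, simulate_bli

cfg = BliSimConfig(
    kd=95e-9,
    bmax=1.0,
    concentrations=(10e-9, 31.5e-9, 62.5e-9, 100e-9, 150e-9, 200e-9),
    noise_sd=0.02,
    blank_slope=1e6,  # nm per molar of carrier-protein background
    seed=5,
    analyte="zf4-8",
)
signals, blanks = simulate_bli(cfg)
curve = build_binding_curve(signals, blanks, t_plateau=150.0)

print("concentration (nM)   plateau shift (nm)")
for c, r in zip(curve.concentrations, curve.responses):
    print(f"{c * 1e9:12.1f} {r:20.3f}")

result = fit_one_site(curve)
rel_err = abs(result.kd - cfg.kd) / cfg.kd
print(f"\nK_D   = {result.kd * 1e9:6.1f} nM  (true {cfg.kd * 1e9:.0f} nM, "
      f"off by {100 * rel_err:.0f}%)")
print(f"B_max = {result.bmax:6.3f} nm  (true {cfg.bmax:.1f} nm)")
print(f"RSS   = {result.rss:.2e},  converged = {result.converged}")

print(
    "\nPlateau shifts rise hyperbolically with concentration and "
    "half-saturate near K_D. A single 6-point equilibrium series "
    "determines K_D only to within a few tens of percent: the top "
    "concentration is ~2x K_D, so B_max and K_D are correlated and "
    "plateau noise propagates into both. Medians over many replicate "
    "series (as the test suite measures) land much closer to truth."
)
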