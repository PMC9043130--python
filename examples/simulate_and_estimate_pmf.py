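"""Umbrella sampling on synthetic trajectories: recover w(z) and D(z).

Generates biased Brownian-dynamics windows over a known 4 kcal/mol barrier,
then reweights them (binned WHAM) into a PMF and estimates the diffusion
coefficient from per-window variance and correlation time.
"""

import numpy as np

import permeakit as pk
from permeakit.pmf import UmbrellaWindow, estimate_diffusion, estimate_pmf

barrier = pk.GaussianBarrier(height=4.0, center=0.0, width=2.5)
D_true = 0.02  # Å²/ps

windows = []
for i, center in enumerate(np.arange(-12.0, 12.1, 2.0)):
    cfg = pk.SimConfig(dt=0.01, n_steps=2_000_000, seed=10 + i, output_stride=50,
                       initial_z=float(center), domain=(-16, 16))
    ts = pk.simulate(barrier, pk.ConstantDiffusion(D_true),
                     [pk.HarmonicBias(k=2.5, center=float(center))], cfg)
    windows.append(UmbrellaWindow(float(center), 2.5, ts))

pmf = estimate_pmf(windows, bin_width=0.2, bulk_region=(-13, -11))
print(f"PMF barrier: {pmf.barrier:.2f} kcal/mol (true 4.00), "
      f"{pmf.meta['iterations']} WHAM iterations")

dprof = estimate_diffusion(windows)
print(f"D(z) at window centers: {dprof.D.min():.4f}–{dprof.D.max():.4f} Å²/ps "
      f"(true {D_true})")
print(f"correlation times: {dprof.tau.min():.1f}–{dprof.tau.max():.1f} ps")
# The barrier height should land within ~0.1 kcal/mol of truth at this
# sampling (20 ns/window); D is noisier near the barrier where the windows
# feel the anharmonic flank.
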