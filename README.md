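# refrase — iterative fringe-phase restoration for QSM

Quantitative susceptibility mapping (QSM) reconstructs tissue magnetic
susceptibility χ (ppm) from the phase of multi-echo gradient-echo MRI by
inverting a dipole convolution: the measured field shift is
b = f₀·10⁻⁶·(χ * d) with D(k) = 1/3 − k_z²/|k|² and f₀ the Larmor
frequency. The inversion needs a contiguous, trustworthy field map — but
near the rim of the brain support, background gradients from air cavities
and bone push the per-voxel phase change beyond π, the Nyquist limit of
any unwrapper. Those "fringe" voxels are usually thrown away (shrinking
the mask) or left in (streaking the whole map).

This package restores them. The background field estimated on the
trustworthy interior (evaluation area m_EA, delineated by local phase
coherence) is *parametric* — orthonormalized solid spherical harmonics
plus an explicit external dipole-source distribution — so it can be
extrapolated onto the full brain support m_max and subtracted from the raw
wrapped phase **before** unwrapping:

    b = b̃_bg + U( wrap(φ̂(t) − wrap(2π·t·b̃_bg)) ) / (2π·t)

Subtract-then-unwrap succeeds exactly where unwrap-then-subtract provably
fails (see `examples/02_order_of_operations.py`). Iterating — map the
corrected phase, re-mask by coherence, refit the background, re-correct
the raw phase — grows m_EA toward m_max over a handful of iterations.
Susceptibility maps come from a hybrid Tikhonov + gradient-regularized
inversion (no spatial priors). A self-contained numerical head phantom
(7 T, 128³, assigned susceptibilities, random 5th-order harmonic
background, T2* decay, complex noise, Monte-Carlo instances) provides the
test bed, ground truth and evaluation protocol.

Intended users: researchers working on MRI phase processing, QSM pipeline
developers, and anyone needing a reproducible phantom for background-field
and unwrapping benchmarks.

## Worked example

```python
from refrase import (PhantomSpec, RefraseConfig, simulate_phantom,
                     conventional_pipeline, reconstruct_qsm, refrase_iterate)
from refrase.evaluate import evaluate_reconstruction

spec = PhantomSpec.scaled(grid=64, rng_seed=1)     # scaled-down phantom
series, gt = simulate_phantom(spec)
cfg = RefraseConfig(q_lc_min=0.6, n_iterations=5,
                    reconstruct_each_iteration=True, early_stop_rel=0.0)

b_conv, m_conv = conventional_pipeline(series, gt.labels.m_max, cfg)
chi_conv = reconstruct_qsm(b_conv.data, m_conv, cfg.qsm).chi
print(evaluate_reconstruction(chi_conv, m_conv, gt))

report = refrase_iterate(series, gt.labels.m_max, cfg)
for rec in report.records:
    m = evaluate_reconstruction(rec.chi, rec.m_ea, gt)
    print(rec.iteration, rec.n_rel, m["chi_std_R1"], m["rmse_rim"])
```

Output (`python examples/04_refrase_vs_conventional.py`):

```
conventional (single pass, m_EA = m_max):
  sigma_chi(R1) = 0.0258 ppm, rim RMSE = 0.0255 ppm
restoration loop (threshold 0.6):
  iter 1: n_rel = 0.0346, sigma_chi(R1) = 0.0258 ppm, rim RMSE = 0.0233 ppm
  iter 2: n_rel = 0.0233, sigma_chi(R1) = 0.0202 ppm, rim RMSE = 0.0202 ppm
  iter 3: n_rel = 0.0180, sigma_chi(R1) = 0.0195 ppm, rim RMSE = 0.0195 ppm
  iter 4: n_rel = 0.0148, sigma_chi(R1) = 0.0213 ppm, rim RMSE = 0.0191 ppm
  iter 5: n_rel = 0.0136, sigma_chi(R1) = 0.0205 ppm, rim RMSE = 0.0184 ppm
```

`n_rel` is the fraction of the brain support still excluded from the
evaluation area: it peaks at the first iteration (coherence masking
removes the corrupted rim) and then shrinks as restored phase re-enters.
The control-region scatter σ_χ(R1) and the rim RMSE against ground truth
both end below the conventional single-pass result.

Each `examples/0*.py` script demonstrates one capability (phantom
simulation, order of operations, background fitting, the restoration loop,
the inversion) and prints what its numbers mean. A thin CLI wraps the same
code: `refrase simulate|refrase|conventional|qsm|evaluate|sweep --help`.

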