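"""Iterative fringe-phase restoration vs the conventional single pass.

Simulates one noisy phantom, runs both pipelines, reconstructs
susceptibility, and compares mask coverage, control-region homogeneity
and rim error against the known ground truth.
"""

import numpy as np

from refrase import (PhantomSpec, QSMConfig, RefraseConfig,
                     conventional_pipeline, reconstruct_qsm, refrase_iterate,
                     simulate_phantom)
from refrase.evaluate import evaluate_reconstruction

spec = PhantomSpec.scaled(grid=64, rng_seed=1)
series, gt = simulate_phantom(spec)
m_max = gt.labels.m_max
cfg = RefraseConfig(q_lc_min=0.6, n_iterations=5, early_stop_rel=0.0,
                    reconstruct_each_iteration=True)

print("conventional (single pass, m_EA = m_max):")
b_conv, m_conv = conventional_pipeline(series, m_max, cfg)
chi_conv = reconstruct_qsm(b_conv.data, m_conv, cfg.qsm).chi
mc = evaluate_reconstruction(chi_conv, m_conv, gt)
print(f"  sigma_chi(R1) = {mc['chi_std_R1']:.4f} ppm, "
      f"rim RMSE = {mc['rmse_rim']:.4f} ppm")

print("restoration loop (threshold 0.6):")
report = refrase_iterate(series, m_max, cfg)
for rec in report.records:
    m = evaluate_reconstruction(rec.chi, rec.m_ea, gt)
    print(f"  iter {rec.iteration}: n_rel = {rec.n_rel:.4f}, "
          f"sigma_chi(R1) = {m['chi_std_R1']:.4f} ppm, "
          f"rim RMSE = {m['rmse_rim']:.4f} ppm")
# n_rel is the excluded fraction of the brain support; it shrinks as rim
# phase is restored, while the control-region scatter and the rim error
# drop well below the conventional result.
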