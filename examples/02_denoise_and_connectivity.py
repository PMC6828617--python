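"""Denoise ROI series and build per-condition Fisher-z connectivity maps.

Shows the confound-regression + band-pass stage and the condition-wise scan
pooling that turns each subject into one connectivity map per condition.
"""

import fcmvpa as f
from fcmvpa.denoise import build_task_regressors

design = f.make_design(n_runs=2, stimulus_types=("face", "body"),
                       repetitions=2, seed=3)
effect = f.EffectSpec(n_rois=20, base_covariance=f.blocked_correlation(20))
subject = f.simulate_subject(design, effect, f.NoiseSpec(), seed=3)

denoised = f.denoise_subject(subject, design)
print(f"denoised run shapes: {[t.shape for t in denoised.timeseries]}")

regs = build_task_regressors(design, run=0)
idx = f.condition_scan_indices(regs, "fear|face")
print(f"scans assigned to fear|face in run 1: {len(idx)} "
      f"(first few: {idx[:5].tolist()})")

indices = [
    f.condition_scan_indices(build_task_regressors(design, run=r), "fear|face")
    for r in range(design.n_runs)
]
cm = f.fc_map(denoised.timeseries, indices, "fear|face",
              subject_id=subject.subject_id)
fv = f.vectorize_lower_triangle(cm)
print(f"connectivity map: {cm.z_matrix.shape}, pooled scans: {cm.n_scans_used}")
print(f"feature vector length: {len(fv.values)} = 20*19/2 edges")
print(f"mean within-community z: {fv.values[fv.values > 0.2].mean():.2f} "
      "(Fisher z of the simulated rest correlations)")
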