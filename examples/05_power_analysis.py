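"""Simulation-based power analysis for cross-lagged network designs.

How large a two-wave sample is needed to recover a realistic sparse
19-node network?  Each cell simulates panels from the default generative
model, runs the full estimation pipeline, and scores edge recovery against
the generating matrix.  A sample size is adequate when sensitivity,
specificity and the weight correlation all clear 0.6.
"""

from clpnet import AnalysisConfig, default_spec, power_analysis

spec = default_spec(seed=8)
config = AnalysisConfig(cv_folds=5, lambda_grid_size=40)
curve = power_analysis(spec, n_grid=[250, 1000, 4000], replications=3,
                       seed=8, config=config)

print(curve.to_frame().round(3).to_string(index=False))
worst = {n: min(curve.mean[m][n] for m in curve.mean)
         for n in curve.sample_sizes}
print("\nminimum of the three recovery properties per sample size:")
for n, v in worst.items():
    verdict = "adequate" if v > 0.6 else "underpowered"
    print(f"  n={n:>5}: {v:.3f}  ({verdict})")
# Sensitivity rises steeply with n; specificity stays high because edge
# retention uses the pipeline's cross-lagged threshold rather than the raw
# penalized support.
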