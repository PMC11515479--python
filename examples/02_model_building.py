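"""Rebuild the estimation equation from synthetic design samples.

Generates 2000 averaged samples whose PaCO2 follows the published
equation exactly (zero noise), then runs the full model-building chain:
exclusion filters, candidate-feature catalogue (identity/square/cube/log
of 17 base variables), iterative residual-correlation selection and
Huber IRLS refits.  With noise-free data the procedure must recover the
published term set and coefficients; the printed trace shows which term
each iteration picked and at what correlation.
"""

from paco2est import (FORCED_TERM, apply_filters, build_design_matrix,
                      enumerate_candidates, generate_design_samples,
                      published_model, select_iteratively)

samples, _ = generate_design_samples(2000, rng=7, noise_sd=0.0,
                                     outlier_fraction=0.0)
kept, report = apply_filters(samples)
print(f"filters: kept {report.n_kept}/{report.n_input} "
      f"({report.n_excluded_paco2} with PaCO2 > 75 mmHg, "
      f"{report.n_excluded_vte} with Vte < 12 mL)")

catalogue = enumerate_candidates(kept)
print(f"candidate catalogue: {len(catalogue)} transforms "
      "(etCO2 itself is always in the model)")

design = build_design_matrix(kept, [FORCED_TERM, *catalogue])
model, trace = select_iteratively(design)

print("\nselection trace (term, |Pearson r| with current deviation):")
for step in trace.steps:
    print(f"  {step.index + 1}. {step.chosen.label:<10} |r| = "
          f"{step.max_abs_r:.3f}")
print(f"stopped: {trace.stop_reason} (no candidate above |r| = 0.2)")

print(f"\nrecovered equation: PaCO2 = {model.intercept:.4f}")
for term, coef in model.coefficients.items():
    print(f"    {coef:+.4f} * {term.label}")

truth = published_model()
worst = max(abs(model.coefficients[t] - c)
            for t, c in truth.coefficients.items())
print(f"\nlargest coefficient deviation from the published equation: "
      f"{worst:.2e} (noise-free recovery is exact to numerical precision)")
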