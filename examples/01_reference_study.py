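"""Load the reference dissolution study and inspect its structure.

The study is a 25-run D-optimal mixture design for glipizide
sustained-release tablets: five excipient percentages summing to 82.8 % of
the tablet mass, with cumulative release measured at 2, 8 and 24 h.
"""

import mixrelease as mr

ds = mr.load_reference_dataset()
print(f"{ds.n_formulations} formulations x {ds.q} components, "
      f"release at t = {ds.times.tolist()} h")
print(ds.to_frame().head(5).to_string(index=False))

report = mr.validate_constant_sum(ds)
print(f"\nconstant-sum check at the rounding-aware tolerance "
      f"({report.tol}): pass = {report.passed}")
print("rows off the exact 82.8 total (printed rounding):")
print(report.table[report.table.deviation > 0.05].to_string(index=False))

print("\nPearson correlations of the releases across time points:")
print(mr.pearson_correlations(ds).round(2).to_string())
print("\nSpearman (rank) correlations - their magnitudes match the "
      "published heatmap values 0.23 / 0.62 / 0.69:")
print(mr.response_correlations(ds, method="spearman").round(2).to_string())
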