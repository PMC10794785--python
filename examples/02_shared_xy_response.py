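"""Compare the responses to Chr X and Chr Y copy number.

Simulates a gene panel in which a subset responds to both chromosomes with
Y effects ~0.7x the X effects, refits the dosage model, and asks: do the
significant X- and Y-responsive sets overlap more than chance, and what is
the slope relating Y to X effects when both are measured with error?
"""

from xydosage import dosage_model as dm
from xydosage import shared_response as sr
from xydosage import synthetic_data as sd

meta = sd.generate_design(sd.LCL_DESIGN, seed=1)
truth = sd.generate_truth(3000, 0.18, 0.08, 0.06, seed=5)
counts = sd.generate_counts(meta, truth, seed=6)
fit = dm.fit_dosage_glm(counts, meta)

fx = fit[fit["coef"] == "x_copies"].set_index("gene")
fy = fit[fit["coef"] == "y_copies"].set_index("gene")
sig_x = set(fx.index[fx["padj"] < 0.05])
sig_y = set(fy.index[fy["padj"] < 0.05])

ov = sr.overlap_test(sig_x, sig_y, set(fx.index))
print(f"X-responsive: {ov.n_a}, Y-responsive: {ov.n_b}, shared: {ov.n_overlap}")
print(f"hypergeometric overlap p: {ov.p:.3g}")

both = sorted(sig_x & sig_y)
r, p, _ = sr.correlate_effects(
    fit[fit["coef"] == "x_copies"], fit[fit["coef"] == "y_copies"], both
)
dem = sr.weighted_deming(
    fx.loc[both, "log2fc_per_copy"], fy.loc[both, "log2fc_per_copy"],
    fx.loc[both, "se"], fy.loc[both, "se"],
)
print(f"Pearson r of shared-gene effects: {r:.3f}")
print(f"weighted Deming slope (Y per X): {dem.slope:.3f} "
      f"(95% CI {dem.ci95[0]:.3f}-{dem.ci95[1]:.3f})")
# A slope below 1 means each Y chromosome shifts these genes less than
# each inactive X does, while the high correlation shows the same genes
# move in the same direction.
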