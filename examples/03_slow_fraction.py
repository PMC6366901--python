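"""Measure the slow-growing subpopulation of a growth-rate distribution.

Wild-type yeast shows a ~10% slow-growing subpopulation next to a fast
bulk whose mode sits at 0.407 1/h.  The slow fraction is the percentage
of colonies outside the left edge of the bulk, found by scanning the
cumulative distribution for its steepest 5-point window and walking out
to where the CDF leaves the fitted line by more than 0.02 1/h.
"""

from microhet import hetstats, synth

spec = synth.MixtureSpec(components=synth.WT_MIXTURE, n_colonies=2000,
                         rng_seed=7)
rates = synth.generate_rate_mixture(spec)["rate"].to_numpy()

summary = hetstats.summarize(rates)
print(f"mode growth rate : {summary.mode:.2f} 1/h")
print(f"slow fraction    : {summary.slow_fraction:.1f} %")
print(f"fast fraction    : {summary.fast_fraction:.1f} %")
print(f"bulk edges       : {summary.bulk_edges}")
print(f"mean {summary.mean:.3f} 1/h, CV {summary.cv:.2f}")
# With a 10% slow component planted at 0.15 1/h the statistic reports a
# slow fraction near 10% and a mode on the 0.01 grid next to 0.407.
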