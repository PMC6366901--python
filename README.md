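# microhet

Single-cell proliferation heterogeneity from microcolony time-lapse
imaging, for yeast geneticists and quantitative microbiologists studying
why isogenic cells grow at different rates.

Clonal yeast populations contain a slow-growing subpopulation (~10% in
common lab strains) alongside a fast bulk whose mode growth rate is
0.407 h⁻¹. `microhet` implements the complete analysis chain behind that
observation, from raw images to population statistics:

1. **Imaging** — cells are detected as pixels beyond mean ± 2.2 s.d. of
   the frame (plus optional Sobel edges), grouped into microcolonies by
   connected components after binary closing, tracked by mutual-nearest
   centroids, truncated when colonies touch, and filtered (> 50 px at
   start, > 2-fold growth).
2. **Growth rates** — for each colony, OLS of ln(area) on time over every
   3-timepoint window; windows with R² < 0.9 are discarded and the
   maximum surviving slope is the colony's rate. Centered per-timepoint
   rates feed a run-based fast↔slow switching classifier, and a strict
   0.02 h⁻¹ cutoff scores survival in long drug assays.
3. **Heterogeneity statistics** — on a 0.01 h⁻¹ grid: the mode (smoothed
   histogram argmax) and the slow/fast fraction, defined as the
   percentage of colonies outside the bulk's edges. Edges are found by
   scanning the CDF for its steepest 5-point window, fitting a line
   there, and walking out to the first point deviating horizontally by
   more than 0.02 h⁻¹. Includes the mode-shift calibration that corrects
   slow fractions of mutants with reduced modes, and penetrance as
   overlap with the wild-type bulk.
4. **Screen analysis** — replicate reproducibility via shifted
   Kolmogorov–Smirnov distance graphs (means aligned up to 0.05 h⁻¹,
   edges require D ≤ 0.1, largest clique kept), Mann–Whitney tests with
   BH-FDR < 0.1 classifying strains into seven phenotype categories, and
   upper-tail hypergeometric enrichment
   p = Σᵢ₌ₓ₉ C(X,i)·C(N−X,Ng−i)/C(N,Ng) over functional classes.
5. **Organelle state model** — the closed-form prediction of the
   low-membrane-potential (TMRE) fraction under exponential growth with
   no high→low switching,

   ```
   % low = 100 · f_low·e^(r_f t)·(1 − s) /
           (f_slow·e^(r_s t) + f_fast·e^(r_f t) + f_low·e^(r_f t))
   ```

   quantile gating into HI/M1/M2/LO bins, petite (respiration-deficiency)
   percentages, and absolute mtDNA copy number from qPCR standard curves
   with delta-method error propagation.
6. **Synthetic data** — seeded generators for every input: rendered image
   stacks with exact ground truth, growth-rate mixtures, planted
   deletion screens, branching state-switching populations, annotation
   tables and qPCR plates.

## Worked example

```python
from microhet import hetstats, synth

spec = synth.MixtureSpec(components=synth.WT_MIXTURE, n_colonies=2000,
                         rng_seed=7)
rates = synth.generate_rate_mixture(spec)["rate"].to_numpy()
s = hetstats.summarize(rates)
print(s.mode, s.slow_fraction, s.bulk_edges)
```

prints

```
0.41 9.5 (0.35000000000000003, 0.46)
```

— the mode snaps to the 0.01 h⁻¹ grid next to the planted 0.407 h⁻¹
bulk, the slow fraction reports the planted 10% slow subpopulation
(9.5% in this draw), and the bulk occupies 0.35–0.46 h⁻¹. The
`examples/` directory has one short script per capability (tracking,
growth rates, slow fraction, screen classification, the switching
model, qPCR); each prints its numbers with a note on what they mean. A
thin CLI mirrors the stages: `microhet synth|track|rates|hetstats|
screen|organelle|run`.

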