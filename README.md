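# raphequant

Quantification pipeline for characterizing Cre-driver mouse lines and mapping
circuitry of the dorsal raphe (DR), a heterogeneous midbrain nucleus
containing serotonin (5HT), dopamine (DA), GABA and glutamate neurons.
Studies in this area hinge on a handful of counting procedures that are easy
to describe and easy to get subtly wrong; `raphequant` implements them as a
tested, reproducible library:

* **Colocalization counting** — reporter-labeled (eYFP+) somata are detected
  per channel, assigned to four ~300 × 300 µm DR subregions, and classified
  by co-expression of an identity marker (TpH for 5HT, TH for DA).
  *Specificity* of a line is the fraction of reporter cells carrying the
  marker, `100 · n_double / n_total`; *penetrance* is the number of
  marker-positive cells labeled per animal, summarized as mean ± SEM.
* **Monosynaptic input mapping** — rabies-label-positive pixels are segmented
  by a fixed intensity threshold, artifact ROIs removed, pixels assigned to
  atlas regions via an integer label map, designated regions (injection site
  and neighbors, olfactory bulb, cerebellum) excluded, and counts normalized
  once per brain to percent of total input pixels. A validation regression of
  pixel counts on manual neuron counts quantifies the pixel-count bias.
* **Axon density** — background subtraction (white top-hat), fixed-threshold
  binarization, and coverage `100 · positive px / ROI px` per target region.
* **Evoked-EPSC analysis** — 10 sweeps averaged per cell, peak inward
  deflection measured in the 50 ms window after the light pulse, cells with
  peaks not exceeding the 10 pA baseline-noise criterion classified as
  non-responders, and paired comparisons for pharmacological block.
* **Statistics** — summary-based Welch *t*
  (`t = (m₁−m₂)/√(SEM₁²+SEM₂²)` with Welch–Satterthwaite df), paired *t*,
  one-/two-way ANOVA + Tukey, a Spearman |residual|-vs-fitted variance gate,
  Box-Cox transformation with MLE λ, and Benjamini–Hochberg FDR adjustment.

Because microscopy and electrophysiology raw data of this kind are rarely
shareable, the package ships a first-class synthetic-data generator
(`raphequant.synth`) that renders sections, pseudo-brain series, axon fields
and sweep sets with planted ground truth, so every stage of the pipeline is
benchmarked against known answers.

## Worked example

```python
from raphequant import cellcount, synth

spec = synth.SectionSpec(p_coexpress=0.95, cells_per_subregion=40, seed=1)
section, truth = synth.make_section(spec)

policy = cellcount.DetectionPolicy(threshold=0.425)
dets = cellcount.detect_cells(section, "reporter", policy)
dets = cellcount.classify_coexpression(dets, section, "marker", policy)
dets = cellcount.assign_subregions(dets, spec.subregion_layout, section.um_per_px)
table = cellcount.tabulate(dets, animal_id="demo", marker="marker",
                           layout=spec.subregion_layout)
print(table.total_double(), "/", table.total(),
      "=", cellcount.percent_coexpressing(table), "%")
```

prints

```
151 / 160 = 94.4 %
```

— 160 planted somata are all recovered, 151 of them double-labeled, and the
pooled specificity (94.4%) sits inside the binomial spread of the planted
co-expression probability 0.95. The scripts in `examples/` walk through each
capability the same way (input mapping prints per-region pixel fractions next
to planted truth with the validation R²; the EPSC example prints responder
fractions and the paired CNQX-block *t*-test). A thin CLI mirrors the
library: `raphequant simulate|coloc|inputmap|axon|ephys|demo --help`.

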