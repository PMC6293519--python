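# flipr-screen

Analysis pipeline for genome-wide dsRNA calcium-mobilization screens, built
around the screen for *Drosophila* genes that regulate GBP/PLC-mediated
Ca²⁺ signaling: cells carrying a genetically encoded Ca²⁺ sensor are plated
on 384-well dsRNA library plates, stimulated with the growth-blocking
peptide (GBP) cytokine, and read kinetically on a fluorometric imaging
plate reader (FLIPR). The package is for screeners and computational
biologists who need the whole downstream analysis — trace quantification,
plate normalization, positive-control QC, hit calling and housekeeping
filtering — as tested, scriptable components, together with a synthetic
plate generator so every stage can be validated against planted ground
truth.

## The statistic

Each well's kinetic trace is reduced to the total agonist-induced change in
fluorescence ("[Ca²⁺]\_T"; trapezoidal area under the baseline-subtracted
curve by default, peak height as an alternative). Every dsRNA is then
scored within its plate:

    Z = (x − x̄_plate) / s_plate

with x̄ and s the mean and sample SD of the plate's library wells.
Replicate plates are merged by the unweighted mean Z per amplicon.
An amplicon is a *suppressor* hit when mean Z < −3 and an *enhancer* hit
when mean Z > +3 (strict inequalities); gene-level hits aggregate
amplicons. Before any of that, each plate must pass an internal-control
gate: an IP₃-receptor-class positive-control dsRNA has to inhibit the
response of the null-control wells by ≥ 60 %, otherwise the whole plate is
discarded. Finally, hit genes annotated to any of eleven GO categories
covering general transcription/translation machinery are filtered out,
since their knockdown depresses the fluorescent reporter itself.

The packaged reference tables (`src/flipr_screen/data/`) are the screen's
published filtered hit lists: 82 suppressor genes and 61 enhancer genes.

## Worked example

```python
import flipr_screen as fs

# a small synthetic screen: 500 genes, 1% planted suppressors/enhancers,
# screened in duplicate
design, truth = fs.generate_design(
    500, frac_suppressor=0.01, frac_enhancer=0.01,
    effect_params=fs.EffectParams(suppressor=(0.2, 0.2), enhancer=(1.8, 1.8)),
    seed=0)
params = fs.TraceModelParams()

import pandas as pd
frames = []
for p in range(design.n_layout_plates):
    for rep in (1, 2):
        traces = fs.simulate_plate(design, p, rep, truth, params, seed=0)
        frames.append(fs.quantify_traces(traces, params.agonist_add_time))
measurements = pd.concat(frames, ignore_index=True)

surviving, qc = fs.filter_plates(measurements)          # 60% control gate
z, _ = fs.screen_zscores(surviving)                     # per-plate Z
merged, _ = fs.merge_replicates(z)                      # mean Z per amplicon
hits, conflicts = fs.aggregate_genes(fs.call_amplicons(merged))
print(fs.recovery_report(hits, truth))
```

prints

```
  direction  tp  fp  fn   tn  sensitivity  fdr
0      down   5   0   0  495          1.0  0.0
1        up   5   0   0  495          1.0  0.0
```

i.e. all five planted suppressors (response multiplier 0.2 → strongly
negative Z) and all five enhancers (1.8 → strongly positive Z) are
recovered with no false positives at the ±3 cutoffs.

The same pipeline is available from the shell:

```
flipr-screen run-all --out run1 --seed 1
flipr-screen report --run-dir run1
```

which writes every stage table (measurements, QC report, Z-scores, merged
Z, hit lists pre/post housekeeping filter) plus a manifest into `run1/`.

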