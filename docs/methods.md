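# Methods

## Pipeline overview

The package analyses plate-based dsRNA knockdown screens whose readout is
a kinetic fluorescence trace per well of a 384-well plate: baseline, then
an agonist-evoked Ca²⁺ transient whose size reflects how strongly the
well's knockdown perturbs the GPCR/PLC/Ca²⁺ signaling axis. The stages
are: trace quantification → internal-control plate QC → per-plate Z-score
normalization → replicate merging → two-sided hit calling → GO-based
housekeeping filtering, with a synthetic plate generator supplying fully
specified inputs and ground truth.

## Trace model (synthetic data)

A well's trace is

    f(t) = F0 + A·g(t − t_add) + ε(t)

with `g` a peak-normalized difference of exponentials
(`exp(−s/τ_decay) − exp(−s/τ_rise)`, zero before agonist addition) and

    A = A_peak · (1 − e_plate · (1 − m)) · L,   L ~ lognormal, E[L]=1, CV=c_w

where `m` is the gene's multiplicative response effect (1 = null, < 1
suppressor, > 1 enhancer, 0 = complete pathway block), `e_plate ∈ [0, 1]`
the plate's knockdown efficiency, and `ε` i.i.d. Gaussian read noise.
Vehicle wells receive no transient. The kinetic form was chosen for
realism and a closed-form amplitude, not fitted to any instrument.

Defaults (arbitrary fluorescence units, seconds): `F0 = 1000`,
`A_peak = 500`, `t_add = 30`, 90 samples at `dt = 1`, `τ_rise = 3`,
`τ_decay = 15`, well-to-well CV `c_w = 0.05`, read noise SD 5. A 5 %
well CV is typical of FLIPR-class readers; it also keeps the lognormal
amplitude distribution close enough to Gaussian that the ±3 Z cutoff
retains its nominal two-sided tail rate of 2Φ(−3) ≈ 0.27 % — at CV 0.1
the standardized right tail alone would exceed 0.35 % and the fixed-cutoff
calibration the analysis assumes would no longer hold.

Plate efficiency models the screen's observed plate-to-plate variability
(library wells clustering atypically close to control). It is drawn per
plate dataset from a two-component mixture: good plates
`N(0.95, 0.03)` clipped to [0, 1], failed plates uniform on [0.2, 0.55],
failure probability 0.05 by default. The cause of such failures is not
modelled, only their signature: the internal control (true multiplier 0)
on a plate with efficiency `e` shows `100·e` percent inhibition, which is
exactly what the QC gate thresholds.

The default library emulates a genome-wide collection: 13,900 genes with
one or two amplicons each (74 % have two), filling 66 layout plates of
368 library wells plus 8 null-control, 4 internal-control and 4 vehicle
wells (the tail of column 24), screened in duplicate — 132 plate
datasets. Planted effect fractions default to 1 % suppressors and 1 %
enhancers (uniform multipliers on [0.1, 0.5] and [1.5, 2.5]); the
published screen's own hit rate is ~0.8 % of amplicons, and much larger
planted fractions would inflate the plate SD enough to defeat a fixed ±3
cutoff by construction. RNG streams derive from
(root seed, plate index, replicate), so any plate is reproducible in
isolation.

What the generator does *not* emulate: spatial plate effects (edge
evaporation, dispense gradients), temporal drift within a run, cytotoxic
wells, off-target dsRNA effects, and correlated noise between replicate
plates. Passing tests therefore demonstrate the *analysis* is correct
under the stated noise model, not that real screens are free of those
artifacts.

## Quantification

`ca_total` reduces a trace to the total agonist-induced change in
fluorescence. The baseline is the mean of all pre-addition samples
(window configurable, ≥ 2 samples enforced); the response window runs
from addition to the end of the trace. `auc` (default) is the trapezoidal
integral of the baseline-subtracted trace over the window — "total
change" read as an integrated response, capturing both store release and
entry; `peak` is provided because instrument software sometimes reports
peak height instead, and the choice is a config field. Negative
excursions are never clipped, so vehicle wells scatter around zero and
the plate statistics stay unbiased. No smoothing is applied by default;
an optional odd-width median filter is exposed for spike artifacts.

## Normalization and merging

Z-scores are computed per plate dataset as `(x − mean) / SD` with the
sample (n−1) SD. The centering population is the plate's library wells
only (default): dedicated control wells are drawn from a different
distribution and would bias the null center; `all_wells` is available
since the original description of "plate" is ambiguous. Plates need ≥ 3
library wells and positive SD; zero-SD plates are flagged as degenerate
and emit no scores. Replicates merge by the unweighted arithmetic mean
per amplicon; amplicons with no surviving replicate are reported as
unmeasured so coverage ("every dsRNA screened at least once") is
auditable. If a replacement assay of a plate survives alongside the
original, both enter the mean as additional replicates.

## Plate QC

A plate is retained iff the internal positive control inhibits the
null-control response by at least the cutoff (default 60 %):
`100·(1 − mean(IC)/mean(control))`, means over however many wells of each
role are present. The boundary is inclusive, with a 1e−9 guard so a
noise-free plate computing 60 − 1e−14 is not discarded by floating-point
round-off. Plates missing either well group are discarded as
not-evaluable with the reason recorded; every decision is logged and kept
in the QC report.

## Hit calling and filtering

Amplicon calls use strict inequalities at −3/+3. Genes aggregate with the
"any amplicon" policy by default (published hit lists contain
single-amplicon genes, so one must suffice); "all" is available for
stringent runs. Genes whose amplicons disagree in direction are
quarantined in a conflict report rather than resolved — the source
analysis never addresses the case. The housekeeping filter removes hits
whose genes carry any of eleven GO categories (splicing, ribosome,
translation and its factors, RNA-polymerase-II machinery) by direct
annotation; matching through the ontology closure is optional and takes a
user-supplied child→parent edge file, since resolving ancestors correctly
requires a specific GO release and none is bundled or fetched.

## Reference tables

The published filtered hit lists ship as TSV fixtures (82 suppressor and
61 enhancer genes). Typographic minus signs and thin spaces in the source
were normalized to ASCII. One suppressor row (drk) prints a single
amplicon id against two Z values; the fixture preserves the row as
printed and the parser accepts it by repeating the id with a warning. Two
enhancer amplicon ids appear under two gene rows each; the parser warns
but keeps them, as the printed table does.

## Problem sizes and numerical choices

The test suite and acceptance script use scaled-down libraries chosen to
exercise every code path with comfortable statistical margins: the
null-calibration check screens 10,000 amplicons in duplicate (20,000
per-replicate Z values; a binomial test at 99 % confidence against the
2Φ(−3) tail), recovery pools 20 seeded 500-gene screens (≈ 100 planted
effects per direction), and the QC sweep uses 20 plates spanning 30–90 %
efficiency. Shorter traces (40 samples, addition at 10 s) are used where
only amplitudes matter. Z-score correctness is held to 1e−12 against a
plain two-pass oracle (with a 1e−12 absolute floor where cancellation
makes a pure relative bound meaningless near Z = 0).

## Known limitations

Percent inhibition requires a positive control mean; plates whose control
wells average ≤ 0 are not evaluable rather than assigned a sign-flipped
inhibition. The null calibration of |Z| > 3 calls is stated for
per-replicate plate Z-scores; duplicate-merged mean Z has null SD 1/√2,
so its tail rate at the same cutoff is far smaller — fixed cutoffs on
merged scores are conservative by design. No spatial (B-score/median
polish) correction and no multiple-testing machinery are included: the
analysis deliberately mirrors a fixed-threshold screen designed to avoid
false positives.
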