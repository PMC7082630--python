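# Methods

`targetrank` implements a multi-evidence drug-target deconvolution
pipeline for chemical proteomics.  Three orthogonal readouts — thermal
stability, expression regulation, and cysteine oxidation — each produce
an ordinal protein ranking, and the rankings are combined by cumulative
summation into a single shortlist of candidate targets.  Because the
three assays fail in different ways (a near-terminus binder may barely
shift thermal stability; an allosteric effector may not touch a redox
site), the combined rank is far more specific than any single method.

## Thermal proteome profiling (TPP)

A TPP experiment heats drug- and vehicle-treated material for a few
minutes at each point of a temperature gradient (default 37, 41, 44,
47, 50, 53, 56, 59, 63, 67 °C), pellets the aggregated protein, and
quantifies what remains soluble, typically with one TMT reporter
channel per temperature.  Per protein, condition and replicate the
trace is normalised to the lowest-temperature channel and fitted with
the standard three-parameter melting sigmoid

    f(T) = (1 − p) / (1 + exp(b − a/T)) + p,

where `p ∈ [0, 0.5)` is the non-denaturing plateau, and `a` (°C units)
and `b` (dimensionless) jointly set the midpoint and steepness.  The
melting temperature is the 0.5 crossing, available in closed form:

    Tm = a / (b − ln(0.5 / (0.5 − p))),

defined when `p < 0.5` and `b > ln(0.5/(0.5 − p))`; fits violating the
precondition (flat traces, plateau at bound) are flagged unconverged
and excluded from ranking, as are crossings extrapolated far outside
the assay span (±20 °C beyond the grid).

Fitting is bounded least squares (`scipy.optimize.curve_fit`, a > 0,
b > 0, p ∈ [0, 0.5)).  The first attempt starts from a data-driven
guess — plateau from the hot tail, Tm from the first interpolated 0.5
crossing of the data, b₀ = 10 (a typical proteome steepness on this
grid) — which converges in one shot on essentially all realistic
traces; on failure up to 50 deterministically jittered restarts are
tried before declaring failure.  R² is reported but not gated on: the
only default exclusion beyond convergence is the replicate filter
below, and users who want curve-quality gates can apply them on the
fits table.

The thermal shift is ΔTm = mean(Tm, drug) − mean(Tm, vehicle) over
replicates.  Proteins with any missing or unconverged replicate trace,
or whose within-condition replicate Tm spread exceeds 1 °C (inclusive
boundary: exactly 1 °C passes), are excluded.  The spread can instead
be taken over per-replicate shifts (`mode="delta"`), which forgives a
batch effect common to both conditions of a replicate; per-condition is
the default and the stricter reading.  Survivors are ranked by |ΔTm|
descending.

## Expression proteomics

After ~48 h of drug exposure at LC50 across a panel of cell lines
(default three), the regulation score of a protein in a cell line is
the difference of replicate-mean log2 intensities, treated minus
control (unpaired; replicates are separate cultures).  Only proteins
quantified — present, finite, positive — in every control and drug
sample of the dataset are scored, which keeps rank sums comparable.
Contrast compounds run alongside the drug of interest are accepted in
the input and ignored by the ranking.  Per cell line proteins are
ranked by |score| descending (a signed mode exists for sensitivity
analysis); the per-cell-line ranks are summed and the sums re-ranked
ascending.  Intensities are assumed load-normalised upstream; an
optional per-sample median-centering step is available but off by
default.

## Redox proteomics

Sequential thiol labelling tags free thiols with a first isobaric
label, then reduces reversibly oxidised cysteines and tags them with a
second label, so per peptide and sample

    oxidation_ratio = label2 / (label1 + label2)

is the oxidised fraction of that cysteine pool.  Ratios are computed
per sample and averaged within condition; peptides must be quantified
in every sample (complete cases) to enter the analysis.  The
differential statistic is delta_ox = mean drug ratio − mean vehicle
ratio with a two-tailed equal-variance Student t-test.  Degenerate
variance cases resolve by the limit of the statistic (p = 1 for equal
means, p = 0 otherwise).  Peptides are ranked twice — delta_ox
descending (the drug of interest is an oxidant, so increases lead) and
p ascending — and the rank sum, re-ranked ascending, is the peptide
rank; an `absolute` mode ranks |delta_ox| for symmetric discovery.
Each protein inherits its best peptide's rank and proteins are
re-ranked ordinally.  No multiple-testing correction enters the
ranking (it is a ranking, not a discovery set); Benjamini–Hochberg
q-values are emitted as a courtesy column.

## Rank aggregation

Every method ranking is an ordinal permutation 1..n with ties broken
by protein identifier, so rankings are pure functions of their input.
Across methods, a protein missing from a method (not quantified, or
filtered) receives that method's penalty rank n_ranked + 1, flagged as
imputed; dropping incompletely observed proteins instead (available as
`policy="drop"`) would discard exactly the multi-evidence candidates
aggregation exists to find.  Cumulative sums are of raw ranks by
default; a normalised mode divides each rank by its list length first
to compensate very unequal method coverage.  Lowest sum = top
candidate.

The concordance join pairs peptides significant at p < 0.05 (strict)
with proteins shifted by |ΔTm| ≥ 1 °C and labels each pair concordant
when oxidation accompanies stabilisation or reduction accompanies
destabilisation.  Both thresholds are conventional defaults, exposed
as parameters.

## Synthetic data

The generator exists so that every stage, and the pipeline as a whole,
can be validated against planted ground truth.  It emulates the study
design: duplicate TPP runs with two conditions over the 10-point
gradient, triplicate expression runs over three cell lines with
control and drug arms, and triplicate redox runs with paired label
abundances.  A configurable subset of proteins are targets: +2 °C
melting shift under drug, a one-unit common-sign log2 fold change in
every cell line, and a +0.2 oxidised-fraction shift on one cysteine
peptide.  Background proteins have exactly zero true effect (the truth
tables record this), plus small zero-centred background regulation
(SD 0.1 log2 units) in the expression panel so that the background is
not artificially silent.

Baseline melting curves are drawn per protein — Tm ~ U(42, 60) °C,
plateau ~ U(0, 0.2), steepness b ~ U(9, 13) — so curves descend from
near 1 to their plateau within the gradient.  Noise has two abundance
scales because the assays do: within a single TMT plex (the TPP
channels) technical reporter noise is small, lognormal σ = 0.015,
calibrated so that replicate Tm discordance after fitting matches the
reproducibility reported for real TPP (median ≈ 0.3 °C, almost all
pairs within 1 °C); between biological replicate cultures (expression
intensities, redox totals) lognormal σ = 0.1.  Per-replicate Tm jitter
(σ = 0.1 °C) models true biological stability variation.  Oxidation
fractions are Beta-distributed around the true per-sample fraction
with concentration κ = 100 (ratio SD ≈ 0.04 at fraction 0.2; κ = 0
switches the noise off); a planted shift that would leave [0, 1] is
clipped with a warning.  Redox abundance noise scales both labels of a
sample jointly, so measured ratios carry only the Beta noise — this
preserves the labelling-depth invariance of the ratio and makes
zero-noise round-trips exact.  Missingness is completely at random,
per cell for TPP and expression and per label pair for redox (one
spectrum quantifies both labels); the default rate is 0 and tests set
explicit rates when exercising the filters.

What the generator does not emulate: reporter-ion ratio compression
and co-isolation interference, abundance-dependent missingness (real
missingness is left-censored, not MCAR), correlated noise across
peptides of one protein, protein-level normalisation artefacts, and
any real biological covariance between the three modalities.  Passing
the planted-target tests therefore demonstrates that the statistical
machinery is correct and well calibrated, not that real-data
sensitivity will match.

## Numerical and determinism choices

All rankings break ties by identifier ascending; every stochastic
component takes an explicit seed (restarts in the fitter use a fixed
internal seed), so a configuration plus seed reproduces every output
byte for byte.  TSVs encode missing values as empty fields and write
floats with `%.10g`.  The exp in the melting model is clipped at
|z| = 700 to avoid overflow in the flat tails.  Problem sizes used in
the validation suite — 100 random parameter draws for the Tm oracle,
200 random instances (≤ 500 items) for the ranking oracles, ~10,000
null peptides for t-test calibration, 20 seeds × 1005 proteins for
planted-target recovery, ~4,500 peptides for the missingness
bookkeeping — were chosen to make the binomial/KS tolerances involved
tight while keeping a full run inside a few minutes on one CPU.

## Known limitations

Tm estimates from 10-point curves are sensitive to noise in the
lowest-temperature reference channel (it scales the whole normalised
trace); real analyses mitigate this with proteome-wide normalisation,
which this package assumes has already happened.  For proteins melting
near the top of the gradient the plateau is not reached within the
assay span, the plateau parameter becomes weakly identified, and
replicate Tm estimates can disagree by more than the 1 °C concordance
threshold even at R² > 0.999 — such proteins are (correctly, per the
filter's definition) excluded from the thermal ranking and fall back
on the penalty rank in the aggregate.  The paired-shift filter mode
(`mode="delta"`) is more forgiving here because the identifiability
error is largely shared between conditions of a replicate.  The penalty
imputation for missing methods is a policy, not an inference — a
protein absent from a method is treated as "worst observed + 1", which
is deliberately harsh and configurable.  The concordance analysis uses
raw p-values and a fixed Tm cutoff; it is a descriptive join, not a
calibrated test of association.
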