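# Methods

## The problem

RT-qPCR quantifies a target transcript *relative* to one or more reference
("housekeeping") genes, assuming the references are constitutively
expressed.  In developing brain tissue that assumption routinely fails:
common references (Actb, Gapdh, Ywhaz, ...) drift with postnatal age or
respond to experimental treatment, and a drifting reference silently
distorts every fold change normalised to it.  refstab implements the
standard remedy: score a panel of candidate references with four
independent stability algorithms, aggregate them into a consensus index,
select references by an explicit two-stage rule, and only then quantify
targets by 2^−ΔΔCt.

## Replicate QC

Technical replicates of one (sample, gene) reaction are collapsed to their
arithmetic mean Cq.  A cell is retained only if it has ≥ 2 replicates and
their sample standard deviation (n−1 denominator) is ≤ `max_sd` (default
0.35 cycles).  Exclusion is per cell, not per sample: one bad assay does
not discard a sample's other genes (both views are logged).  Under
replicate noise σ_rep, the exclusion probability is
P(S₄ > max_sd) with (n−1)S²/σ_rep² ~ χ²₃; the test suite checks the
pipeline's empirical rate against a 10⁶-draw Monte-Carlo evaluation of
that quantity.

## Stability algorithms

All four score with the same orientation — lower = more stable — but on
different scales, which is why they are aggregated by rank, never by raw
score.

**geNorm.** On linear relative quantities
q(g,i) = E^(min_i Cq(g) − Cq(g,i)) (E = amplification factor per cycle,
default 2.0), the pairwise variation of genes g,h is
V(g,h) = SD_i[log2 q(g,i)/q(h,i)], and M(g) is the mean of V(g,·) over the
other genes.  The gene with the largest M is removed and M recomputed
until two genes remain.  A gene's reported score is its M in the round of
its elimination; genes alive in the last computed round (which has three
genes) keep that round's M, so the surviving pair shares the last
recomputed value rather than their pairwise V.  Ties break by panel
order.

**NormFinder (ungrouped).** On y = log2 q, the additive model
gene-effect + sample-effect is removed by double centering; with G genes
and n samples the per-gene variance estimate is
s²(g) = Σ_i r(g,i)² · G / ((G−1)(n−1)) and ρ(g) = √max(0, s²).  This is
the homoscedastic small-sample correction; the grouped inter/intra-group
decomposition is out of scope.  Because sample centering removes any
per-sample loading offset, ρ estimates the gene's own biological SD in
log2 units — the parameter-recovery tests exploit exactly this.

**BestKeeper.** On raw Cq: dispersion(g) = mean |Cq(g,i) − GM(g)| around
the gene's geometric-mean Cq (the original tool's convention; classical
n−1 SD behind `use_sd=True`), CV = dispersion/GM × 100, plus the Pearson
correlation of each gene with the per-sample geometric-mean index as a
diagnostic.  Note BestKeeper rewards low absolute Cq scatter, so a flat
but biologically unrelated gene can outrank a co-regulated pair — the toy
fixture demonstrates this disagreement deliberately.

**Comparative ΔCt.** score(g) = mean over partners h of
SD_i[Cq(g,i) − Cq(h,i)].  At E = 2 this is algebraically identical to the
geNorm first-round M (log2 quantity ratios equal negated Cq differences);
the suite verifies the identity to 1e−9 on random matrices.

## Consensus and selection

Each method's scores become ascending average ranks (ties share the mean
position, so rank sums are conserved at G(G+1)/2).  The comprehensive
stability index is the geometric mean of a gene's four ranks; it lies in
[1, G] and is monotone in every method's rank.

Stage 1 (screening): with the maximum achievable index equal to G, genes
with index strictly greater than `fraction × G` (default 0.75, giving 6
for an 8-gene panel) are excluded; a gene exactly at the threshold
survives.  Stage 2 (confirmation): over a structure's analysis subsets —
each single age plus all ages pooled, four subsets by default — a gene is
declared stable iff its index is ≤ `max_index` (default 3, inclusive) in
at least `min_instances` (default 3) subsets.  The inclusive/strict
boundary conventions are chosen so that a boundary gene survives both
stages.

## Expression analysis

ΔCt(i) = Cq_target(i) − mean_ref Cq(i); the arithmetic mean of reference
Cq equals geometric-mean normalisation on the linear scale at a common
efficiency.  ΔΔCt subtracts the mean ΔCt of the calibrator cell (default:
intact group at the earliest age), and fold = 2^−ΔΔCt, so the
calibrator's geometric-mean fold is exactly 1.  Per group × age cell,
fold values outside the Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
(quartiles by linear interpolation of order statistics) are flagged and
excluded from inference; cells with < 4 values pass through unfiltered
with a warning.

Inference runs on log2 fold change by default (raw behind a flag; the
scale is recorded in every report): two-way ANOVA
(group × age, interaction, Type-III sums of squares with sum-to-zero
coding — appropriate for the unbalanced cells outlier exclusion creates),
then pairwise contrasts — between groups within each age and between ages
within each group — as t-tests on cell means with the full model's pooled
residual variance, Sidak-adjusted with family size m = the number of
contrasts actually computed (reported alongside).  Shapiro–Wilk per cell
(n ≥ 3) and Levene across cells (center = mean) are computed as advisory
diagnostics; the pipeline never branches on them.

## The synthetic generator

Cq(g,i,r) = μ_g + L_i + δ(g, age_i) + γ(g, group_i) + b(g,i) + e(g,i,r),
with L_i ~ N(0, τ²) a per-sample loading offset shared by all genes,
b ~ N(0, σ_g²) biological noise, e ~ N(0, σ_rep²) technical noise, and
deterministic age/group effects in cycles (negative = higher expression).
Normal noise on the Cq (log) scale is the standard qPCR error model; an
optional contamination mode inflates a fraction of biological deviations
(`outlier_fraction`, `outlier_scale`) to exercise the quartile filter.
Defaults: τ = 0.4, σ_g = 0.25, σ_rep = 0.12 cycles, quadruplicates,
3 groups × 3 ages, 8 candidate references + 1 target, one structure per
call (multi-structure data are independent concatenations).  Per-cell n
defaults to 8; the real study this design mirrors does not print per-cell
counts, so no default claims to match them.

Ground truth (`SimTruth`) records each gene's total instability —
biological SD combined in quadrature with the design-level SD of its
injected effects — and the target's true fold profile, sufficient to
score any downstream ranking or fold estimate.

The named `developmental_scenario` has five stable candidates
(σ = 0.25), two age-drifting ones (Actb down 1 cycle by P50, Ywhaz up
1 cycle), one treatment-responsive one (B2m, +0.8 cycles in the FS
group), and a target (S100b) stepping up 2-fold from P21 onward.  The
drifting genes also carry elevated biological noise (σ = 0.7): an age
trend is constant within a single-age analysis subset and therefore
invisible to three of the four subsets, so drift alone could never fail
the 3-of-4 selection rule; giving developmentally regulated genes higher
between-animal variability is both realistic and what makes the
end-to-end selection property well-posed.

## What passing tests do and do not show

The generator reproduces the variance structure the algorithms assume —
shared loading offsets, gene-specific Gaussian noise, additive design
effects.  It does not simulate amplification-efficiency differences
between assays, inter-plate effects, litter/cage hierarchies, or
fluorescence-level artefacts; passing tests therefore validate the
arithmetic and the selection logic, not robustness to those real-data
complications.  Reported figures: parameter recovery uses n = 100 samples
× 50 seeds (consensus Spearman vs truth ≥ 0.8) and n = 200 × 50 reps
(NormFinder ρ̂ within 10% of σ); the selection protocol uses the scenario
at n = 30 per cell × 25 seeds; reference-sensitivity uses 50 reps at
n = 30.  On the sensitivity check, the drifting-reference bias equals the
injected drift only in expectation, so the test brackets the estimate
within 15% of the predicted biased value rather than asserting a strict
inequality on a noisy quantity.

## Numerical conventions

All SDs use the n−1 denominator.  Scores are reported to 4 decimals in
output files; internal comparisons are float64 with absolute tolerances
stated per test.  Quartiles are linear-interpolation (type-7) order
statistics.  Ranks of exact ties are averaged.  geNorm elimination ties
break by panel order, making every pipeline stage deterministic for a
fixed input; simulation is reproducible bit-for-bit from the seed.
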