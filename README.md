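# refstab

Reference-gene stability screening and relative quantification for
RT-qPCR Cq data.

Quantifying a transcript by RT-qPCR means normalising it to reference
("housekeeping") genes — and in developing or treated tissue the usual
references are often anything but stable.  refstab implements the full
selection-then-quantification workflow used in developmental
neuroscience qPCR studies:

1. **Replicate QC** — technical replicates are collapsed to mean Cq;
   cells whose replicate SD exceeds 0.35 cycles are excluded (per cell,
   with full provenance).
2. **Four stability algorithms** — geNorm M (iterative elimination on
   pairwise log-ratio SDs), ungrouped NormFinder ρ (model-based residual
   SD), BestKeeper dispersion (MAD around the geometric-mean Cq), and the
   comparative ΔCt method.  Lower always means more stable.
3. **Consensus ranking** — per-method ranks (ties averaged) are combined
   into the comprehensive stability index, the geometric mean of the four
   ranks, index(g) = (r₁r₂r₃r₄)^¼ ∈ [1, G].
4. **Two-stage selection** — screening drops genes whose index exceeds
   75% of the maximum achievable index (6 for an 8-gene panel); a gene is
   then confirmed stable only if its index is ≤ 3 in at least 3 of the 4
   per-structure analysis subsets (each age separately, plus all ages).
5. **Expression analysis** — 2^−ΔΔCt fold changes of a target against the
   selected references (arithmetic-mean Cq of the reference set ≡
   geometric-mean normalisation), Tukey-fence outlier exclusion, two-way
   ANOVA (Type-III) with Sidak-adjusted pairwise contrasts, and
   Shapiro–Wilk / Levene diagnostics.
6. **Synthetic data** — a generator for Cq datasets with known ground
   truth (`Cq = μ_g + loading + age/group effects + biological +
   technical noise`), so every stage above is testable without access to
   instrument data.

See `docs/methods.md` for the model details and conventions.

## Worked example

Generate a synthetic study (5 stable reference candidates, 2 age-drifting
ones, 1 treatment-responsive one, and a target that doubles from P21
onward), then run the whole workflow:

```sh
refstab simulate --scenario developmental --n 8 --seed 5 --out-dir run/sim
refstab stability --measurements run/sim/measurements.csv \
    --annotations run/sim/annotations.csv --structure DH \
    --genes Actb,Gapdh,B2m,Rpl13a,Ppia,Hprt1,Pgk1,Ywhaz \
    --out-dir run/stab
refstab select  --consensus-json run/stab/consensus.json --out-dir run/sel
refstab express --measurements run/sim/measurements.csv \
    --annotations run/sim/annotations.csv --structure DH \
    --target S100b --refs auto --selection-json run/sel/selection.json \
    --out-dir run/expr
```

The all-ages consensus table (`run/stab/consensus_DH_all.tsv`) ranks the
quiet genes at the top and pushes the drifting/responsive ones
(Actb, Ywhaz, B2m) to the bottom:

```
gene    genorm  normfinder  bestkeeper  delta_ct  index
Gapdh   1.0     1.0         4.0         1.0       1.4142
Hprt1   2.0     4.0         1.0         3.0       2.2134
Ppia    3.0     2.0         3.0         2.0       2.4495
Rpl13a  4.0     3.0         2.0         4.0       3.1302
Pgk1    5.0     5.0         5.0         5.0       5.0
B2m     6.0     6.0         6.0         6.0       6.0
Actb    7.0     7.0         7.0         7.0       7.0
Ywhaz   8.0     8.0         8.0         8.0       8.0
```

The selection report applies the index ≤ 3 in ≥ 3-of-4-subsets rule and
keeps only genuinely stable candidates (`stable genes: ['Gapdh',
'Hprt1', 'Ppia', 'Rpl13a']`), which `express --refs auto` then uses for
normalisation.  The resulting ANOVA on log2 fold change of S100b
(`run/expr/anova_S100b.tsv`):

```
effect     sum_sq     df   F          p
group      0.137535   2.0  0.591606   0.556531
age        17.545688  2.0  75.472525  0.0
group:age  0.868773   4.0  1.868506   0.127243
residual   7.206812   62.0
```

The injected 2-fold step at P21 surfaces as an overwhelming age effect;
group and interaction stay at noise level, exactly as simulated.  Had a
drifting gene (e.g. Actb) been used as the reference instead, the age
effect would have been cancelled by the reference's own 1-cycle drift —
the test suite demonstrates this sensitivity quantitatively.

The same functionality is available as a library
(`refstab.cq_data`, `refstab.stability`, `refstab.consensus`,
`refstab.expression`, `refstab.simulate`).

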