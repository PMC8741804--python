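# Methods

This note documents the statistical models, conventions and design choices
behind `refstab`, in the order data flows through the package.

## Ct data model and I/O

A Ct (quantification cycle) value is the PCR cycle at which a reaction's
fluorescence crosses threshold; lower Ct means more template, and at 100 %
amplification efficiency one cycle corresponds to a twofold abundance
change. The package treats a Ct matrix as genes × samples (optionally
× technical replicates) of finite, strictly positive cycle values, with an
optional sample → group map (e.g. tissue zones).

Technical replicates are collapsed by the arithmetic mean of Ct — the
convention the downstream stability tools assume — with the per-cell
replicate SD (ddof = 1) reported for QC. No replicate-outlier rule is
applied before averaging. Replicate counts must be equal across cells;
ragged designs are rejected rather than padded, because every downstream
algorithm requires a complete matrix. Missing Ct values are rejected by
default naming the offending cell; the explicit `drop_sample` policy
instead removes every sample containing a missing value, so geNorm and
BestKeeper always see complete data. Delimiters are auto-detected among
comma and tab; decimal points only.

## Standard curves

Efficiency is estimated by ordinary least squares of mean Ct on log₁₀
relative input over a serial dilution (≥ 3 points, fivefold steps by
default), with

    E = (10^(−1/slope) − 1) × 100 %.

R² is the squared Pearson correlation of the fit, not adjusted R². The
quantity axis is relative (most concentrated point at 0); only input
ratios matter for the slope. A non-negative slope yields a flagged fit
with efficiency marked invalid instead of an exception, so assay batches
can be screened. On noise-free simulated series the fit inverts the
generator to below 1e−9 percentage points for E anywhere in (50, 150).

## geNorm

Relative quantities are Q_ij = (1+E_i/100)^(Ctmin_i − Ct_ij); the default
E = 100 % (Q = 2^(Ctmin − Ct)) matches the 2^−ΔΔCt convention used for
quantification, and per-gene efficiencies from the standard-curve module
may be supplied instead. The pairwise variation of genes j,k is the
SD over samples (ddof = 1) of log₂(Q_j/Q_k); M_j is the mean over all
partners. Because common per-sample shifts cancel in every ratio, M is
invariant to loading differences — verified to machine precision.

Stepwise ranking removes the gene with the highest M (ties broken by
input order), recomputes on the remainder, and stops at two genes, which
are reported as a tied rank-1 pair (ratios cannot separate them). Each
gene's reported M is its value at the step of exclusion; the final pair
share their two-gene M. V(n/n+1) is the SD over samples of the log₂ ratio
of normalization factors (geometric means of quantities) built from the
n and n+1 most stable genes; the conventional advisory cutoff V < 0.15
selects the recommended reference count, and the advisory M < 1.5 cutoff
is surfaced as an annotation, never a filter. A two-gene panel returns
the pair's single V as M for both, with a warning. At least three genes
are required for the stepwise procedure.

## NormFinder

Work on y = −Ct (a log₂ quantity up to sign and offset). The model is

    y_igj = μ_i + d_ig + β_gj + ε_igj,  Var(ε_igj) = σ²_ig,

with β a per-sample template effect and d_ig the gene × group interaction
— the systematic bias a poor reference introduces between groups.

*Intra-group variances.* Within each group, residuals remove gene and
sample means. The naive residual mean square m_i then mixes variances:
E[m_i] = (1 − 2/I)σ²_i + (1/I²)Σ_k σ²_k for I genes. Solving this moment
system gives the corrected estimates; negative solutions (possible at
small n) are clamped to zero with a warning.

*Inter-group deviations.* d̂_ig is the two-way-centered gene × group mean.
The centering across genes embodies the identifiability assumption that
the panel's deviations roughly balance; a panel whose genes all shift the
same direction confounds d with the group means. Each d̂ is shrunk toward
zero by γ²/(γ² + σ²_ig/n_g), where γ² is the method-of-moments estimate
of the true inter-group variance — deviations supported by little data
are discounted.

*Stability value.* ρ_i = mean over groups of |d̃_ig| + mean over groups
of σ̂_ig. Both terms are on the cycle (log₂) scale, so systematic bias
and random noise contribute commensurably; using the standard error
σ̂/√n_g for the second term instead would let intra-group noise vanish
with sample size and decouple the ranking from a gene's actual
variability. Ungrouped mode fits the same two-way model to the whole
matrix and returns σ̂_i alone. Grouped mode requires ≥ 2 groups with ≥ 2
samples each; ungrouped requires ≥ 3 samples; both require ≥ 3 genes (the
moment correction is singular at I = 2).

## BestKeeper

Per-gene descriptives are computed on the raw Ct scale: geometric mean,
arithmetic mean, min, max, dispersion, CV% = 100·SD/AM. The dispersion
column is the classical sample SD (ddof = 1) by default, with a switch to
the mean absolute deviation from the geometric mean (the original
spreadsheet tool's convention); published tables labelled "standard
deviation" cannot disambiguate the two, so the label is taken at face
value. The BestKeeper index is the per-sample geometric mean of all
candidates' Ct (no iterative exclusion), and each gene is scored by the
Pearson r of its Ct with the index, ranked descending. A zero-variance
gene has undefined r and is flagged not-rankable; policy decides whether
that raises or assigns the last rank.

BestKeeper's r rewards genes that track the panel-wide signal. When
common per-sample variation dominates — the regime real Ct series show,
with index correlations of 0.96–0.99 — an unstable gene decorrelates from
the index and ranks low. When common variation is absent, a dominant
noisy gene *drives* the index and earns the highest r; this inversion is
a known artifact of the method, not of this implementation, and the
validation suite therefore exercises the realistic common-variation
regime (sample-shift SD 1.5 cycles).

## Consensus ranking

Each algorithm's metric is converted to dense ranks: sorted in the stable
direction, exactly tied values share a rank, and the next distinct value
receives the previous rank + 1 — so geNorm's tied top pair is followed by
rank 2. Dense ranking is the only convention under which a tied pair at
position 1 combines with single ranks from the other two algorithms into
the familiar one-decimal consensus values (a competition-ranking
convention would shift every subsequent gene by one). The consensus is
the arithmetic mean of the three ranks, kept at full precision for
ordering and displayed to one decimal with half-up rounding
(5/3 → 1.7, 10/3 → 3.3). Consensus ties break by geNorm rank, then input
order. Geometric-mean aggregation is deliberately not offered.

## 2^−ΔΔCt quantification

The per-sample reference factor is the arithmetic mean Ct of the selected
reference genes — algebraically the geometric mean of their 2^−Ct
quantities under a common efficiency. ΔCt subtracts the factor from the
target's Ct; ΔΔCt subtracts the calibrator's ΔCt (a sample, or a group's
mean ΔCt); fold change is 2^−ΔΔCt. Efficiency is fixed at 100 %;
efficiency-corrected (Pfaffl-type) quantification is out of scope. Fold
changes are invariant to per-sample loading shifts, multiplicative under
chained calibrators, and exactly 1 at a sample calibrator.

## Expression analysis

Candidate screening retains genes with group-mean abundance ≥ 5 (FPKM) in
every tissue, max pairwise fold change < 2, and q ≥ 0.05 in every
comparison. z-scores standardize each gene row to mean 0, SD 1 using the
sample SD (ddof = 1; population convention available); zero-variance rows
map to zeros with a flag. K-means uses Lloyd's algorithm with k-means++
seeding, best of 10 restarts by inertia, deterministic per seed, with
cluster ids relabeled in order of first appearance; defaults are k = 12
for RNA-seq panels and k = 6 for qPCR panels. The DE filter enumerates
all pairwise group comparisons (6 for 4 tissues), computes the
direction-agnostic ratio of group means on the linear scale, tests each
comparison with a two-sided Welch t on log₂ values, and reports a one-way
ANOVA per gene; a call passes iff fold > 2 and p < 0.05. Pairwise p
values are not multiple-testing corrected by default (matching the
thresholds as stated); the statistical test behind upstream RNA-seq
pipelines varies, so Welch-t/ANOVA is the documented stand-in.

## Synthetic data

The generator draws Ct directly on the cycle scale:

    Ct_igr = μ_i + δ_ig + s_j + e_ij + ε_r,
    e_ij ~ N(0, σ_i),  ε_r ~ N(0, σ_rep),

which is exactly the structure the three algorithms consume (all operate
on Ct or quantities log-linear in Ct). The default panel emulates a
screening study design: 12 genes, 4 tissue groups × 3 biological samples,
3 technical replicates; baselines uniform on 18–30 cycles (the mid-Ct
range of moderately expressed housekeeping genes), intra-group SDs graded
0.2–2.0 cycles so the panel spans clearly stable to clearly unstable
candidates, inter-group shift SDs graded 0–1.5 cycles, common sample
shifts N(0, 0.3), replicate noise SD 0.1. The truth object records the
parameters and the implied ideal ordering by total perturbation
σ²_i + Var_g(δ_ig).

`graded_panel_params` provides the two-group recovery design used for
validation: intra-group SD and inter-group shift magnitude jointly graded
per gene (0.1–1.5 and 0–1.6 cycles), shift signs random so panel
deviations balance, and 16 samples per group — sized so the sampling
error of a per-gene variance estimate (≈ σ²√(2/(n−1)) ≈ 0.37 σ² at
n = 16) resolves adjacent grades, making rank recovery a meaningful test.

What the generator does *not* emulate: PCR kinetics (no per-cycle
amplification curves, no Cq-calling artifacts), inter-run batch effects,
co-regulation between genes beyond the shared sample shift, non-Gaussian
heavy-tailed noise, and missingness. Passing tests on this model show the
algorithms recover the variance structure they assume; they do not show
robustness to assay-level artifacts real data may contain.

## Validation problem sizes

The test suite validates against independent brute-force oracles on
1000 random 4×6 matrices (geNorm) and 1000 random 5×10 matrices
(BestKeeper); 100 constructed co-regulated pairs; 100 graded two-group
simulations for NormFinder recovery (Spearman ≥ 0.9 required in ≥ 90);
100-seed recovery checks for ΔΔCt (planted 8-fold) and efficiency; a
1000-gene null panel for DE error control; and byte-level determinism of
two identically seeded pipeline runs. The whole suite runs in well under
a minute on one CPU.

## Known limitations

* NormFinder's moment correction is noisy for small panels (I close to
  3) and small groups; clamped-to-zero variance estimates are flagged but
  still enter the ranking.
* geNorm cannot separate perfectly co-regulated genes (reported tied);
  co-regulated *sets* larger than two can mask shared instability for all
  three algorithms.
* The BestKeeper r ranking inverts in data without common variation (see
  above); inspect the descriptive SD/CV columns alongside r.
* The DE filter assumes log-scale normality within groups; with 3
  replicates per group the Welch test is approximate.
* Efficiency is assumed 100 % in quantification and (by default) in
  geNorm quantities; supply per-gene efficiencies where assays deviate
  substantially.
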