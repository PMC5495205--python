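# Methods

`refstab` implements the standard reference-gene selection workflow for
qPCR experiments: four expression-stability algorithms, a geometric-mean
consensus, the pairwise-variation rule for how many reference genes a
normalization needs, standard-curve efficiency QC, and 2^−ΔΔCq target-gene
quantification with a Mann–Whitney validation step.  This note records the
models, the numerical conventions, and the design choices that were
genuinely open.

## Data model and scales

All analysis starts from quantification cycles (Cq).  Technical replicates
are collapsed by their **arithmetic mean on the Cq scale**, which equals
the geometric mean on the quantity scale — the natural average for an
exponential process.  Replicate sets whose range exceeds `max_spread`
(default 0.5 cycles, a common plate-QC convention) are flagged but kept;
nothing is ever imputed, and the stability algorithms refuse incomplete
matrices (`require_complete` either fails or drops offending samples,
logged).  Accepted Cq must lie in (0, 45], bracketing the 10–36 cycle range
typical of mixed rRNA/mRNA panels.

geNorm and NormFinder operate on **log2 relative quantities**

    value(i, s) = (min_s' Cq(i, s') − Cq(i, s)) · log2(1 + E_i),

with per-gene efficiency E_i = 1 unless efficiency correction is switched
on.  Referencing each gene to its own minimum Cq makes the most expressed
sample quantity 1; the per-gene constant cancels in every dispersion
statistic, so the choice is purely numerical hygiene.  BestKeeper and the
comparative ΔCt method operate on raw Cq, as originally defined.  All
standard deviations throughout use the n−1 denominator.

## The four stability algorithms

**geNorm.**  M_j is the mean over partners k≠j of SD across samples of
(value_j − value_k).  Ranking is stepwise: recompute M on the remaining
panel, drop the argmax, repeat until two genes remain; the final pair is
unrankable by construction and shares rank 1.5.  Ties in the argmax are
broken lexicographically and logged (probability zero on real data).
Normalization factors NF_n are per-sample geometric means of the n most
stable genes' quantities; V_n/n+1 = SD_samples(log2(NF_n/NF_n+1)); the
recommended count is the smallest n ≥ 2 with V < 0.15 (never 1 — a single
reference cannot be validated by this rule), "undetermined" with an
all-genes advisory if no n qualifies.  Genes with full-panel M ≥ 1.5 are
flagged in reports but not removed.

**Comparative ΔCt.**  Stability = mean over partners of SD of the
per-sample Cq difference, pooled across groups.  On raw Cq this is
*identical* to full-panel geNorm M at E = 1 (value differences are negated
Cq differences plus constants), and the test suite asserts equality to
1e−10 — the two implementations serve as mutual oracles.

**NormFinder.**  A variance-decomposition estimator on log2 quantities
y_igj (gene i, group g, sample j).  Per-sample loading is removed by
centering on the gene mean (d_igj = y_igj − ȳ·gj); per gene/group means
m_ig and variances s²_ig of the centered values follow.  Because centering
couples genes, the intragroup variance is de-biased as

    σ̂²_ig = max(0, K/(K−2) · (s²_ig − (1/K²) Σ_i' s²_i'g)),

requiring K ≥ 3 genes.  Inter-group bias a_ig = m_ig − mean_g m_ig has
variance component τ̂²_i = max(0, var_g(a_ig) − mean_g(σ̂²_ig/n_g)) and
shrunken bias ã_ig = a_ig·τ̂²/(τ̂² + σ̂²/n_g).  The stability value

    ρ_i = mean_g( |ã_ig| + sqrt( τ̂²·(σ̂²_ig/n_g) / (τ̂² + σ̂²_ig/n_g) ) )

combines bias and noise; lower is more stable.  With one group ρ reduces
to the intragroup SD.  The centering correction plugs Σ s² in for the
(unobservable) Σ σ² — an O(1/K) approximation; correctness is certified by
recovery tests (seed-averaged σ̂² within 10 % of truth at n_g = 50,
correlation > 0.99 with the generative σ², a 1-cycle group-shifted gene
ranked least stable in ≥ 95/100 runs), not by matching any published table.
The original tool's best-two-gene combination output is out of scope; the
consensus uses single-gene ρ ranks.

**BestKeeper.**  Descriptive dispersion of raw Cq per gene — mean absolute
deviation from the mean by default (the original tool's "SD [±Cq]"
column), sample SD by config — plus the Pearson correlation (two-sided p
via the t transform, n−2 df) of each gene against the BestKeeper index,
the per-sample geometric mean of all candidates' Cq.  Ranking is by
ascending dispersion; dispersion > 1 cycle flags a gene "inconsistent"
without removing it.  Whether to rank by dispersion or by r is genuinely
ambiguous in practice; dispersion is the default and is recorded in the
report metadata.

## Consensus

Per-method ranks (average ranks on ties; geNorm's final pair enters as
1.5/1.5) are combined by geometric mean, weighting methods equally; final
ties break lexicographically so output is deterministic.  Methods a run
cannot produce (e.g. NormFinder on a 2-gene panel) are omitted and listed
in `methods_used`.

## Efficiency QC

Ten-fold dilution series are fit by OLS of Cq on log10 input;
E% = 100·(10^(−1/slope) − 1), so slope −3.3219 is perfect doubling.
Replicated points are averaged before regression.  Default gates:
R² ≥ 0.99 and E within 90–110 %, a window wide enough for well-behaved
assays (typically ~98–110 %) and conventional in the field.  A
non-negative slope is reported as non-amplifying and never acceptable.

## 2^−ΔΔCq quantification and validation

ΔCq = Cq_target − mean(Cq over the reference set) per sample (arithmetic
mean of reference Cq = geometric mean of reference quantities at E = 1);
ΔΔCq subtracts the calibrator-group mean ΔCq, making the calibrator's mean
log2 fold exactly 0; fold = 2^−ΔΔCq.  Efficiency-corrected (Pfaffl-style)
ratios are out of scope.  Two algebraic properties anchor the tests: folds
are invariant to per-sample loading constants, and a single reference gene
carrying a δ-cycle shift in the test group biases the target's log2 fold
by exactly +δ — the mechanism by which an unstable reference distorts
downstream biology.

Validation compares per-replicate qPCR folds with external per-replicate
estimates by a two-sided Mann–Whitney U test: exact p by full enumeration
of all C(n1+n2, n1) assignments (average ranks for ties) when n1+n2 ≤ 16,
else the tie-corrected normal approximation with 0.5 continuity
correction.  Enumeration over every achievable U at n1 = n2 = 8 bounds the
approximation error at 0.011 (worst near p ≈ 0.44; far smaller in the
tails where decisions happen).  With 3 + 3 replicates the smallest exact
two-sided p is 2/20 = 0.1, so no 3-replicate contrast can reach p < 0.05 —
significance annotations at 0.05/0.01 are labels, not decisions.

## Synthetic data generator

The generator emulates the design of a multi-stage fungal qPCR study
because raw Cq tables are rarely deposited:

    Cq_igjr = baseline_i + δ_ig + b_gj + ε_igj + η_igjr,

with loading effect b_gj ~ N(0, σ_sample²) shared by all genes of a
biological sample, biological noise ε ~ N(0, σ_bio,i²), technical noise
η ~ N(0, σ_tech²) — Gaussian on the Cq scale, i.e. log-normal abundance,
the implicit assumption of all four algorithms.  Noise terms are always
drawn even at σ = 0 so runs differing in one σ share the remaining random
numbers (common-random-number testing of cancellation properties).  Genes
of interest carry known per-group log2 folds (fold f lowers Cq by log2 f).

The `fungal-dev` preset fixes the study conditions: 13 candidates over 4
developmental stages × 3 biological × 3 technical replicates, baselines
10.5–30 cycles (abundant rRNAs low-Cq, scarce enzymes high-Cq), σ_sample
0.15, σ_tech 0.10.  Two genes (ACT1, 18S) are designed ultra-stable
(σ_bio 0.05, no stage shifts), a middle field has σ_bio 0.25–0.40 with
small shifts, and the tail ends at HISTH4 (σ_bio 0.55, shifts to 1.8
cycles) — graded so that recovery of the designed ranking is a meaningful
end-to-end test at realistic replicate counts.  Two targets, CDC25
(up-regulated to 8-fold) and CHI1 (down to 0.25-fold), validate the ΔΔCq
path against the generative truth.  The exported `SimTruth` includes a
composite instability score (mean |shift deviation| + σ_bio) used only for
ordering assertions; it is not claimed to equal any method's statistic.

What the generator does *not* emulate: PCR inhibitors and outlier wells,
amplification-curve shape, between-plate batch effects, non-Gaussian
dropout near the detection limit.  Passing tests therefore demonstrate
correctness of the algorithms under their own model assumptions, not
robustness to every artefact of real plates.

## Problem sizes and determinism

Simulation-based checks use 20–100 seeds at the study's own replicate
counts (12 biological samples), chosen so the whole suite runs in well
under a minute while the Monte-Carlo assertions retain comfortable
margins (e.g. the designed stable pair tops the consensus in ~96 % of
runs over a 400-seed census).  Every random draw funnels through one
`numpy` generator seeded from the run configuration, so all outputs —
CSVs included — are byte-identical under a fixed seed.

## Known limitations

- NormFinder's two-gene combination recommendation is not implemented.
- BestKeeper's sequential index refinement and per-gene regression
  diagnostics are not implemented.
- Efficiency-corrected ΔΔCq (per-gene E in the fold computation) is
  supported for the expression matrix but not for the ΔΔCq path.
- The exact Mann–Whitney enumeration is O(C(n1+n2, n1)) and is capped at
  n1+n2 = 16 by the auto mode.
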