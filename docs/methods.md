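# Methods

This note documents the statistical procedures the package implements,
the design decisions taken where the protocol leaves choices open, and
what the synthetic-data study does and does not establish.

## Co-expression network construction

Input is a genes × samples expression compendium on a log2-like additive
scale (microarray-style), annotated per sample with an immune cell type
(T, B, NK, monocyte, dendritic in the motivating application) and an
activation/differentiation state.

1. **Genome-wide screen.** A one-way fixed-effects ANOVA per gene across
   the cell-type × state design strata, Benjamini–Hochberg corrected;
   genes with q < 0.01 are candidates. The grouping factor is the finest
   design stratum because it subsumes both between- and within-cell-type
   regulation; the protocol does not name the factor explicitly, and this
   is the one choice that covers both contrast families with a single
   screen. Genes constant in every sample have an undefined F (0/0) and
   are assigned p = 1 with a warning; genes with between-group signal and
   zero residual variance get p = 0.
2. **Within-cell-type correlation.** For each cell type separately, all
   candidate pairs are tested for Pearson correlation on that cell
   type's samples, with the two-sided p from t = r·√((n−2)/(1−r²)) on
   n−2 df. BH correction is applied within each cell type over all
   tested pairs (correlations are computed separately per cell type, so
   the testing family is per cell type as well; whether the original
   analysis corrected per cell type or globally is not stated). An edge
   is kept iff **r > 0.9 and q < 0.01**. The threshold is signed:
   strongly anti-correlated pairs are not edges. Pairs involving a
   zero-variance gene are skipped and never enter the BH family.
3. A gene belongs to a network only via at least one retained edge;
   cell types with no retained edge yield no network (with a warning),
   mirroring cell populations for which the protocol produces nothing.

## Overlap accounting and the specificity filter

Membership is defined by network node sets. The unique-overlap matrix
counts genes in exactly one network on the diagonal and genes in exactly
one pair of networks off the diagonal; genes in three or more networks
contribute to no cell. The specificity filter keeps genes present in at
most two networks — the working definition of a cell-type-attributable
signal. Mean degree is reported as 2E/V.

## Focus networks

The specificity-filtered genes of one cell type are projected onto a
reference functional network (HumanNet-style edge list). Functional
coherence is assessed with a **degree-preserving permutation filter**:
candidate labels are redrawn uniformly within degree quintiles of the
reference node set (controlling for hub bias), a candidate's null
distribution pools the induced degrees of same-stratum members of the
permuted sets, and its empirical p-value is
(1 + #{null ≥ observed})/(1 + #null). BH across candidates; nodes with
q < 0.05 are retained together with the induced edges among them.

This filter deliberately has the same interface and output formats
(SIF + node attribute tables) as the published network-coherence
algorithm used in the motivating study, so a run of that external tool
can be slotted into the pipeline; its internals are not re-derived here.
Clusters are the connected components of the retained subgraph
(singletons dropped) — layout-based cluster boundaries are not
algorithmically specified anywhere, and components are the only
reproducible choice. Each cluster is annotated by hypergeometric
upper-tail enrichment of gene → term annotations against the full
expressed background, BH-corrected per cluster (q < 0.05).

## Response differential expression

Treatment cohorts are FPKM/TPM-like matrices with RECIST labels.
CR/PR → response, PD → non-response, SD excluded (SD columns are kept in
matrix exports for display but never tested). Genes must exceed a count
of 1 in at least 25% of samples (boundary inclusive) to be tested.
Each gene gets a two-sided Mann–Whitney U between the classes — exact
when the smaller group has ≤ 8 samples and there are no ties,
tie-corrected normal approximation otherwise (cohort sizes of 6–18 per
class straddle exact feasibility) — BH across genes, and a linear-scale
fold change (mean_response + ε)/(mean_non-response + ε) with ε = 0.01
because FPKM/TPM inputs contain zeros (the scale on which the original
fold changes were computed is unstated; linear-scale means are used
throughout). A gene passes at **q < 0.05 and ≥ 2-fold in either
direction**.

Passing genes are Blom-transformed per gene,
z = Φ⁻¹((rank − 3/8)/(n + 1/4)) with mean ranks for ties, before
agglomerative hierarchical clustering with Euclidean distance. Linkage
is **complete** — only the distance is prescribed by the protocol; complete
linkage produces compact display blocks and the choice is switchable.

Validation intersects discovery- and validation-cohort pass lists.
Genes validating with the opposite direction of effect are **retained
but flagged discordant** (platform or splice-variant effects can flip an
apparent direction without invalidating the gene).

## Survival evaluation

* **Stage coding:** I/Ia/Ib/Ic → 1, II* → 2, III* → 3, IV → 4,
  case-insensitive; anything else is an error naming the label.
* **Univariate screen:** per gene, a 1-D Gaussian mixture is fitted by
  EM for K = 1..5 with 10 seeded restarts; K minimises BIC; patients are
  assigned to maximum-responsibility components and compared with a
  (K−1)-df log-rank test. Groups are not forced to two: when K > 2 all
  components enter the test. Unstratifiable genes (K = 1 or zero
  variance) enter the BH family with p = 1, which keeps panel-level
  q-values conservative.
* **Splitting:** train/validation splits are random within stage strata
  at a global fraction (default 255/390), so stage proportions are held
  constant; per-stratum sizes are deterministic, membership depends on
  the seed.
* **Cox modelling:** partial-likelihood maximisation with **Efron tie
  handling** (the only tie method lifelines implements; with continuous
  simulated times, ties are measure-zero anyway). AIC = 2k − 2·logPL.
  Backwards stepwise elimination drops, at each step, the covariate
  whose removal lowers AIC most, stopping when no removal lowers AIC;
  age and stage can be configured as never-drop. The returned model's
  AIC never exceeds the full model's. Note the procedure's intrinsic
  operating characteristic: a 1-df null covariate is eliminated iff its
  LR statistic is below 2, so the long-run elimination rate for pure
  noise is P(χ²₁ < 2) ≈ 0.843, not 1.
* **Proportional-hazards diagnostic:** the Grambsch–Therneau test on
  scaled Schoenfeld residuals against a Kaplan–Meier transform of time
  (left-continuous at event times). With d events, centred transform g,
  Schoenfeld residual matrix r and coefficient covariance V, the global
  statistic is d·u'Vu/Σg² with u = Σ gₖ rₖ (χ² on p df); per-covariate
  statistics are d·(Vu)ⱼ²/(Vⱼⱼ·Σg²) (χ² on 1 df), so a single-covariate
  model's global and per-covariate tests coincide. Per-covariate values
  are cross-checked against lifelines' implementation in the tests.
* **Risk groups:** the threshold is the median linear predictor of the
  training cohort, boundary ties going to the high-risk side; an
  odd-sized training set of 255 distinct scores splits 128/127. The
  threshold is transported unchanged to held-out data and groups are
  compared by log-rank.

## Synthetic data

The generators define the study conditions for every test:

* **Compendium** (log2-like additive scale): 5 cell types × 3 states ×
  10 replicates (230-ish samples in the default study, matching a
  multi-state immune compendium design), per-gene baselines
  N(8, 1.5²), i.i.d. Gaussian noise with σ = 1. Each planted module
  carries, in its active cell types, a constant mean offset (amplitude
  2 log2 units — a strong but realistic regulation effect) plus a
  shared latent factor. The latent loading is solved from the target
  pairwise correlation r as a = σ·√(r/(1−r)), since two module genes
  then correlate at a²/(a²+σ²) = r; at σ = 0 any positive loading gives
  r = 1 exactly. Half of the latent variance is carried by standardized
  between-state shifts — this is what makes module genes differentially
  expressed across design strata and hence visible to the ANOVA screen —
  and half by per-sample variation; both components are empirically
  standardized so the calibration holds at finite n (realised mean r is
  within 0.01 of target at n = 1000 and within 0.03 over 50 seeds at
  n = 30).
* **Response cohorts** (non-negative linear scale): per-gene base
  abundances are log-normal (log-mean 2.3, log-sd 1 — a plausible
  FPKM-like spread); patient values are the base times mean-preserving
  multiplicative log-normal noise with log-sd 0.5. Planted genes have
  their group mean multiplied by the fold (exactly the fold in
  expectation; exactly the fold pointwise at dispersion 0). Default
  design 15 vs 15 labelled patients, matching advanced-melanoma cohort
  scale; responders alternate CR/PR, non-responders are PD, SD patients
  receive base expression and are excluded from testing.
* **Survival cohorts:** exponential proportional hazards,
  T ~ Exp(h₀·exp(lp)), lp = Σβ_g·x_g + β_age(age−60) + β_stage(stage−2),
  h₀ = 0.02 events/month (median ≈ 35 months for a typical patient),
  independent exponential censoring (0.01/month default), ages uniform
  35–85, stages drawn from (0.2, 0.3, 0.45, 0.05) — a melanoma-registry-
  like stage mix with few stage-IV patients. Gene expression is standard
  normal; genes can be declared bimodal (a latent high/low component
  separated by a stated amount) to plant mixture-stratifiable prognostic
  genes.

What the synthetic study does **not** emulate: probe/platform effects,
batch structure, library-size variation, count discreteness, gene-gene
correlation outside planted modules, informative censoring, and
competing risks. Passing tests demonstrate that the statistical
machinery is correct and calibrated under the stated model; they do not
certify performance on real microarray or RNA-seq data, where
preprocessing choices dominate.

## Numerical choices and degenerate inputs

* BH is the exact step-up with a running minimum; tested against an
  O(m²) brute-force transcription of the definition.
* An all-equal vector Blom-transforms to exactly zero (the offsets map
  the mid-rank to ½) with a warning.
* Zero-variance genes: excluded from correlation families; forced K = 1
  (unstratifiable) in the GMM; error as a Cox covariate.
* "Constant everywhere" ANOVA genes: p = 1 with a warning. Rows whose
  sample variance is at rounding level (≤ 1e-10 relative) are treated
  as constant.
* Cox fits use a Newton precision of 1e-9 so that small-fixture
  estimates agree with a brute-force partial-likelihood oracle to 1e-4.
  Suspected monotone likelihood (convergence failure) triggers one
  ridge-stabilised refit (penalizer 0.1) with a warning.
* All-censored log-rank inputs report statistic 0, p = 1 with a warning;
  proportional-hazards checks need ≥ 3 events, else NaN with a warning.
* Every stochastic stage takes an explicit seed; identical spec + seed
  reproduces byte-identical outputs.

## Problem sizes used in the shipped study

The default end-to-end study uses 5 cell types × 30 samples, 300
background genes, one 8-gene module per cell type (r = 0.95), 15 vs 15
response cohorts at 4-fold with 10 planted biomarkers, and a 390-patient
survival cohort split 255/135 with half the panel prognostic
(β = −0.5 on bimodal expression). Calibration experiments use 50
replicates throughout. These sizes were chosen as the smallest designs
at which the planted effects sit well inside the detectable regime, so
recovery failures indicate implementation defects rather than power
limits.

## Known limitations

* The network-coherence filter is a permutation stand-in with the same
  interface as the published external algorithm, not a reproduction of
  it; retained node sets will differ from that tool's output.
* Only Efron tie handling is available for Cox models.
* Fold change is linear-scale with a fixed pseudocount; heavily
  zero-inflated data may warrant a different ε.
* The GMM screen assumes 1-D Gaussian components; heavy-tailed
  expression can inflate the selected K.
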