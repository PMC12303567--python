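# Methods

`sceqtl` implements a "one-pot" genotype–phenotype mapping workflow for a
pooled haploid yeast-style cross observed by single-cell RNA sequencing:
thousands of F2 segregants from a BY×RM-type cross are grown and sequenced
together, each droplet barcode yields sparse allele counts at the cross's
biallelic polymorphic sites plus a UMI expression profile, and the pipeline
reconstructs per-cell genotypes, assigns cells back to a reference strain
panel, and maps the genetic architecture of fitness and expression.

## Synthetic cross and observation layer

Because the haploid segregants carry exactly two alleles per site, a
genotype is summarized as the RM-allele frequency per site.  The simulator
(`sceqtl.cross`) draws segregants as parental mosaics under a Poisson
crossover process on the genetic map (Haldane map function, no
interference): between adjacent sites at genetic distance d Morgans the
allele switches with probability r = ½(1 − e^{−2d}).  Chromosomes assort
independently and every site has marginal RM frequency ½.

Planted architectures are additive: fitness is Σ β_q g_q plus Gaussian
noise scaled to a target narrow-sense heritability (default h² = 0.5), and
each gene's strain-level mean expression is a baseline plus its planted
cis/trans effects plus noise scaled to a per-gene expression heritability
(default 0.4).  Trans effects are optionally concentrated on shared
"hotspot" loci regulating many genes.

The observation layer mirrors the dataset this package emulates: mean
breadth of coverage 0.03 (the fraction of polymorphic sites with ≥1 read
per cell), 4.83 cell barcodes per segregant, 10% doublets, a per-read
error/swap channel

    P(read = RM | state) = (1 − s)·[state = RM ? 1 − ε : ε] + s·f_site,

where a swapped read draws an allele from the pool frequency f at that
site, and negative-binomial UMI counts with lognormal per-cell library
sizes.  Doublet barcodes contain two cells' worth of material: their
coverage is the union of two independent draws (≈2× breadth), their reads
come from either strain, and their library size is the sum of two draws.
The per-cell coverage distribution is binomial per site; the real data's
heavier-tailed coverage distribution is not modelled, so tests say nothing
about extreme-coverage cells.

**Desk-scale geometry.** Simulations scale the 41,594-site cross down by
a factor of 20–80.  Two scalings are used deliberately and are not
interchangeable.  For genotyping/assignment stages the per-site spacing is
kept realistic (0.4 cM between adjacent sites over 16 chromosomes, 800 cM
total), preserving the tight-linkage imputation regime that the HMM
exploits at 3% breadth.  For QTL-mapping stages the *total* map length is
kept realistic (≈4,300 cM over ~1,000 thinned sites, i.e. ~4.3 cM/site),
so linkage disequilibrium decays within the ±10-site window used to score
locus recovery.  Likewise the bundled end-to-end fixture (500 sites)
raises breadth to 0.2 so that the number of covered sites per cell (~100)
matches a proportional slice of the real regime.

## HMM genotyping

Each cell's hidden BY/RM state sequence per chromosome is a two-state
Markov chain with transitions from the Haldane map (scaled by a global
estimated factor), initial distribution (π_RM, 1−π_RM) with π_RM = 0.5,
and the error/swap emission channel above.  Scaled forward–backward,
vectorized across cells, yields P(state = RM | reads) at every site —
covered or not — so low-coverage sites are imputed through the
recombination process.  Posteriors match exhaustive path enumeration to
1e−10 on small chromosomes (tested).

Parameters (ε, s, recombination scale) are estimated by generalized EM
(Baum–Welch): the M-step maximizes the expected complete-data
log-likelihood numerically for (ε, s) and the transition scale, each step
accepted only when it improves the objective, so the log-likelihood is
non-decreasing.  Pool frequencies are held fixed — at the reference
panel's mean genotype when a panel is available (accurate), else at the
empirical pooled read frequencies.

A structural caveat drives one design choice: in an F2 pool the allele
frequencies hover around ½, so ε and s act almost identically on the
likelihood (only (1−s)ε + s·f̄ is well identified); the weak per-site
frequency deviations that separate them are easily overwhelmed by panel
sampling noise and by doublet reads, and plain EM drifts along this ridge.
When a reference panel is supplied, `GenotypeHMM.fit` therefore refines
the channel in a second stage: cells are provisionally matched to their
nearest panel strain by expected distance, cells whose mismatch rate is a
robust outlier (median + 2·1.4826·MAD — doublets and spurious matches)
are dropped, and (ε, s) are re-estimated by direct maximum likelihood with
the matched strain's alleles as known states.  Known states make the error
channel (state-dependent) and the swap channel (frequency-dependent)
separately identifiable; recovery at the default study conditions is
ε̂ ≈ ±0.01 and ŝ ≈ ±0.02–0.03 per batch.

## Lineage assignment and consensus profiles

A cell posterior g_c is compared with every strain genotype g_s by the
expected distance Σ_i (g_c + g_s − 2 g_c g_s), which reduces to the
Hamming distance on hard genotypes.  The best match is accepted only when
it beats the best match against randomly generated panels of the same
size.  Null panels are fresh segregants simulated on the same genetic
map: they carry realistic allele frequencies *and* linkage, but cannot
contain the cell's strain.  (Shuffling the real panel's columns site-wise
— an alternative we evaluated — destroys linkage so thoroughly that any
real segregant beats the null, which voids false-assignment control.)
The permutation p-value uses the add-one convention and is
Benjamini–Hochberg adjusted across cells; cells are assigned at q < 0.05.
With true strains excluded from the panel the realized assignment rate
stays at the nominal level (tested).

Relatedness between genotypes is the degrees-of-freedom-adjusted R² of
the rounded vectors (ties round to RM); the slope sign is reported
separately since R² is sign-blind.

Doublets are flagged by three clauses evaluated in order: covered-site
count at or above the batch's third quartile; no significant assignment;
and mutual genotype R² < 0.1 between the two best-matching strains.  A
known limitation, documented rather than patched: a 50:50 mixture is
*genuinely* related to each of its components (~75% allele agreement),
so under a calibrated permutation null a moderately-covered doublet is
often significantly assigned and escapes clause 2.  Sensitivity of the
rule on constructed mixtures is therefore well below 1 at every geometry
we tested, while the false-flag rate on singlets stays below 1%.

Consensus genotype per strain is the per-site median of its assigned
cells' posteriors (robust to outlier cells); consensus expression is the
UMI profile of the assigned cell with the largest total count.
Downstream expression is normalized by per-gene standardization followed
by division by the cell's total count.

## REML variance components

The mixed model is y = Xβ + Σ_c W_c u_c + ε with X an intercept, each
W_c column-standardized (zero-variance columns dropped and logged), and
relationship matrices K_c = W_c W_cᵀ/m_c.  "Variance explained" is
Σσ²_random/(Σσ²_random + σ²_res).  With one random term the restricted
likelihood is maximized exactly on the eigenbasis of K (a 1-D profiled
search over the heritability ratio — no iterations, verified against a
grid-search oracle).  With several terms, average-information REML steps
are used with EM-style fallback whenever an AI step fails or decreases
the likelihood; components are floored at ~0 and standard errors come
from the inverse AI matrix at the optimum.  Convergence is a relative
log-likelihood change below 1e−6 within 200 iterations; non-convergence
raises an error carrying the trajectory.

Two-design partitions (genotype/expression for a trait, cis/trans for a
gene's expression) fit the two single-design models and the joint model,
then apply the difference algebra: shared = R_a + R_b − R_ab,
a_exclusive = R_ab − R_b, b_exclusive = R_ab − R_a, residual = 1 − R_ab.
Sampling noise can make a difference slightly negative; negative
components are clipped at zero and the partition re-normalized to sum to
one, with a log entry.  A gene with no cis-eQTL has cis fraction exactly
zero by definition.

Overall expression heritability orthogonalizes the normalized expression
matrix by PCA, takes the minimal k components reaching 99% of variance,
fits each against the genotype random effect, and sums eigenvalue-share ×
R².  The share uses the total expression variance (not renormalized
within k), so with the threshold at 1 and fully genetic expression the
weighted sum reduces to 1; both the single-PC shortcut (when one
component dominates) and the weighted sum are the same code path.

## Sparse QTL/eQTL mapping

The scan minimizes F_o(β) = ‖y − Xβ‖² + λ‖β‖₀ by greedy forward search:
each step adds the locus whose inclusion minimizes the RSS (all effects
refit exactly, via the Gram matrix), then a single-swap refinement pass
(≤5 sweeps) replaces any selected locus that a strict RSS improvement can
swap out.  Search stops when no addition lowers F_o or at
max_k = min(n/10, 300).  Ties break to the lowest site index for
determinism.  On orthogonalized designs the result equals exhaustive
best-subset search (tested over all 2¹⁰ subsets).

Both genotypes and the response are standardized before a scan: the BIC
floor λ ≥ log(n) is a penalty calibrated for unit-variance residuals, and
without response standardization the penalty's meaning would depend on
the trait's units.

For trait QTL, λ is cross-validated: 10 random partitions, a forward path
per training split (paths stop once improvements fall to the λ floor —
larger penalties can never revive them), held-out prediction error scored
for every candidate λ in a grid shared across folds (each fold's path
improvements, floored at log(n_train)), per-fold optimum taken at the
*largest* λ among error minimizers (the sparsest model the data
supports), and λ* set to the mean of fold optima.  The ties-to-sparsest
convention is what makes a permuted-trait null collapse to ≤1 selected
locus in ≥90% of runs; its cost is that λ* typically sits above the BIC
floor even under strong signal.  Per-gene eQTL scans use λ = log(n)
directly (n = number of consensus segregants, the regression sample
size), sharing one genotype Gram matrix across genes.

The power analysis subsamples strains without replacement at a grid of
sample sizes, re-runs the per-gene scan, and reports the linear
regression of detected-eQTL count on n.

## Regulatory architecture

Hotspots: 25-kb windows tiled from position 1; a window is a hotspot when
both its eQTL count and its distinct-regulated-gene count reach the third
quartile of the respective distributions over occupied windows ("fourth
quantile" read as top quartile; quartiles over occupied windows, since
including empty windows degenerates the threshold).

cis/trans: an eQTL is cis to its gene when it lies on the gene's
chromosome within [TSS − 1,000 bp, gene end + 200 bp] in strand-aware
orientation (genes without strand default to +); everything else is
trans.  A Wilcoxon signed-rank helper compares per-gene mean |effect| of
cis vs trans eQTL, and a 2×2 odds-ratio/chi-square helper tests
QTL-in-hotspot enrichment.

QTL↔eQTL matching: the trait QTL's predicted effects on a gene are refit
by multiple regression of the gene's expression on the QTL genotypes;
pair scores are exp(−d_cM/δ)·exp(−|Δβ|/τ) within a chromosome (δ = 10 cM;
τ = pooled effect SD unless set), zero across chromosomes.  The
Needleman–Wunsch alignment over the two position-sorted lists maximizes
the summed *log* pair scores minus γ = 0.5 per unmatched QTL, so a pair
only forms when its score exceeds e^{−γ} — a QTL 200 cM from the nearest
eQTL stays unmatched.  Alignment optimality is verified against
exhaustive enumeration of monotone pairings on small instances.

The rank permutation test compares the mean rank (by |effect|, larger =
stronger) of a gene's matched QTL with 999 random same-size subsets of
the unmatched QTL; p is the fraction of subsets with a higher mean rank,
ties counted at half weight (mid-p) so that integer ranks do not deflate
the null distribution.  The test is calibrated when the matched set is a
small fraction of the QTL pool (subsets come from the complement only, so
a large matched fraction makes p over-dispersed — a property of the test
definition itself, documented here).

Model similarity extends the pair score with an allele-frequency factor
exp(−|Δf|/φ) (φ = 0.1, f = panel RM frequency), aligns on the
multiplicative scale, and normalizes by the larger self-alignment score:
self-similarity is 1, disjoint cross-chromosome models score 0, and a
model shifted by exactly δ cM scores e^{−1} in a flat-frequency panel.

## Pipeline

`run_pipeline` executes simulate → genotype → assign → partition → herit
→ map-qtl → map-eqtl → hotspots → cistrans → match, each stage reading
only serialized artifacts of earlier stages.  A stage re-runs when forced,
when an output is missing, or when an upstream stage re-ran; all
randomness derives from one global seed through a (seed, stage, substage)
generator hierarchy, so full or partial re-runs are bit-identical.  The
manifest records parameters, seeds and SHA-256 checksums of every output.

## Known limitations

- The expression observation layer is negative-binomial with library-size
  scaling only; no cell-cycle program, no zero-inflation term, no
  denoising autoencoder (the normalization hook accepts any pre-transform;
  the package ships identity and a truncated-SVD low-rank smoother), so
  pipeline-level expression heritabilities at
  desk scale are dominated by UMI sampling noise and are much lower than
  the planted strain-level values.
- The doublet rule's sensitivity ceiling discussed above.
- ε/s separation requires a reference panel; without one, only their
  identified combination is meaningful.
- The L0 objective's cross-validation is conservative by construction
  (sparsest-model ties); small-effect loci near the detection boundary
  are dropped before spurious ones are admitted.
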