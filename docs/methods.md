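# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical choices that matter for reproducibility.

## Synthetic cohorts

The generator (`fearscan.simdata`) emulates a multi-breed cohort sampled from
commercial-breeding facilities: by default 6 breeds × 100 dogs, 5,000 SNPs on
38 autosomes, breed differentiation Fst = 0.10, within-breed inbreeding
F = 0.05, 1% sporadic missingness, ~83% females, ages Uniform(1, 10) years,
dogs spread over 12 facilities, and five breed-linked size classes.

**Breed allele frequencies** follow the Balding–Nichols model: with ancestral
frequency p ~ Uniform(0.05, 0.5) and differentiation Fst, the breed frequency
is Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst), giving E = p and Var = Fst·p(1−p).

**LD and inbreeding** are generated jointly through haplotype uniforms. Each
haplotype carries one latent Uniform(0,1) draw per LD block (default 5 SNPs),
refreshed per SNP with probability 1 − ld_copy_prob (default 0.7); the allele
at SNP i is 1 when the uniform falls below that SNP's frequency. This
comonotone-copula construction preserves every per-SNP marginal frequency
exactly while inducing tunable within-block r², so LD pruning has real
structure to act on. Inbreeding couples the two haplotypes of an individual:
per block, with probability F the second haplotype copies the first
(identity by descent), which yields P(hom minor) = p² + F·p(1−p) exactly for
F ≥ 0. For F < 0 the second haplotype is anti-coupled (u₂ = 1 − u₁); the
realized per-locus Wright F is then −|F|·p/(1−p), the feasibility bound —
heterozygote excess necessarily attenuates at low MAF. Chromosome assignment
is even; positions accumulate random 5–50 kb gaps. No attempt is made to
reproduce real canine LD maps, reference-genome coordinates, or pedigrees.

**Phenotypes.** Each genetic component (SF, NSF, SR) gets a latent score
fixed effects + genetic + noise. The genetic value mixes a sparse causal part
(default 10 SNPs, N(0,1) effects) with a dense polygenic background over all
markers, at a 70/30 variance split (`poly_frac = 0.3`), then genetic and
noise variances are rescaled so var(g)/(var(g)+var(e)) equals `h2_target`.
Heritability is therefore defined net of fixed effects, matching a pipeline
that adjusts phenotypes for fixed effects before REML. FM (food motivation)
is pure nuisance (no genetic part). Item scores express their component's
latent plus N(0, 0.6²) item noise, discretized at empirical tertiles (binary
treat/touch items at the median) — a modeling choice, since the real
instrument's item-score distribution is not published. The umbrella step is
represented as two sub-items (opening and closing phases) so the startle
component has at least two indicators.

What passing tests on these cohorts demonstrate: the estimators recover known
truth under breed structure, LD, and inbreeding of realistic magnitude. What
they do not demonstrate: robustness to genotyping artifacts, real LD decay,
assortative mating within kennels, or non-Gaussian phenotype tails.

## Marker QC

Order is fixed and each variant is removed exactly once: non-autosomal or
unmapped → monomorphic or indel → MAF ≤ 0.05 → call rate ≤ 0.90 (both strict
"keep if >" thresholds), then LD pruning. The QC report enforces
input = removals + retained as an invariant. Missing calls are filled with
the per-variant modal dosage (ties to the smaller dosage) — at sporadic
(~1%) missingness this is statistically immaterial and avoids a haplotype
phasing/imputation dependency; a variant with no observed calls is an error.
LD pruning slides a 200-variant window by 50; while any retained pair in the
window has r² > 0.6 the lower-MAF member is removed (equal MAF: the later
variant). The tie-break makes pruning deterministic; retained sets are
idempotent under re-pruning.

## Inbreeding comparison

F̂ = (O_hom − E_hom)/(L − E_hom), with E_hom = Σᵢ [1 − 2fᵢ(1−fᵢ)·nᵢ/(nᵢ−1)]
over the individual's non-missing markers and fᵢ the within-group frequency.
QC (and pruning) is redone within each breed before estimation, since each
breed has its own set of fixed or nearly-fixed markers that would otherwise
bias F̂. Breeds need ≥ 10 dogs per population to enter the comparison. The
two-population test is gated: a two-tailed F-test (larger/smaller variance
ratio, doubled upper tail) at α = 0.05 selects pooled-variance vs Welch's
t-test; Welch df is not rounded. The two-tailed F-test convention was chosen
because it reproduces the published unequal-variance annotations for all 16
breeds in the bundled summary table.

## Behavioral components

PCA is on the item correlation matrix; four components are retained (the
retention rule behind the published four-component solution is unstated, so
the count is fixed rather than eigenvalue-thresholded). Varimax rotation is
Kaiser-normalized and iterated to an SVD fixed point (tolerance 1e-10), which
preserves total explained variance. Components are labeled by the item group
with the highest mean absolute rotated loading (approach items → SF, treat
items → FM, mat/leash/cone/statue → NSF, umbrella → SR) and signed so the
confident ("green"-scored) direction loads positive, making higher scores
mean less fearful. Scores use the least-squares regression method
S = Z R⁻¹ Λ and are mean-zero by construction. KMO follows the anti-image
formula; the two-item case degenerates to exactly 0.5.

Fixed-effect adjustment screens each candidate (facility, sex, size class,
age, GRM PC1/PC2 from the variance-standardized GRM) one at a time — model
F-test for factors, slope t-test for covariates — retains those with
p < 0.05, refits jointly, and returns residuals. With no significant
candidate the adjusted phenotype is the centered raw score. Single-
observation factor levels are dropped with a warning. The retention α is a
package choice; the source analyses report exact p-values but no cut-off.

## Heritability

AI-REML on y = Xβ + g + e with g ~ N(0, K σ²_g). K is trace-normalized to
mean diagonal 1 at entry, so σ²_g is in phenotypic-variance units and
h² = σ²_g/(σ²_g+σ²_e) is the fraction of phenotypic variance tagged by the
markers regardless of GRM scale — without this, a centered GRM (average
diagonal ≈ mean dosage variance, ~0.4) silently rescales σ²_g. The
likelihood is evaluated in the eigenbasis of K (one O(n³) decomposition,
O(n) per iteration). Iterations start at σ²_g = σ²_e = var(y)/2; steps are
AI-Newton with halving until the restricted log-likelihood does not
decrease, components floored at 1e-6·var(y) (h² reported in [0, 1]);
convergence at parameter change < 1e-8 or log-likelihood change < 1e-10,
max 100 iterations. The SE of h² is delta-method on the inverse AI matrix.
K ∝ I is flagged unidentifiable. One REML engine stands in for the several
estimators a practitioner might run (AI-REML, Gibbs, GCTA REML); published
comparisons of those estimators agree within their SEs on cohorts of this
size, and Gibbs sampling is out of scope here.

## Association

Per marker: y = Wα + xβ + u + ε with u ~ N(0, K σ²_g). After one
eigendecomposition of the centered GRM, the variance ratio δ = σ²_e/σ²_g is
profiled by minimizing the concentrated restricted likelihood over a 21-point
log₁₀ grid on [1e−5, 1e5] refined by bounded Brent search (xatol 1e-4 in
log-space); β and se(β) follow by GLS in the rotated space with
σ̂² = RSS/(n−p), and the Wald statistic (β/se)² is referred to χ²₁. The
default mode re-profiles δ per marker; `mode="fast"` reuses the null-model
ratio for all markers (EMMAX-style), which on null simulations is calibrated
(λ_gc ≈ 1, type-I ≈ 0.05) at a fraction of the cost. Monomorphic markers get
NaN statistics and a log line. Thresholds: Bonferroni α/m and suggestive 1/m;
the separate reporting cut-off (default 4×10⁻⁵) is a presentation threshold
for hit tables and the default GRS panel, not an inference threshold. λ_gc is
the median χ²₁ quantile at 1−p divided by qchisq(0.5, 1) ≈ 0.455. A published
suggestive threshold of 3.54×10⁻⁶ alongside 293,519 markers is internally
inconsistent with 1/m ≈ 3.41×10⁻⁶; the formula is implemented as stated and
the discrepancy left unresolved.

## Gene windows

Windows are [pos − flank + 1, pos + flank] (1-based inclusive, width exactly
2·flank; default 500 kb each side), clamped at 1 (and at the chromosome
length only when a length table is supplied). Same-chromosome hits within the
merge gap (default 1 Mb) collapse into one window from min(pos) − flank + 1
to max(pos) + flank. Distances are SNP-to-nearest-gene-edge (0 inside a
gene); whether published distances were measured to the gene edge or start is
unstated, so nearest-edge is used and flagged. Upstream/downstream is
positional (lower/higher coordinate), strandless. BED input is converted to
1-based inclusive at the boundary.

## Risk scores

cGRS counts minor (risk) alleles, with full reversal (2 − dosage) at
negative-effect markers so counts stay in {0, 1, 2}; only the homozygote
recoding is pinned down by the source description, and reversal vs
"heterozygote always 1" differ only in labeling, not ordering. wGRS is the
signed sum Σ βⱼ·dosageⱼ, consistent with negative group means in published
summaries. Extremity bins use mean ± sd_mult·SD (population SD, boundary
inclusive — the inclusive convention is needed for degenerate two-point
fixtures and is measure-zero for continuous phenotypes). The SNP panel is a
required, logged parameter (default: markers below the reporting cut-off);
the panel behind published group means is not recoverable from the source.
Group comparisons: one-way F-test plus Tukey–Kramer (studentized range,
unequal group sizes) at α = 0.05. When effects are estimated in-sample, the
extreme-bin separation is partly mechanical; outputs label it descriptive.

## Problem sizes and determinism

Test and acceptance simulations use 400–5,000 SNPs and 150–600 dogs —
chosen so the full suite and the acceptance script each run in minutes on a
laptop core while keeping estimator SEs comparable to a real cohort of ~600
dogs. Every generator and the pipeline are deterministic under a fixed seed;
pipeline reruns produce identical artifact checksums. All published-value
reproductions in the tests were computed by this package's own code paths;
no empirical number is asserted that a test does not recompute.

## Known limitations

Single-GRM, single-trait REML only (no bivariate or partitioned analyses);
no X-chromosome association model; no permutation thresholds; no
out-of-sample risk-score validation or LD-aware shrinkage; the mode-fill
imputation ignores haplotype information; synthetic LD is block-wise, not a
decay curve.
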