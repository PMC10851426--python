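# Methods

## Model and procedure

scnkit analyses *group-level* structural covariance: each group
contributes a single network whose edge weights are Pearson correlations
of covariate-residualized regional cortical thickness across that group's
subjects. Because a group is one network, subject-level statistics do not
exist; inference treats the whole pipeline as a statistic of the group
labeling and permutes labels.

Stages, with the conventions chosen where several are in use:

**Residualization.** Per region, OLS of thickness on an intercept plus the
named covariates (default `age`, `sex`, `tiv`). Default scope is
*per-group* (regressions fit within each group separately), the standard
practice when each group gets its own covariance matrix; a *pooled* scope
is available. Rank-deficient designs (e.g. a single-sex group with `sex`
as covariate) are a hard error naming the covariate.

**Correlation.** `numpy.corrcoef` on the residuals; the diagonal is zeroed.
A zero-variance region (constant residuals) would produce NaNs; its
correlations are defined as 0 with a logged warning, keeping matrices
finite and auditable.

**Density thresholding.** At density *d* the `K = round(d·N(N−1)/2)`
strongest pairs become edges. Ranking is by *signed* r (most positive
first) by default — at densities ≤ 0.40 on 148 nodes this effectively
excludes negative correlations; ranking by |r| is available
(`edge_rank="absolute"`). Ties at the cutoff resolve by lexicographic
(i, j) node order (the pair list is generated in that order and the sort
is stable), so edge counts are exact and runs are reproducible. Using one
ranking for all densities makes the stacks nested by construction. Note
`round`, not truncation: at d = 0.10 on 148 nodes, K = round(1087.8) =
1088.

**Metrics.** On binary undirected graphs: C is the mean of nodal
Watts–Strogatz clustering coefficients (nodes of degree < 2 contribute 0)
— this, not the transitivity ratio, is what small-world γ conventionally
normalizes; transitivity is exposed separately. Lp is the mean
shortest-path length over *finite* ordered pairs; disconnected pairs are
excluded rather than substituted, which keeps Lp defined at every density
in the sweep (fragmentation is flagged per density by
`check_density_validity`). Efficiencies use 1/∞ = 0. Elocal(i) is the
global efficiency of the subgraph induced by i's neighbours. BC is raw
(unnormalized) Brandes betweenness in the undirected convention —
normalization would cancel in the permutation test anyway. Distance-based
metrics share one all-pairs BFS implemented as O(diameter) boolean matrix
products, fast for small dense graphs; betweenness delegates to networkx.

**Null models.** Maslov–Sneppen double-edge swaps with exactly
`swaps_per_edge·|E|` attempted swaps (default 10 per edge, standard mixing
practice); swaps creating self-loops or duplicate edges are rejected and
still count. Degree sequences are conserved exactly by construction; rigid
graphs that admit no valid swap (e.g. a triangle) are returned unchanged
with a logged note. Connectedness is *not* enforced — the metrics handle
disconnection and enforcing it would bias the null. A density-only
(Erdős–Rényi) null is available as an option. γ = C/mean(C_rand),
λ = Lp/mean(Lp_rand), σ = γ/λ over the ensemble (default size 1,000).
One caveat of the finite-pair Lp convention: on a *fragmented* real graph
compared against mostly-connected nulls, λ can fall below 1 and inflate σ;
the per-density component counts written by the validity report make this
visible.

**Inference.** Test statistic: AUC(group 1) − AUC(group 2) of a metric's
density curve (trapezoidal integral; group 1 is the patient-like group).
Null distribution: group labels permuted preserving sizes; the *entire*
pipeline — including re-fitting the covariate regressions within each
permuted group — is re-run per permutation, keeping the null exchangeable
(`refit_residuals=False` offers the cheaper residualize-once variant).
Two-tailed p with add-one correction, so p ≥ 1/(n_perm+1) and never 0.
Nodal metrics (BC, DC, NE) are BH-FDR corrected across regions *within
each metric family*, matching the granularity at which nodal results are
reported. Default n_perm = 1000.

Descriptive cohort comparison uses a pooled-variance t-test when
Shapiro–Wilk (α = 0.05, per group) does not reject normality in either
group, Mann–Whitney U otherwise, and a Pearson χ² without continuity
correction for sex. Partial correlation residualizes both variables on an
intercept plus covariates and refers t = r√((n−2−k)/(1−r²)) to n−2−k df;
the Bonferroni factor defaults to the number of pairs actually tested.
Design power for a two-sided two-sample t-test uses the noncentral t with
noncentrality d/√(1/n1+1/n2); at d = 0.56, n = 56/59, α = 0.05 it
evaluates to 0.85 (2 d.p.).

## Synthetic cohort generator

A latent-factor block model: regions are partitioned into `n_modules`
contiguous modules (default 8 for 148 regions, ≈ 18 regions each — large
enough for stable clustering estimates at ~56 subjects per group); each
subject draws one N(0,1) factor per module and

    thickness[s, r] = mean_thickness[r] + loading[group(s)]·factor[m(r), s]
                      + beta_age·(age − mean) + beta_sex·sex
                      + beta_tiv·(tiv − mean) + ε,  ε ~ N(0, noise_sd)

with age ~ Uniform(45, 70) years, sex ~ Bernoulli(0.5), TIV ~
N(1.45·10⁶, 1.3·10⁵) mm³, and small covariate slopes (−0.01 mm/year,
+0.05 mm for males, 5·10⁻⁸ mm/mm³) so residualization has real work to do.
Defaults: 56 patients vs 59 controls, mean thickness 2.5 mm, loadings
0.6 (patients) / 0.8 (controls).

The loading is the generator's single topological knob: within-module
correlation is l²/(l²+σ²_noise). `noise_sd` defaults to 0.6 mm so that
these correlations (≈ 0.4–0.65 at the default loadings, the magnitude
typical of thickness covariance) *compete with the sampling noise of
between-module correlations* at n ≈ 56. This matters: with much smaller
noise both groups' edge rankings separate modules perfectly and density
thresholding — which discards correlation magnitudes — transmits no group
difference at all. Only in the competitive regime does a lower patient
loading let between-module edges displace within-module edges at fixed
density, lowering patient clustering and local efficiency, which is the
planted direction of effect.

Two deliberate departures from strict realism: (a) the chosen factor and
noise scales imply a between-subject thickness SD near 1 mm, several times
larger than real morphometry, because the correlation structure — not the
marginal scale — is what the pipeline consumes; (b) the linear-Gaussian
model has unbounded tails, so rare negative draws are floored at 0.05 mm
with a logged count (≈ 0.5–1% of values at defaults) to keep datasets
strictly positive. The generator also does not emulate spatial
autocorrelation on the cortical sheet, hemispheric symmetry, region-wise
heteroscedasticity, or realistic lesion/complication structure —
consequently, passing recovery tests demonstrate correctness of the
*pipeline mechanics and statistical calibration*, not performance on real
MRI-derived tables.

`inject_regional_atrophy` additionally lowers patient thickness in chosen
regions by a fixed offset, for mean-difference (as opposed to covariance)
scenarios.

## Numerical and design choices

- All randomness flows through `numpy.random.Generator` seeded from
  explicit integers; the pipeline derives named per-stage sub-seeds
  (crc32-based, process-stable) from one master seed, so full runs are
  byte-reproducible.
- Triangle and degree counts are computed in float32 BLAS products (exact
  for counts < 2²⁴) and divided in float64, so metric values match exact
  enumeration to machine precision; the test suite holds them to
  brute-force oracles at 10⁻¹² on random graphs.
- Edge counts use Python `round` (banker's at .5 ties) — deterministic and
  matching the stated formula.
- AUC uses the trapezoidal rule on the actual density grid; curves with
  non-finite values are a hard error rather than silently integrated.
- Permutation tests for γ/λ/σ are possible in principle but cost
  n_random × n_densities rewirings per permutation; the pipeline reports
  observed γ/λ/σ curves per group (with ensemble normalization) and
  permutes C, Lp, Eglobal, Elocal and the nodal metrics.

## Problem sizes in the shipped checks

The statistical acceptance checks run on reduced cohorts chosen as the
package's own test design: type-I calibration uses 200 homogeneous
60-region cohorts (6 modules, both loadings 0.7) with n_perm = 200 — the
nominal-rate property does not depend on parcellation size; effect
recovery uses 20 cohorts at loadings 0.5 vs 0.9 with n_perm = 50 (the
smallest attainable p, 1/51 ≈ 0.02, still clears α = 0.05). The
full-size 148-region configuration is exercised end to end by the
construction, null-model and acceptance-script paths.

## Known limitations

- Group-level SCN only: no subject-level covariance variants, weighted or
  directed metrics, sparse inverse-covariance networks, rich-club or
  modularity statistics.
- The finite-pair Lp convention makes λ (and hence σ) optimistic on
  fragmented graphs; inspect the validity report at low densities.
- Nodal metric AUCs are group-level quantities; correlating them with
  per-subject clinical scores is not meaningful, so the clinical
  correlation helper pairs subject-level quantities (e.g. mean thickness)
  with clinical variables instead.
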