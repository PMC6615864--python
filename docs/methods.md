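# Methods

## The screen model

A pooled shRNA dropout screen measures, per hairpin, the change in
relative abundance between a reference timepoint t0 (taken after infection
and antibiotic selection, before treatment) and a final timepoint tF after
a fixed number of population doublings under vehicle (DMSO) or drug. A
hairpin whose gene knockdown impairs growth under a condition is depleted
there; a *sensitiser* gene is depleted under the ligand but not under
vehicle.

The generative model implemented in `synthetic_data` is deliberately the
same family as the analysis model so that parameter-recovery tests are
well-posed:

1. **Baseline abundance.** Plasmid-pool proportions are log-normal,
   `p_h(0) ∝ LogNormal(0, sigma_lib)`, `sigma_lib = 1` by default — wide
   enough that hairpin abundances span ~2 orders of magnitude, as pooled
   libraries do.
2. **Infection bottleneck.** A multinomial draw of `C = coverage × H`
   cells (coverage 1000 cells/hairpin by default, matching the
   representation floor maintained in such screens). t0 is sequenced from
   these cells; replicates are independent trajectories from this draw on.
3. **Growth and passaging.** Over each passage block of 3 doublings, cell
   counts scale deterministically by `2^{Δd (1 + e_h s_{g,c})}` where
   `s_{g,c}` is the per-doubling selection coefficient of gene g under
   condition c and `e_h ∈ [0,1]` the hairpin's knockdown efficacy
   (`Beta(5, 2)`, mean ≈ 0.71 — most hairpins work well, some poorly).
   Between blocks the population is bottlenecked back to `C` cells by a
   multinomial resample; growth runs 15 doublings in total. Growth rates
   with `1 + e·s ≤ 0` clamp to zero cells.
4. **Sequencing.** Counts are gamma-Poisson around `depth × H × q_h`
   (mean depth 300 reads/hairpin) with a single sequencing dispersion
   `phi_seq = 0.05` — typical replicate-level overdispersion for counting
   screens.

Selection defaults: sensitisers feel `s_lig = −0.2` only under their
ligand, so a fully efficacious hairpin has expected log₂FC
`d·s = 15 × (−0.2) = −3`, comfortably past the −1 sensitiser threshold —
these are clear positive controls, not marginal ones. Essential genes
(5% of the library) feel `s_ess = −0.15` in every growth arm including
vehicle; they exercise the vehicle-subtraction step. Planted ligand
sensitisers default to 10% of genes (4% per ligand + 2% shared).

**What the generator does not model:** multiple shRNA integrations per
cell (screens use low MOI precisely to avoid them), PCR amplification
bias, index hopping/cross-contamination, wall-clock passage cadence
(everything is indexed by doublings), and within-replicate correlation
between arms beyond the shared t0 bottleneck. Passing recovery tests
therefore shows the statistics behave correctly when the NB model is
approximately right and effects are of the planted size; it does not
certify performance under PCR artefacts or correlated library composition
drift.

## Read quantification

The reference is a fixed set of equal-length (22 nt) guides, so counting
is dictionary lookup rather than positional alignment: trim reads to the
guide length, quality-trim from the 3' end (Phred+33, minimum score 20 by
default — configurable because encoding offset and threshold are easily
conflated in legacy descriptions), drop reads left shorter than the
guide, then match. `one_mismatch` mode counts a read iff exactly one
guide attains the minimal Hamming distance (0 or 1); ties are discarded
as ambiguous and reported. Reverse-complement search is not performed
(the protocol sequences the sense strand). Exact mode is the default; at
a per-base error rate ε the expected exact-mode match rate is
`(1 − ε)^22` (≈ 97.8% at ε = 0.001), which the tests verify.

## Differential representation

* **Filter.** Keep a hairpin iff CPM ≥ 0.5 in *every* t0 replicate
  (inclusive boundary: 5 counts in a 10M-read library passes). Treatment
  samples never influence the filter.
* **TMM.** Per non-reference sample: drop hairpins zero in either sample,
  form `M = log2 ratio` and `A = mean log2 abundance` of library-scaled
  proportions, trim the top/bottom 30% of M and 5% of A by rank, and
  average M weighted by inverse asymptotic variance
  `1/v, v = (N_k−y_k)/(N_k y_k) + (N_r−y_r)/(N_r y_r)`; factor `= 2^mean`.
  The reference sample is the one whose upper quartile of scaled counts
  is closest to the mean upper quartile; factors are rescaled to
  geometric mean 1. Fewer than two usable hairpins falls back to factor 1
  with a warning.
* **Dispersions.** The Cox–Reid adjusted profile likelihood
  `APL_g(φ) = ll(y_g; μ̂_g(φ), φ) − ½ log det(XᵀWX)`, `W = μ/(1+φμ)`, is
  evaluated on a 41-point log grid over `[1e-4, 10]`. The common
  dispersion maximises `Σ_g APL_g` (grid argmax refined by a bounded
  scalar search in log10 φ). Tagwise dispersions maximise
  `APL_g + (prior_df / residual_df) · mean_g APL` (prior_df = 10),
  located on the same grid and polished by quadratic interpolation in
  log10 φ — a deliberate trade against per-hairpin iterative refinement,
  which costs ~10⁵ scalar GLM fits per pool for accuracy far below the
  shrinkage bandwidth.
* **GLM/LRT.** Log-link NB GLMs are fitted by IRLS with per-row step
  halving, vectorised across hairpins (relative deviance tolerance 1e-8,
  50 iterations, η clamped to ±45, all-zero groups flagged degenerate).
  The design is a one-hot group indicator (t0, DMSO, PDS, PhenDC3); each
  contrast's reduced design merges the treatment with t0. LR = deviance
  difference, clamped at 0, with chi-square df = rank difference (1).
  Reported log₂FC comes from a fit with a prior count of 0.5 (scaled by
  relative effective library size) added, so zero counts give finite
  estimates; the test itself uses raw counts.
* **FDR.** Benjamini–Hochberg step-up within each pool × contrast
  (pools are independent experiments; cross-pool gene unions happen at
  the calling stage). NaN p-values propagate rather than silently drop.

## Gene calling and set logic

A gene is significantly depleted if `n_sig ≥ ceil(0.5 n)` **or**
`n_sig ≥ 3` hairpins are significant (FDR ≤ 0.05, log₂FC < 0) and the
median log₂FC is negative; sensitiser additionally requires median
log₂FC ≤ −1 (inclusive). Both branches of the disjunction suffice alone,
including the degenerate 2-hairpin/1-significant case. The median is
computed over the significantly depleted hairpins by default (an
"all hairpins" mode is provided; the choice matters for genes with a few
strong and several inert hairpins, and the significant-only default pairs
naturally with reporting "number of depleted hairpins and median
log₂FC"). Ligand-specific sets subtract genes depleted under vehicle;
cross-screen summaries report Venn regions, per-screen two-ligand
intersections, and key genes = genes present for both ligands in every
screen. A symmetric enrichment direction (log₂FC ≥ +1) is provided for
resistance-style analyses but is not exercised by the recovery tests.

## Enrichment

One-sided Fisher tests are hypergeometric right tails
`P(X ≥ a | N, K, n)`; the universe defaults to genes actually tested
post-filter (untested genes cannot be hits). When a target's universe
size is unknown and only a background proportion p₀ is quoted, fold
`= (a/n)/p₀` is exact but the tail is a binomial approximation and the
result is tagged accordingly. The EASE score is the same tail with the
overlap cell decremented (a = 1 ⇒ p = 1), hence always ≥ the Fisher p.

## Pharmacology

The 4PL is parametrised
`y = bottom + (top − bottom)/(1 + 10^{(log10 x − logIC50)·hill})` with
positive hill meaning response falls with dose, so `y(IC50)` is the
midpoint and GI_p inverts the curve exactly at `y = 100 − p` (for a
normalized fit with hill 1, GI₂₀ = IC50/4). Normalized fits fix
top = 100, bottom = 0 and need ≥ 2 distinct doses; free fits need ≥ 4.
Initialisation is a fixed grid (extremes for top/bottom, dose-range
candidates for logIC50, hill ∈ {±1}); the best final RSS wins, making
fits deterministic. Bliss surfaces take a % viability matrix whose first
row/column are the single-agent margins and cell (0,0) the untreated
control (validated to 100 ± 5%); replicate matrices are averaged before
computing `S = 100·(I_obs − (I_a + I_b − I_a I_b))`, positive = synergy,
and the peak is the maximum of the mean surface (rather than the mean of
per-replicate peaks — the mean surface is what the averaged-replicate
convention of combination software reports). One-site binding fits
constrain K_d > 0 and start from the interpolated half-saturation point.

## Numerical and testing notes

* All randomness flows through `numpy.random.default_rng` seeds; child
  streams come from `SeedSequence` so stages are independently
  reproducible.
* The test suite checks the implementation against independent oracles:
  a straight-line TMM re-implementation, zooming brute-force likelihood
  grids for the NB GLM/LRT, exact integer tail sums for the
  hypergeometric/EASE statistics, brute-force step-up for BH, and
  all-pairs Hamming scans for the matcher.
* Simulation-based checks use deliberately modest sizes (e.g. 20 seeded
  screens of 1000 genes × 5 hairpins for recovery; 5000 hairpins for null
  calibration; 200 seeds for pharmacology recovery) — large enough that
  Monte-Carlo error is well inside the asserted bounds.
* `scripts/acceptance.py` recomputes the headline quantities from scratch
  at runtime (5 screens of 500 genes for recovery, 2000 null hairpins,
  100 pharmacology seeds) and writes them as JSON.

## Known limitations

* No trended (abundance-dependent) dispersion, quasi-likelihood F-tests,
  or exact two-group tests — the GLM/LRT route only.
* The one-mismatch matcher considers Hamming distance only (no indels);
  barcode designs with indel-prone chemistry need a different matcher.
* The binomial proportion-background enrichment p-value is approximate by
  construction; only the fold is exact in that mode.
* Gene calls assume each gene's hairpins live in a single pool (true of
  pool-randomised libraries); genes split across pools would need a
  cross-pool aggregation rule that is not implemented.
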