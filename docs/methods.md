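# Methods

## The generative model

The simulator emulates gnotobiotic reconstitution experiments in which two
plant hosts (Lj, At) are inoculated with a taxonomically paired SynCom: each
of the `n_families` bacterial families contributes one strain isolated from
each host, so the two half-communities are exchangeable by construction.

Per sample, strain *s* receives the weight

    w_s = base_s · phi_s(host, compartment) · pi_s(arrival order)

and the expected relative abundance vector is `w / Σ w`. Counts are drawn
Dirichlet–multinomial: `p ~ Dirichlet(c · E[RA])`, `counts ~
Multinomial(depth, p)`, where `c` is the overdispersion concentration.

- **Base abundances** `base_s` are log-normal (meanlog 0, sdlog 1), drawn
  once per experiment and *shared between the two members of a family
  pair*. The sharing is what makes the symmetry results exact: under
  `phi = 1` the expected aggregated RA of either host's strains is exactly
  0.5, and under any scalar `phi` the expected per-strain RA ratio between
  hosts is exactly `phi` — the normalizing sums cancel pair by pair. The
  log-normal sdlog of 1 gives the right-skewed rank-abundance profile
  typical of amplicon data (roughly 1.5 orders of magnitude between the
  most and least abundant strains in a 32-member community).
- **Host preference** `phi_root` (default 4) multiplies the weight of a
  strain *native* to the sample's host, in root samples only; an optional
  `phi_rhizo` (default 1) covers the rhizosphere, and unplanted soil is
  always neutral — preference is a root phenomenon in this system.
  `phi_root` accepts a per-strain mapping so that heterogeneous preference
  strengths can drive correlation studies. For symbiosis-mutant hosts
  (genotype listed in `mutant_genotypes`, default `nfr5`) the factor is
  attenuated to `1 + a·(phi − 1)` with `a = nfr5_attenuation` (default 0.5):
  preference reduced but not abolished. No per-strain effect sizes are
  published for this regime; 4 and 0.5 are calibration choices that put the
  per-strain test comfortably in its detectable range at 12 replicates.
- **Priority effect** `pi_priority` (default 3) multiplies the weights of
  first-arriving strains in sequential designs. A sequential simulation
  emits three arms: each strain set as resident (the other invading) plus a
  mixed-community control, so every strain is observed in an invading role
  on both hosts and the competition control is available from the same
  experiment.
- **Noise**: the Dirichlet concentration (default 200) dominates the
  sampling variance at realistic depths — at `c = 200` a 0.75-mean
  aggregated RA has a per-sample sd of ≈ 0.031 regardless of depth, which
  matches the spread visible across biological replicates in this kind of
  experiment far better than pure multinomial noise would. The model
  collapses to multinomial as `c → ∞`. Default depth is 10,000 reads per
  sample (MiSeq-scale after quality filtering); the recovery analyses in
  the acceptance script run at 100,000 where the closed-form comparisons
  need sampling error from counting to be negligible.
- **Reads** are substitution-only copies of the strain reference at a fixed
  per-base error rate, full reference length, fixed quality string. This is
  exactly what a perfect-match mapper is sensitive to; indels, chimeras and
  primer-mismatch dropout are deliberately not modelled.
- **Culture plates**: each well receives `Poisson(cells_per_well_mean)`
  founder cells from the community profile and its reads are multinomial
  over the founders. At 0.1 cells/well the conditional probability of a
  single founder given non-emptiness is `λe^{−λ}/(1−e^{−λ}) ≈ 0.95`, the
  limiting-dilution regime the well-purity analysis assumes.

Seeding: every public simulation function takes one integer seed and
derives independent child streams from fixed sub-stream indices
(`SeedSequence((seed, k))`), so modules are reproducible independently.

### What the simulator does not capture

Real amplicon data add PCR and primer bias, chimeras, contamination,
compositional coupling with unmodelled taxa, and biological structure
(spatial micro-niches, strain–strain interactions beyond shared
normalization, temporal dynamics). Passing the recovery tests shows the
*statistics* are correct and calibrated under the stated model, not that
the model is a sufficient description of any particular experiment.

## Strain quantification

References are the v5–v7 fragments delimited by 799F
(`AACMGGATTAGATACCCKG`) and 1192R (`ACGTCATCCCCACCTTCC`). Extraction uses
exact degenerate matching (IUPAC codes expand to character classes), the
leftmost forward site, the leftmost reverse-complemented reverse site
downstream of it, both sites included, and a 2,000 nt length cap — all
deterministic.

Mapping is full-length, strand-aware byte equality against the reference
set (reads are assumed merged and oriented; a flag enables
reverse-complement matching, and a constant-length end trim is available).
Reads equal to two or more references are counted as *ambiguous* and
excluded rather than split fractionally or assigned to a top hit: at strain
resolution a tie means the assay cannot distinguish the strains, and
pretending otherwise would silently convert reference redundancy into
counts. Whether terminal overhangs should be tolerated is not standardized
for this kind of mapper; full-length equality is the strictest reading and
is what the trim option relaxes.

## Index statistics

Indices are ratios of means (not means of ratios): mean RA over cognate-host
root samples divided by mean RA over other-host root samples, per
experiment. The 0.1% filter is applied to both means with an inclusive
boundary, mirroring the inclusive boundaries used throughout the package
(well filter ≥ 100 reads kept, OTU well max ≥ 10 kept, purity ≥ 0.90
recoverable, RA ≥ 0.1% abundant). Strains passing the filter have strictly
positive indices, so log transforms need no pseudocounts.

Significance: two-sided Mann–Whitney per strain, exact enumeration when both
groups have ≤ 8 samples and no ties, normal approximation with tie and
continuity correction otherwise; all-tied inputs get p = 1 by convention.
BH adjustment runs across strains within an experiment. The default alpha
is 0.05 and is exposed as a parameter (stricter thresholds such as 0.005
are a caller choice).

The preference–invasiveness comparison uses Pearson correlation on log2
indices — ratios are multiplicative, and on the log scale a shared
fold-factor is a linear signal. Spearman is exposed as an option.
"Independent of relative abundance" is operationalized as the first-order
partial correlation given log2 mean RA. At least 3 strains must pass both
filters.

The family-knockout analysis removes one family at a time, renormalizes
each sample to unit sum, and re-tests native vs non-native aggregated RA
per host (Mann–Whitney); a removal that leaves no features is skipped with
a warning. Because the two aggregates are complementary (they sum to 1 per
sample), the test is equivalent to testing the native aggregate against
0.5, which is the intended community-level preference readout.

## Ecology statistics

- Shannon uses the natural log (the common ecology-package default).
- No rarefaction is applied; a minimum-depth sample filter
  (`min_sample_reads`) is the exposed alternative. Zero-total samples are
  flagged and excluded downstream rather than silently dropped.
- PCoA is classical scaling of the Gower-centred squared-distance matrix;
  negative eigenvalues (non-Euclidean input such as Bray–Curtis) are
  excluded from the variance denominator and reported separately, so
  "proportion explained" always refers to the representable spectrum.
- PERMANOVA computes the pseudo-F from among/within sums of squared
  distances with `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` over random
  permutations (default 5,000); permutations can be restricted within
  strata (e.g. experiment batches). The test statistic matches
  scikit-bio's implementation to numerical precision (checked in the test
  suite); the in-package implementation exists because strata-restricted
  permutation and the explicit R² are part of the contract. Note the p
  floor is only attained when no permutation ties the observed F; with
  balanced two-group designs a random permutation reproduces the original
  partition with probability `2(n/2)!²/n!`, which is non-negligible for
  small n.
- Dunn's post hoc uses mean-rank z tests with the tie-corrected variance,
  BH adjustment, and a compact letter display built from the maximal
  cliques of the non-significance graph.

## Problem sizes and numerical checks

The acceptance script and end-to-end tests use: a 32-strain panel; 12 root
replicates per host for index recovery (the per-strain test's detectable
range at `phi = 4`); 200 null experiments for test-size calibration
(6,400 per-strain tests — at n = 12 per group the exact size of the
level-0.05 Mann–Whitney test is 0.0449, computed from the discrete rank-sum
null, and the empirical rate is checked against that value, not against a
nominal 5% the discrete test cannot attain); 32 replicates per cell for the
priority-effect mean (putting the ±0.02 check at ≈ 3.7 standard errors
given the overdispersion above); 100 runs for the null correlation
coverage, compared against the closed-form null probability
`P(|r| < 0.3) ≈ 0.90` at n = 32 (the t-transform of Pearson r under
independence); and 1,000 simulations × 999 permutations for p-value
uniformity. These sizes keep every Monte-Carlo comparison at ≥ 3 standard
errors while remaining fast on a single CPU.

## Known limitations

- The perfect-match mapper discards any read with sequencing error, so
  absolute read yields are error-rate dependent; relative abundances are
  unaffected under a uniform error model, which is the assumption.
- Greedy centroid clustering is order-dependent by design; determinism
  comes from the abundance-then-lexicographic visiting order, not from a
  globally optimal clustering.
- The OTU-clustering identity is computed from a single optimal global
  alignment (match 1, mismatch −1, gap open −2, extend −0.5); co-optimal
  alignments with different identities are not enumerated. At the 97%
  threshold and ~360 nt fragments this is immaterial, and the panel
  generator guarantees family separations far from the boundary.
- Compact letter displays from clique covers are not unique; the
  deterministic ordering makes them reproducible, not canonical.
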