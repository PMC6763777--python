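# Methods

This note records the modelling and numerical choices behind `priorcd`, the
reasoning where the design was genuinely open, and what the synthetic panels
do and do not demonstrate.

## Pathway activity (ssGSEA)

The per-sample enrichment score is the raw running-sum statistic: genes are
ranked by decreasing expression within one sample, the gene at 0-based
position i carries rank value r = N − i, and

    ES(S) = Σᵢ [P_in(i) − P_out(i)]
    P_in(i)  = Σ_{g∈S, pos(g)≤i} r_g^τ / Σ_{g∈S} r_g^τ
    P_out(i) = #{g∉S, pos(g)≤i} / (N − |S|)

* **τ (weight exponent), default 0.25, dimensionless.** Down-weights the
  rank contribution; τ = 0 gives the unweighted Kolmogorov–Smirnov-like sum.
  Exposed because reasonable ssGSEA variants differ here and downstream
  results are mildly sensitive to it.
* **No cross-sample normalization.** Every downstream use of activities is a
  Pearson correlation, which is invariant to per-pathway affine rescaling,
  so normalizing ES across samples would change nothing while adding a
  coupling between samples.
* **Ties** are broken by feature ID after a stable sort on value, so scores
  are identical across platforms and runs. ES is invariant to any strictly
  monotone transform of one sample's expression (ranks unchanged) — a tested
  property.
* **Missing expression values** are dropped from that sample's ranking (N
  varies per sample). A pathway with no measured member is dropped with a
  log message; a pathway covering *all* measured features has an undefined
  out-of-set ECDF and is an error.

microRNA pathways: miRNA m joins pathway P when the hypergeometric upper
tail P(X ≥ |targets(m) ∩ P|) is below 0.05, drawing |targets(m)| genes from
the universe. The universe is the measured genes appearing in at least one
pathway or one target set; this is a choice — a broader "all measured genes"
universe makes overlaps look more surprising and admits more miRNA pathways.
Pathways with a single member miRNA are kept (their one-row activity profile
is still a valid correlation input) but counted in the log.

Pathway de-redundancy (optional): pairs whose two-way overlap
min(|A∩B|/|A|, |A∩B|/|B|) exceeds 0.80 are collapsed greedily from the most
overlapping pair down, removing the smaller set (ties: the lexicographically
later name). The output provably contains no offending pair.

## Drug screen

Drugs are kept when their inter-quartile range *and* maximum of −log10(GI50)
both reach the top quartile of the respective distributions (comparison ≥,
inclusive linear-interpolation quantile). Drugs with fewer than 4 measured
values are excluded before quartiling. The retained count is sensitive to
the quantile convention, so the method is configurable. Filtering is *not*
idempotent — a second pass re-quartiles the smaller distribution and may
shrink further; this is documented and tested rather than hidden.

## Similarity network

The drug–drug similarity is a correlation of correlations: pathway–drug
Pearson correlations over pairwise-complete cell lines (entries with < 3
complete pairs are missing), then per-pair Pearson over pathways where both
drugs have defined correlations (< 3 usable pathways → missing entry).
Two-sided p-values use the t transform with df = #usable pathways − 2; BH
adjustment pools all unordered pairs of one network level, and the mRNA and
miRNA levels are corrected separately, then merged by edge union.

Edge rule: partner e of drug d qualifies when (r ≥ 0.7 AND FDR ≤ 0.05) OR e
is among d's top ⌈0.0005·(n−1)⌉ partners by decreasing r, ties at the cutoff
included. The disjunctive reading is the default because a conjunction with
the top-0.05% rank rule would make the r/FDR thresholds nearly vacuous and
cannot produce realistic edge counts at screening scale; `--edge-rule
intersect` provides the conjunctive reading. The per-drug top rule gives
every drug with usable correlations a minimum degree of ⌈0.0005·(n−1)⌉,
which also guarantees the propagation reaches every such drug.

## Random walk with restart

pᵗ = (1−α)Apᵗ⁻¹ + αp⁰ with A the column-normalized (unweighted) adjacency,
iterated from p⁰ until ‖pᵗ − pᵗ⁻¹‖₁ < 10⁻¹⁰.

* **α = 0.7** (restart probability). Rankings are insensitive over
  0.1–0.9; the iteration contracts with factor 1−α, so convergence takes
  ~20 iterations at α = 0.7.
* **p⁰ convention.** `unit` assigns each seed mass 1; `normalized` assigns
  1/|seeds|. The walk is linear in p⁰, so the two differ by the constant
  factor |seeds| and produce identical ranks; `unit` is the default, and the
  choice only matters when comparing absolute score magnitudes across seed
  sets of different sizes.
* **Isolated nodes** keep all-zero columns; their restart mass leaks each
  iteration rather than being teleported, matching the literal update rule.
  Consequently Σp is conserved only when no zero columns exist (tested).
* The iterative solution agrees with the direct solve
  p = α(I − (1−α)A)⁻¹p⁰ to ≤ 10⁻⁹ L1 on random graphs up to 200 nodes — the
  standing oracle test for the solver.
* Ranks: decreasing score, ties broken by drug ID (deterministic).

## Permutation significance

p(d) = #{perm : score_perm(d) > score_real(d)} / n_perm with 1000
permutations by default, re-running the walk with the same seed IDs on each
randomized network; BH FDR over all drugs. The strict ">" estimator can
return p = 0; `--p-estimator add-one` gives the (count+1)/(n_perm+1)
variant for users who prefer a positively biased but never-zero estimate.

Two null models are provided:

* **rewire** (default): repeated double edge swaps — pick edges (a,b),(c,d),
  rewire to (a,d),(c,b) when no self-loop or multi-edge results; 10·|E|
  uniform attempts, illegal attempts skipped. Every node's degree is
  preserved exactly (asserted in tests across 1000 rewirings). Swap-saturated
  graphs (a triangle, a star) come back unchanged, in which case p = 0
  everywhere under the strict estimator.
* **relabel**: a uniform permutation of node labels; preserves the degree
  multiset and the unlabeled topology but not per-node degrees.

**Calibration caveat (measured, important).** The rewire null asks "is this
drug's score high given the degree sequence?" — a well-posed question — but
p-values under it are *not* uniformly distributed when the observed network
is itself atypical within its configuration-model ensemble. Correlation
networks are exactly that: they are clustered and (when sparse) fragmented,
so rewired networks mix restart mass more broadly and most drugs' null
scores stochastically dominate their real scores. On null synthetic panels
(no planted structure) this shifts rewire-null p-values upward (conservative
for candidate calling). The relabel null centres the p-values, but the
p-values of all drugs share one network realisation and are positively
dependent, so an iid-calibrated Kolmogorov–Smirnov uniformity test still
rejects in a substantial fraction of panels. The machinery itself is
calibrated: on graphs that *are* typical configuration-model draws,
rewire-null p-values are uniform (tested). Users should treat the
permutation FDRs as a ranking-stability screen, not as exact tail
probabilities.

## LOOCV / ROC

Each seed is hidden in turn and rescored from the remaining seeds; its rank
is taken among itself plus all non-seed network drugs, ties counted against
the held-out drug. The positive class pools the held-out scores; the
negative class pools every round's non-seed scores (default) or averages
them per drug (`per-round-mean`). AUROC is the Mann–Whitney pair statistic
with the 0.5 tie convention, equal to the trapezoidal area under the step
ROC (dual-oracle tested, and cross-checked against scikit-learn in the
suite — the implementation itself has no scikit-learn dependency).

## Synthetic panels

The generator emulates an NCI-60-like screen: 60 samples over 9 tissues;
pathway latent activity = tissue baseline (N(0,1)) + per-sample N(0, σ)
noise; member genes and member miRNAs follow their pathway's latent plus
N(0, σ); each of 4 planted modules of 5 drugs couples its activity to 2
signature pathways, a_d = β·Σ_P z_P + N(0, σ), with 20 uncoupled noise
drugs. Defaults β = 2, σ = 0.5. All randomness flows from a single
`rng_seed`, so identical configs are byte-identical.

Under the defaults, building the network and seeding 3 of a module's 5
drugs recovers the held-out 2 in the top 5 non-seed candidates in ≈98% of
replicates, with whole-module LOOCV AUROC ≈ 0.99 (recomputed by
`scripts/acceptance.py`; 50 replicates keep the run under a minute).

What the panels do **not** emulate: missing values in expression or
activity matrices (exercised separately by unit fixtures), non-Gaussian
expression distributions, overlapping pathway memberships, batch effects,
or dose–response curve artefacts. Passing the recovery tests shows the
pipeline's machinery is sound and sensitive at realistic panel sizes; it
does not certify performance on real screens, where signal-to-noise and
network topology differ.

## Degenerate inputs and tie rules (summary)

* Duplicate feature/drug IDs: element-wise mean ignoring missing, order of
  first appearance kept; aggregation is idempotent.
* Missing values are stored as missing (empty cell or `NA` on disk), never
  imputed to zero.
* Edge lists: canonical lexicographic endpoint order, reversed/repeated rows
  collapse, self-loops are errors; an optional weight column is annotation
  only — propagation is unweighted.
* Seed IDs absent from the network are dropped with a warning; an
  all-unmapped seed list is a hard error, as is an empty restart vector.
* ID matching is exact (no case folding): NSC identifiers are numeric
  strings, and silent folding hides join bugs.

## Known limitations

* Permutation p-values are dependent across drugs and (rewire null)
  conservative on clustered networks; see the calibration caveat above.
* The edge rule's FDR pool covers one network level at a time; a joint pool
  across mRNA and miRNA levels would be slightly more conservative.
* No teleport correction for isolated nodes: their scores are exactly the
  restart mass they receive (0 for non-seeds).
* Spearman similarity, weighted propagation, and precision–recall evaluation
  are deliberately out of scope for this version.
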