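# Methods

## Model and procedure

`countgsa` tests, for each gene set S in a collection, whether the genes of
S are coordinately differentially expressed between two phenotype classes
of an RNA-seq count matrix. Inference is purely permutational: no
distributional assumption is placed on the counts at test time. The null
hypothesis for every set is exchangeability of the sample labels; shuffling
phenotype labels (sample permutation) preserves gene–gene correlation
within sets, which is what distinguishes this design from the faster
gene-permutation null (also provided) that treats genes as exchangeable and
ignores their correlation.

Stages, in order:

1. **Pseudocount and normalization.** Every count is incremented by 1 (so
   logarithms and ratios are always defined), then each sample j is divided
   by its median-of-ratios size factor: the median over genes of
   log(x_gj) − mean_k log(x_gk), exponentiated. The median is taken in log
   space, matching the reference implementation of this normalization; at
   even gene counts this differs slightly from a ratio-space median
   (geometric vs arithmetic interpolation of the two middle values).
   No gene filter is applied: with the pseudocount no gene is degenerate.
2. **Gene scores.** All three statistics are signed, reference class minus
   comparison class, and invariant to sample order within a class:
   * Signal2Noise: (μ₁−μ₂)/(σ₁+σ₂), ddof-1 standard deviations, each
     floored at max(0.2·|class mean|, 1e−8). The floor keeps near-constant
     genes from dominating through a vanishing denominator and bounds
     |score| at 5 for positive data.
   * log2Ratio: log₂(μ₁/μ₂).
   * Signal2Noise_log2Ratio: sign(M)·√(|S|·|M|) with S and M the two above.
     This combination rule is this package's own: it is symmetric in its
     components, antisymmetric under class swap, and zero iff either
     component is zero.
3. **Gene p-values.** Per gene, two-sided and empirical: the observed
   |score| is compared against the N permutation scores of that same gene,
   p = #{π : |s_π| ≥ |s₀|}/N, ties counted in the tail, no +1 correction.
   Permutation columns get p-values by the symmetric leave-self-out rule:
   each of the N+1 columns (observed plus permutations) is compared against
   the other N. This makes the observed and permuted columns exchangeable
   under the null — a requirement for the p-value-based set statistics to
   be calibrated — while reproducing the plain-fraction formula exactly for
   the observed column. In gene-permutation mode there are no label
   permutations to build per-gene nulls, so gene p-values come from the
   cross-gene score distribution, p_g = #{g′ : |s_g′| ≥ |s_g|}/G.
4. **Set scores.** Ten statistics; observed and permuted columns go through
   identical code. Defaults in parentheses.
   * Weighted_KS: genes ranked by decreasing signed score (stable ties);
     running sum gains |s|^p/Σ_S|s|^p at members (p = 1), loses 1/(G−|S|)
     at non-members; the statistic is the running-sum extreme of largest
     magnitude, signed, with an exact +/− tie resolved to the positive
     side. If all member weights are zero the hit steps fall back to 1/|S|.
   * L2Norm: √Σ s². Mean: mean |s| (absolute values, so down-regulated
     sets remain visible to the one-sided test).
   * SigRatio: fraction of member genes with gene p ≤ α (α = 0.05);
     WeightedSigRatio: Σ_{p≤α}|s| / |S|.
   * GeometricMean: (Π p)^{1/|S|}; FisherMethod: −2 Σ ln p;
     TruncatedProduct: Π_{p≤τ} p (τ = 0.05, empty product = 1);
     MinP: min p. Before logarithms p-values are clamped at 1/(10N), since
     empirical gene p-values can be exactly 0.
   * RankSum: genes ranked genome-wide by (gene p ascending, |score|
     descending), average ranks at exact ties; the statistic is the sum of
     member ranks.
5. **Significance.** NAS = AS₀ / mean(null AS); each set's null columns are
   normalized by the same denominator. p-values, FDR and FWER are one-sided:
   ≥ on the natural scale for Weighted_KS, L2Norm, Mean, WeightedSigRatio,
   SigRatio and FisherMethod; ≤ for GeometricMean, TruncatedProduct, MinP
   and RankSum, whose small values indicate significance. FDR follows the
   pooled two-indicator permutation estimator (numerator: all null NAS;
   denominator: observed NAS), clipped to [0,1] with no isotonic step —
   note the ratio is therefore not guaranteed monotone along the NAS
   ordering, though FWER is. FWER uses the per-permutation maximum NAS for
   the ≥ family and the minimum for the ≤ family (the extreme that bounds
   the family-wise error in each direction). The signed Weighted_KS is
   treated within same-sign groups throughout: positive scores are
   normalized by and compared against the positive part of the null,
   negative against the negative part; an empty or zero-mean sign group
   yields NAS 0 (with a warning) and p = 1.
6. **Report.** One table per run: NAME, SIZE (measured genes in the set),
   AS, NAS, P-VALUE, FDR, FWER, sorted by FDR ascending with ties broken by
   NAS extremity (larger NAS first for the ≥ family, smaller first for the
   ≤ family, |NAS| for Weighted_KS) and finally by name, for determinism.

Sets are filtered to those with between `min_size` (15) and `max_size`
(100) genes *present in the data*; the retained sets store the intersected
gene lists, so SIZE reflects the measured genes. Both bounds are inclusive
and CLI-overridable; they are study choices, not method constants.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_permutations` | 2000 | permutation count N; p-values have resolution 1/N |
| `permutation_mode` | sample | sample (label shuffle) or gene (score shuffle) |
| `min_size`, `max_size` | 15, 100 | inclusive bounds on measured set size |
| `alpha` | 0.05 | gene-significance threshold of SigRatio/WeightedSigRatio |
| `tau` | 0.05 | truncation threshold of TruncatedProduct |
| `ks_exponent` | 1.0 | weight exponent of the KS running sum (0 = classic KS) |
| `seed` / `random_state` | 0 | single integer driving the whole permutation stream |

## Synthetic data

The simulator emulates a two-group bulk RNA-seq study with a planted
signal. Defaults: 1000 genes × 400 samples (200 per class), 100 gene sets;
set 1 is the causal set of 16 genes, of which 8 or 12 carry differential
expression; the other 99 sets draw 15–100 members from the 984 non-causal
genes (genes may be shared across sets). Counts are negative binomial with
variance μ + φμ², φ = 0.15, and gene baselines log₂μ ~ U(3, 10) — typical
bulk RNA-seq magnitudes. A differentially expressed gene keeps mean μ in
the reference class and has mean μ·2^(εβ) in the comparison class, with
β ~ U(effect range) and ε a random direction. Scenarios S1–S6 cross
{8, 12} causal genes with effect ranges U[0.8,1], U[1,3], U[2,4].

Design choices worth knowing:

* **One direction per dataset.** All causal genes in a replicate share the
  direction ε. Differential activity of a pathway moves its genes together,
  and the signed KS statistic can only recognize a coherently shifted set;
  with per-gene random directions the causal genes split into both tails of
  the ranking and the running-sum signal cancels. Set
  `coherent_de_direction=False` for independent per-gene directions.
* **No genotype layer.** The class-mean fold change is modelled directly;
  any upstream cause of the expression shift is outside the simulation.
* **Equal sequencing depth by default.** Size factors are ≈ 1 unless
  `depth_variation=(low, high)` draws per-sample depth multipliers, which
  exercises the normalization path.
* Effect sizes are interpreted as |log₂ fold change|, giving the intended
  weak (U[0.8,1]) to strong (U[2,4]) ordering.

What passing simulation tests do **not** show about real data: the
generator has no gene–gene correlation within sets beyond co-membership, no
gene-length or GC effects, no outlier samples, and balanced classes — so
recognition rates here are an upper bound on what correlated, noisy real
designs would give, and the advantage of sample over gene permutation is
understated (they coincide when genes are independent).

## Evaluation utilities

Recognition rate is the fraction of replicates whose top table row (FDR
sort, NAS ties) is the causal set; residual ties are broken by set name.
Power counts replicates with causal p strictly below 0.05. The cross-method
aggregation takes each method's top-K (30) sets, keeps sets reaching the
top K in at least `min_methods` (4) methods, and sorts by the average of
their within-top-K ranks; a 0 rank marks "outside top K for that method".
Averages are displayed to 2 decimals, computed at full precision.

## Numerical conventions and degenerate inputs

* Empirical p-values are plain fractions with ties in the tail; they can be
  exactly 0, hence the 1/(10N) clamp before logarithms.
* The calibration consequence of the discreteness: with the ties-in-tail
  convention, P(p < α) slightly undershoots α for very discrete statistics
  (MinP especially, whose gene-p atoms have mass ≈ |S|/(N+1)); at the
  default N = 2000 all ten statistics are within ±0.02 of nominal at
  α = 0.05 in the null-calibration test, but MinP degrades sharply at
  small N.
* Weighted_KS with a set covering every gene, an empty set anywhere, or
  fewer than 2 samples in a class is an error; a set absent from the data
  is dropped at filtering.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; replicate seeds are spawned via
  `SeedSequence` and kept below 2³¹. Repeated runs are bit-identical.

## Scale of the shipped checks

The test suite and the reproduction script run the simulator at 50
replicates and 200 permutations per pipeline run for the recognition-rate
checks (the causal signal at these scenarios is far above the decision
boundary, so 200 permutations resolve rank 1 comfortably), and at 40
replicates × 2000 permutations on 300-gene null datasets for the
calibration checks. These sizes are the package's own test design; the
library itself has no built-in limits.

## Known limitations

* The ten statistics cover two-class designs only; no multi-class or
  continuous phenotypes, and no covariate adjustment.
* The FDR estimator is the pooled permutation ratio; it is not monotone by
  construction and can be conservative or anti-conservative for small m.
* Gene-permutation mode ignores gene–gene correlation; its p-values are
  known to be optimistic for correlated sets. It exists for speed and for
  comparison with list-based approaches.
* Extreme p-values are bounded below by 1/N; there is no tail
  approximation beyond the permutation resolution.
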