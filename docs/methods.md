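# Methods

## Data model

A dataset is an m × n matrix of genotype codes over Σ = {1, 2, 3}
(1 = major homozygote, 2 = minor homozygote, 3 = heterozygote) with a
case/control label per sample.  Missing genotypes are rejected at load time
rather than imputed: every downstream statistic is a carrier count, and
silent imputation would bias counts in a way the user cannot see.  Indices
are 0-based in the API and 1-based in all rendered output (`SNP2(3)` means
the second SNP at genotype 3).

A pattern is a set of (SNP, genotype) requirements; carrier status is the
exact conjunction.  Matching is therefore monotone: extending a pattern can
only shrink its carrier set.

## Association statistics

For a pattern's 2×2 carrier table (a, b; c, d):

* fitness F = |a/(a+b) − c/(c+d)|, the swarm's objective;
* odds ratio a·d/(b·c).  A zero cell makes it undefined and the package
  says so; a Haldane–Anscombe +0.5 correction is available behind a flag
  (default off) and is used internally only where a finite value is
  operationally required (emotional inputs for patterns with an empty cell
  in a training fold);
* Woolf (log-normal) interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)), z =
  Φ⁻¹(0.975) = 1.959964 at the 95% level.  This choice reproduces published
  interval endpoints at printed precision for large-cell tables; it is not
  appropriate for near-empty cells (where the log-normal approximation
  fails), and the package makes no exact-interval claim there;
* significance via Fisher's exact test (scipy), two-sided by default.  The
  test suite checks it against a full hypergeometric enumeration.

The report's "difference" column is |a − c|, exact when the two groups have
equal size (the design this package targets); with unequal groups it falls
back to the proportion difference scaled by the smaller group and is
flagged.

## Hierarchical binary PSO

Encoding: 2 bits per SNP — (0,0) unselected, (0,1)→1, (1,0)→2, (1,1)→3 —
so the codec is a bijection between bit vectors and patterns.

Leaders (top-K by current fitness, ties to the lower particle index) evolve
by standard binary PSO: velocity v ← v + c₁r₁(p_best − x) + c₂r₂(p_g − x)
clipped to ±Vmax, each bit resampled as Bernoulli(S(v)) with the sigmoid
transfer S.  The global attractor p_g is the best personal best among the
current leaders.  Followers hold a per-bit probability vector initialised
at 0.5: where the leaders' mean bit is ≥ 0.5 (ties count as up) the
probability rises by 1/α_LIF, capped at 1, else it falls by the same step,
floored at 0; the follower's velocity is the logit of that probability with
±Vmax at the caps, and its bit is sampled from the probability.  Roles are
reassigned every iteration.  A baseline mode makes every particle a leader,
which is plain BPSO.

Pattern order is controlled, when requested, by a repair operator applied
after every position update: while the decoded order exceeds k a uniformly
random selected SNP is deselected; while it falls short a random unselected
SNP is selected with a uniformly random genotype.  Unconstrained search is
also available.

Every decoded pattern is evaluated once (fitness cached by canonical
pattern) and archived; the result is the archive filtered to the requested
order and a minimum fitness, ranked by fitness with a deterministic
tie-break.  This matters for multiplicity: real studies report many
interactions, and the archive plus multi-seed restarts recovers several
without niching machinery.

### Default constants

None of the swarm constants is prescribed by the method, so the defaults
are engineering choices, fixed by benchmarking planted-pattern recovery on
synthetic data (20 SNPs, 1000+1000 samples, one planted pair at fitness
≈ 0.2, order 2) across independent data seeds:

| parameter | default | why |
|---|---|---|
| swarm_size | 50 | recovery saturates near here at desk scale |
| n_leaders K | 10 | a broader leader set keeps the follower majority diverse |
| c₁ = c₂ | 2.0 | standard PSO acceleration |
| Vmax | 4.0 | S(−4) ≈ 0.018 keeps converged leaders exploring; at 6 the swarm freezes and recovery drops to ~70% |
| α_LIF | 50 | follower probabilities stay mid-range for dozens of iterations; small values collapse the swarm early |
| max_iter | 200 | comfortable margin at these sizes |
| archive_min_fitness | 0.01 | drops pure-noise patterns from reports |

With the defaults the search recovered the exhaustive-search optimum in
59–60 of 60 runs (3 data seeds × 20 swarm seeds) in the benchmark above.

## Emotional neural network

Inputs: raw genotype codes (a standardization flag exists, default off)
concatenated with the emotional vector S_e (entry q = interaction q's odds
ratio if carried, else 0).  The amygdala path v has length n+2p because the
emotional inputs enter twice — once inside S_all, once through the
dedicated short path; this duplicated route is the faithful architecture
and the default, with a flag to collapse it to a single path.  The
orbitofrontal (OFC) path w has length n+p throughout (activation, reward
and update), the internally consistent reading of the defining equations.
hardlim(0) = 1, the standard hard-limit convention; the boundary is hit
only by an all-zero model.

Learning, per presented sample (R₁ = 1 for a case, 0 for a control):

    Ea₁′ = hardlim(v[:n+p]·S_all)        Eo₁ = hardlim(w·S_all)
    R₀   = −Eo₁                 if R₁ = 1
         = max(Ea₁′ − Eo₁, 0)   if R₁ = 0
    v ← (1−γ)v + α·max(R₁ − Ea₁′, 0)·input
    w ← (1−γ)w + β·R₀·S_all

The R₁ = 0 reward branch is written in the source model without a second
max argument; it is read as max(Ea₁′ − Eo₁, 0) by symmetry with the BELBIC
family it derives from.  "Ea₁" in the amygdala update is identified with
Ea₁′, the only defined amygdala activation.

**A structural property worth stating plainly:** with the conventional
all-zero initialization, non-negative inputs, and hardlim(0) = 1, the
amygdala activation is 1 from the first sample on, so max(R₁ − Ea₁′, 0) = 0
always and v never leaves zero.  The trainable component is the OFC path,
which under these rules behaves exactly as a decayed perceptron whose
*negative* activation votes "case": a case predicted control gets
R₀ = −1 (w moves down its input), a control predicted case gets R₀ = +1,
correct predictions leave w unchanged apart from decay.  The emotional
inputs still do their job — they enter the OFC input with odds-ratio
magnitude, giving carried interactions a large, signed influence.  Because
the model has no bias unit, the always-positive genotype codes act as a
surrogate intercept.  On non-separable data the perceptron churns, so
held-out accuracy depends on where an epoch ends; the per-epoch training
accuracy trace is returned so users can see this.

Defaults: α = β = 0.1, γ = 0.01, 100 epochs, all-zero weights, one online
pass per epoch in a seeded shuffle.  None is prescribed by the method.
Test-time prediction uses no reinforcement signal; E = 1 labels a case, and
the continuous score (amygdala sum − OFC sum) is exposed for ranking.

## Evaluation protocol

Confusion statistics (positive = case): Sn, Sp, Acc, risk ratio
TP(FP+TN)/(FP(TP+FN)), odds ratio TP·TN/(FP·FN).  Zero-denominator
statistics are reported as undefined, never silent NaN, and excluded from
cross-fold means with an exclusion count.

Cross-validation is stratified k-fold (k = 5 by default).  Inside each fold
the interactions are discovered on the training split only — or, in
known-pattern mode, their odds ratios are re-estimated on the training
split only — and the network is trained on the training split; the held-out
fold contributes metrics only.  Fold discovery uses the configured swarm
with a per-fold seed offset so folds are independent searches.

## Synthetic data

Background SNPs are iid per-SNP categorical draws, identical in both
classes; the default genotype frequencies (0.49, 0.09, 0.42) are the
Hardy–Weinberg proportions at minor-allele frequency 0.3 under this coding.
For each planted pattern (disjoint SNP sets), carrier status is Bernoulli
per sample at the class's carrier probability; carriers get the pattern's
genotypes, non-carriers have the pattern's SNPs redrawn from the background
until the full pattern fails (rejection sampling, capped at 1000 rounds —
any pattern of genotype mass < 0.999 terminates almost immediately).
`or_to_carrier_probs` inverts the odds-ratio definition so a target OR can
be planted: p_case = t/(1+t), t = OR·p_control/(1−p_control).

What this emulates: per-SNP genotype frequencies and multi-SNP carrier
effects of controlled size.  What it does not: linkage disequilibrium
between background SNPs, population stratification, genotyping error,
missingness, or interacting patterns on shared loci (a full penetrance
model would be needed; deferred).  Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted effects under
clean conditions — not performance on real cohorts.

## Problem sizes used in the checked examples

The automated checks run at desk scale, chosen to make each property
measurable in seconds to a couple of minutes: interaction statistics are
exact recomputations from published carrier counts (5000 + 5000 by
construction); swarm recovery uses 20 SNPs at 1000 + 1000 samples against
exhaustive enumeration of all 1710 pair patterns over 20 seeded runs; the
emotional-path ablation uses 300 + 300 samples, 20 SNPs, three planted
patterns, 10 simulation seeds × 5 folds; simulator calibration uses 100
simulations at 5000 + 5000.

## Known limitations

* The search is heuristic; at GWAS scale (10⁵–10⁶ SNPs) neither the
  encoding length nor the fitness evaluation cost has been engineered for,
  and exhaustive validation is impossible.
* The classifier's amygdala path is inert under the default zero
  initialization (see above); this is a faithful property of the model, not
  a bug, but users expecting two learnable paths should know.
* Fitness ranks patterns by raw carrier-proportion difference with no
  multiple-testing control; the Fisher p-values in reports are per-pattern
  and unadjusted.
* Carrier probabilities, not penetrance matrices, define planted effects;
  marginal single-SNP signal leaks from planted patterns by construction
  (carriers fix their genotypes), which is realistic but worth remembering
  when interpreting ablations.
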