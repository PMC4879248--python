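# episwarm

Discovery of SNP–SNP genotype-pattern interactions in case-control data, and
risk scoring that feeds those interactions into a brain-inspired "emotional"
neural network.

## Who this is for

Association studies of complex disease (the motivating application is breast
cancer) usually score single markers, yet much of the signal can live in
joint multi-locus genotype patterns — epistasis.  `episwarm` provides:

1. **a hierarchical binary particle swarm (BPSOHS)** that searches the space
   of genotype patterns for those whose carrier frequency differs most
   between cases and controls,
2. **classical association statistics** for any pattern's 2×2 carrier table
   (odds ratio, Woolf confidence interval, Fisher exact p), and
3. **an emotional neural network (ENN)** classifier that treats the
   discovered interactions as a priori *tendency* inputs on a dedicated
   short path, alongside the raw genotypes,

plus a seed-deterministic synthetic genotype simulator with planted
interactions, so the whole pipeline is testable without access data.

## The model

Genotypes are coded on Σ = {1, 2, 3} (major homozygote, minor homozygote,
heterozygote).  A *pattern* C is a conjunction of (SNP, genotype)
requirements; a sample carries C iff all requirements hold.  With `a` of
n_case cases and `c` of n_control controls carrying C:

* search objective (fitness): F(C) = |a/n_case − c/n_control|
* odds ratio: OR = a·d / (b·c), with Woolf interval
  exp(ln OR ± z·√(1/a + 1/b + 1/c + 1/d))

**Search.** Each particle encodes a pattern as 2 bits per SNP
((0,0) unselected; (0,1)/(1,0)/(1,1) = genotypes 1/2/3).  The top-K
particles are *leaders* and move by standard binary PSO
(v ← v + c₁r₁(p_best − x) + c₂r₂(p_g − x), bit ~ Bernoulli(S(v)) with
S the sigmoid); the rest are *followers* whose per-bit probabilities drift
by 1/α_LIF toward the leaders' majority bit.  Every evaluated pattern is
archived, so a run yields a ranked interaction table, not a single optimum.

**Classifier.**  For p discovered interactions, a sample's emotional vector
S_e has entry q equal to interaction q's odds ratio if carried, else 0; the
full input is S_all = (S, S_e).  Two threshold paths compete — an excitatory
amygdala path v (length n+2p; it receives the emotional inputs twice, once
inside S_all and once on a dedicated short path) and an inhibitory
orbitofrontal path w (length n+p):

    E = hardlim(Σ v·input) − hardlim(Σ w·S_all),   E = 1 ⇒ case

Training is online reinforcement (R₁ = 1 when a case is presented):
v grows by α·max(R₁ − Ea₁′, 0), w by β·R₀ with decay γ, where Ea₁′, Eo₁ are
the two path activations and R₀ the derived reward.

## Worked example

Simulate 300 cases + 300 controls over 20 SNPs with three planted pair
patterns (carrier probability 0.40 in cases vs 0.10 in controls), then
search:

```python
from episwarm import (BPSOHS, PlantedPattern, SNPPattern, SimulationSpec,
                      SwarmConfig, kfold_evaluate, simulate_case_control)

patterns = [SNPPattern([(0, 3), (1, 1)]), SNPPattern([(4, 2), (5, 3)]),
            SNPPattern([(8, 1), (9, 3)])]
spec = SimulationSpec(m_case=300, m_control=300, n_snps=20,
                      planted=[PlantedPattern(p, 0.4, 0.1) for p in patterns],
                      seed=0)
data = simulate_case_control(spec)
print(BPSOHS(data, SwarmConfig(seed=42)).fit().summary(data.snp_ids, top=4))
```

```
Hierarchical binary PSO interaction search
  swarm 50 (leaders 10), 200 iterations, seed 42
  1421 distinct patterns evaluated, 986 archived (fitness >= 0.01)
         pattern  order  case_carriers  control_carriers  difference  fitness  odds_ratio       ci_95      p_value
SNP9(1)-SNP10(3)      2            110                30          80 0.266667       5.211 3.341-8.125 6.013838e-15
 SNP1(3)-SNP2(1)      2            108                35          73 0.243333       4.259 2.787-6.508 2.176715e-12
SNP2(1)-SNP10(3)      2            107                38          69 0.230000       3.822 2.526-5.784 4.589703e-11
SNP6(3)-SNP10(3)      2            104                36          68 0.226667       3.891 2.552-5.932 5.001187e-11
```

The two top hits are planted patterns recovered exactly (1-based naming:
`SNP9(1)-SNP10(3)` is the pattern on 0-based SNPs 8 and 9), with their
carrier counts, the case−control carrier gap, the odds ratio and its Woolf
95% interval, and the Fisher exact p-value.  Ranks 3–4 are correlation
shadows of the planted patterns, a real feature of such data.

Does feeding the interactions to the classifier help?  Stratified 5-fold
cross-validation, with the interaction odds ratios re-estimated on each
training split (never the held-out fold):

```python
with_ = kfold_evaluate(data, k=5, seed=0, known_patterns=patterns,
                       enn_params={"epochs": 50})
without = kfold_evaluate(data, k=5, seed=0, known_patterns=[],
                         enn_params={"epochs": 50})
```

```
with interactions   : {'sensitivity': 0.5333, 'specificity': 0.7333, 'accuracy': 0.6333, 'risk_ratio': 2.7716, 'odds_ratio': 4.4363}
no-emotion ablation : {'sensitivity': 0.25, 'specificity': 0.8533, 'accuracy': 0.5517, 'risk_ratio': 2.2323, 'odds_ratio': 2.6649}
```

The tendency inputs lift mean held-out accuracy from 0.55 to 0.63 on data
whose class signal lives only in the planted patterns.

The same pipeline is available from the shell:

```
episwarm simulate --spec spec.yaml --out synth.csv
episwarm detect   --genotypes synth.csv --order 2 --seed 42 --out interactions.tsv
episwarm train    --genotypes synth.csv --interactions interactions.json --model model.json
episwarm predict  --model model.json --genotypes synth.csv --out preds.tsv
episwarm evaluate --genotypes synth.csv --folds 5 --seed 7 --out report.tsv
episwarm run      --config run.yaml      # detect -> train -> evaluate + manifest
```

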