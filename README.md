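# mavc — choice-consistency analysis for multi-attribute visual choice

`mavc` implements the complete computational pipeline of a memory-based
visual decision paradigm analysed with revealed preference theory.  It is
aimed at decision scientists and cognitive modellers who want to (1)
construct budget-line choice sets for multi-attribute visual stimuli, (2)
score choice data for consistency with the Generalized Axiom of Revealed
Preference (GARP), and (3) run the associated Bayesian analyses — all
exercisable end-to-end on synthetic data.

## The science in brief

Each trial offers five visual objects that trade off orientation similarity
to a remembered exemplar along the X- and Y-axis.  The options are built
from a token budget `m = 100` and per-axis prices `(p_x, p_y)` as
equidistant points on the budget line `x·p = m`, so no option dominates.
Scoring a block of choices then reduces to classic revealed-preference
computations:

* `x_i R_D x_j` iff `x_j·p_i ≤ m_i` (and `x_i ≠ x_j`); `R` is the transitive
  closure; GARP forbids `x_i R x_j` together with `x_j P_D x_i`.
* **CCEI** (Afriat's critical cost efficiency index): the largest budget
  deflation `e` under which the relaxed relations satisfy GARP — 1 means
  perfectly consistent; computed by binary search with an exact
  breakpoint-enumeration oracle.
* **Houtman–Maks**, **money pump** and **minimum cost** indices quantify
  violations by observations removed, arbitrage cost of violating cycles,
  and cheapest relation-slack removal respectively.

On top of the scoring sit the study's statistical analyses: a one-sided
Bayes factor for Kendall's tau between retention interval and CCEI, a
product-space (transdimensional MCMC) Bayes factor comparing an exponential
forgetting model `μ_t = a + (1−a)·b·e^(−αt)` against a constant-mean null
(both with truncated-normal observation noise on [0, 1] and uniform priors),
a replication Bayes factor via evidence updating, reconstruction-task
manipulation checks, and a bootstrap comparison of reconstruction error
against choice-set orientation increments.  See `docs/methods.md` for the
full model descriptions and numerical choices.

## Worked example

Score a simulated dataset and test the directional hypothesis:

```python
import numpy as np
from mavc.synthetic_data import simulate_ccei_dataset
from mavc.association import bf_kendall_onesided
from mavc.revealed_preference import ObservationSet, ccei, garp_violations
from mavc.synthetic_data import ChooserSpec, simulate_chooser_block

# a deterministic utility maximizer is perfectly consistent
rng = np.random.default_rng(0)
block = simulate_chooser_block(rng, ChooserSpec(kind="linear-utility", w=0.6), t=5.0)
obs = ObservationSet.from_block(block)
print(len(garp_violations(obs)), ccei(obs))   # -> 0 1.0

# forgetting-curve data show a strong negative RI-consistency association
data = simulate_ccei_dataset(np.random.default_rng(4), n=120)
res = bf_kendall_onesided(data.t, data.ccei, alternative="negative")
print(round(res.diagnostics["tau"], 3), f"{res.bf10:.3g}")
# -> -0.31 6.48e+04
```

The first two numbers say the maximizer produced zero GARP violations and a
CCEI of 1 (the Afriat direction).  The last line shows Kendall's tau ≈ −0.31
between retention interval and consistency, with a Bayes factor around
6 × 10⁴ — overwhelming evidence for the inverse relationship that the
forgetting model builds in.

The same operations are available from the shell:

```bash
mavc simulate-random --n 1000 --seed 1 --out random.csv
mavc consistency --in random.csv --out scores.csv
mavc sensitivity --n 1000 --seed 1
mavc simulate-forgetting --n 300 --seed 1 --out ccei.csv
mavc h1 --in ccei.csv
mavc model-compare --in ccei.csv --seed 1
```

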