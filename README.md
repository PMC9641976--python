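# karyodyn

Forward-time population dynamics of an unusual *Drosophila melanogaster*
karyotype system in which **every individual — female or male — must carry a
Y-derived chromosome**, plus the companion empirical procedures: karyotype
count tallies and ddPCR copy-number karyotype calling.

## The scientific problem

In a *D. melanogaster* strain isolated from the Seychelles archipelago, the X
chromosome has lost its ribosomal DNA (rDNA) locus. rDNA is essential for
viability and the Y chromosome carries the only other rDNA locus, so XX
females are inviable and all females carry at least one Y-type chromosome.
Two Y variants segregate in the population:

* the **full-length Y**, carrying rDNA and the male fertility factors
  (*kl-2*, *kl-3*, *kl-5*); and
* a **truncated Y (Y^S)**, retaining rDNA but lacking the long-arm fertility
  factors — it supports viability but not male fertility.

Despite being useless for male fertility, Y^S makes up roughly half of all
Y-type chromosomes (52.38% in scored females). `karyodyn` implements the
model that explains this: extra Y heterochromatin burdens females
(oogenesis, lifespan), and if the full-length Y costs females sufficiently
more than the truncated Y^S, selection through females maintains Y^S
against its fertility disadvantage in males.

## The model

Karyotypes are multisets (n_X, n_Y, n_Y^S); sex follows the X count
(2 → female, 1 → male). Female fitness:

| genotype | fitness |
|---|---|
| XX | 0 (no rDNA source) |
| XXY^S | 1 − h·s |
| XXY | 1 − h′·y |
| XXY^SY^S | 1 − s |
| XXYY | 1 − y |
| XXYY^S | 1 − [(1 − h″)·s + h″·y] |

with *s*, *y* the two-copy female costs of Y^S and Y, dominance
coefficients h = h′ = h″ = 0.5 by default, and costs in [−1, 1] (negative =
beneficial). Male fitness is binary: 1 with ≥1 full Y and ≤2 Y-types, 0 for
Y^S-only males (sterile) and XYYY; the triple-Y genotypes XYYY^S and
XYY^SY^S get 0.1.

Meiosis: female X's pair and segregate (all eggs carry one X); a lone
Y-type accompanies one X at random (XXY → ½ X, ½ XY eggs); two Y-types
pair so each egg gets exactly one. Male sex-chromosome tri-/quadrivalents
partition randomly between the meiosis-I poles (XYY^S → the three splits
X|YY^S, XY|Y^S, XY^S|Y at ⅓ each).

Each Wright–Fisher generation, individuals contribute fitness-weighted
gamete distributions to per-sex pools; N = 100 zygotes are drawn as
independent egg × sperm pairs. The summary statistic is the **Y^S share**:
Y^S / (Y + Y^S) chromosomes, pooled over both sexes. A deterministic
infinite-population recursion (`deterministic_run`) serves as an oracle for
the stochastic engine.

## Worked example

```bash
python analysis/01_tally_karyotypes.py
python analysis/02_simulate_trajectories.py
```

prints (abridged):

```
females: n = 48, Y-type chromosomes = 63 (Y 30, Y^S 33)
  Y : Y^S = 47.62% : 52.38%
equal_costs (y=0.5, s=0.5):
  replicates losing Y^S by generation 200: 100/100
  mean Y^S share at generations 0/50/100/200: 0.492 / 0.003 / 0.000 / 0.000
twofold_cost (y=0.8, s=0.4):
  replicates losing Y^S by generation 200: 8/100
  mean Y^S share at generations 0/50/100/200: 0.492 / 0.324 / 0.296 / 0.309
```

Reading: the observed strain carries 63 Y-type chromosomes in 48 females,
52.38% of them truncated. If the two chromosomes cost females equally
(y = s = 0.5), the male-sterile Y^S is lost from all 100 simulated
populations within 200 generations — its observed abundance is then a
paradox. If the full-length Y costs females twice as much (y = 0.8,
s = 0.4), both chromosomes persist in 92/100 populations with Y^S at ~30%
of Y-types, matching the qualitative picture in the strain.

The cost-plane sweep and the ddPCR caller characterization:

```bash
python analysis/03_cost_sweep.py      # ~40 s; persistence > 90% where y − s > 0.5
python analysis/04_ddpcr_karyotyping.py
```

Library use mirrors the scripts:

```python
from karyodyn import SimConfig, FitnessParams, run_replicates

config = SimConfig(params=FitnessParams(s=0.4, y=0.8), seed=11, replicates=100)
trajectories = run_replicates(config)
```

A `karyodyn` CLI exposes the same steps (`simulate`, `sweep`, `tally`,
`call-ddpcr`, `synth`, `gamete-table`); see `karyodyn --help`.

## ddPCR karyotyping

Copy-number ratios from digital droplet PCR are converted to integer
karyotypes: Pp1-Y2/RpL32 counts all Y-types, PRY/RpL32 full-length Y's
only, Upf1/RpL32 the X dose. Primer-efficiency differences make one copy
read ≈0.8 on the Y assays, so ratios are divided by a per-assay efficiency
before half-up rounding; Y^S = total − full, and ambiguous ratios (>0.25
from an integer after normalization) are flagged rather than rejected.

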