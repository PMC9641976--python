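# Methods

## Model

The population is a discrete-generation Wright–Fisher model over
sex-chromosome karyotypes (n_X, n_Y, n_Y^S) in a genetic background where
the X carries no usable rDNA, so every viable individual needs at least one
Y-type chromosome (full-length Y or truncated Y^S). Sex is set by the
X:autosome ratio — two X's female, one X male; other X doses are outside
the model and assigned fitness 0. Generations do not overlap; population
size is fixed; there is no mutation (Y^S cannot arise de novo, and the
X-fusion chromosomes that eventually arose in real populations are not
modeled), no migration, and no recombination.

### Fitness

Female fitness encodes the heterochromatin burden of Y-type chromosomes on
oogenesis and lifespan. Two-copy costs are `s` (Y^S Y^S) and `y` (YY), each
in [−1, 1]; single-copy costs are scaled by dominance coefficients
`h` (Y^S) and `h_prime` (Y); the YY^S heterozygote interpolates with
`h_dblprime`: fitness 1 − [(1 − h″)s + h″y], so h″ = 0 reproduces the
Y^SY^S homozygote and h″ = 1 the YY homozygote. All three dominance
coefficients default to 0.5. XX females (no rDNA) and females with three or
more Y-type chromosomes have fitness 0; the latter is a closure rule — the
defined cost table covers at most two Y-types, and Y-dose toxicity grows
with copy number, consistent with the near-absence of triple-Y individuals.
Fitness is clamped below at 0; negative costs (beneficial chromosomes) may
push fitness above 1 and are left unclamped.

Male fitness is fertility: 1 with at least one full-length Y and at most
two Y-types; 0 for males whose only Y-type chromosomes are Y^S (missing
the axonemal-dynein fertility factors) and for the classically sterile
XYYY; the triple-Y-type genotypes XYYY^S and XYY^SY^S get a small fitness
`m3` (default 0.1, matching the rarity of triple-Y individuals); four or
more Y-types extend the XYYY rule to 0.

### Meiosis

Eggs: the two X's pair and segregate, so every egg carries exactly one X
(X nondisjunction is ignored). A single Y-type is a univalent that follows
one X at random — XXY gives ½ X and ½ XY eggs. Two Y-types pair with each
other and segregate, one per egg, each variant equally likely when they
differ. Egg distributions for females with ≥3 Y-types are deliberately an
error: such females have fitness 0 and can never be asked for gametes.

Sperm: the X and the 1–3 Y-types form a bivalent, trivalent or
quadrivalent that partitions randomly at meiosis I. "Random" is
implemented as uniform over the labeled assignments of the (individually
tracked) chromosomes to the two poles, excluding empty poles; either pole
then becomes the sperm with probability ½ (meiosis II faithful). For a
trivalent this is exactly the observed behavior — three equiprobable 1|2
splits. For quadrivalents the same rule admits 1|3 splits; since direct
observations of quadrivalent behavior are not available, a
`splits="balanced_only"` switch restricts them to 2|2 partitions. The
default extends the trivalent rule because it is the unique uniform
assignment rule that reproduces it. Identical chromosomes (e.g. two full
Y's) are enumerated as distinguishable and collapsed afterwards, which
yields the correct multiplicities (XYY → ⅓ XY, ⅓ Y, ⅙ X, ⅙ YY).

### Generation cycle

Each individual contributes fitness × its gamete distribution to its sex's
pool; pools are summed over individuals and normalized. N zygotes are
formed by independent (egg, sperm) draws — a single multinomial over the
product distribution — and sexed by their X count. Offspring sex ratio is
therefore emergent, not constrained. An empty pool (no fit females or no
fertile males) terminates the run with an extinction flag and a truncated
trajectory.

Generation 0 holds N/2 females and N/2 males drawn multinomially from the
observed strain karyotype frequencies (females: XXY .375, XXY^S .3125,
XXYY .0625, XXY^SY^S .125, XXYY^S .125; males: XY .24, XY^S .18, XYY .16,
XY^SY^S .14, XYY^S .26). The printed male values cover 49/50 scored males
and sum to 0.98; they are renormalized at configuration time. The fixed
even starting sex ratio avoids degenerate all-one-sex starts at N = 100;
it is a documented choice, overridable through `SimConfig`.

### Summary statistics

The Y^S share is Y^S / (Y + Y^S) chromosomes pooled over both sexes
(per-sex shares are recorded alongside), NaN when no Y-type exists. The
sweep summarizes each (y, s) cell by (i) the mean Y^S share over
generations 1–100 and (ii) the persistence probability — the fraction of
replicates with at least one Y^S chromosome at generation 100 (the end of
the averaging window; a population-extinct replicate counts as
non-persistent). After whole-population extinction the last defined share
is carried forward for the window average (switchable to NaN-padding).
Replicate seeds derive from (root seed, cell coordinates, replicate index)
via `numpy` seed sequences, so results are independent of traversal order.

## Deterministic oracle

`deterministic_run` iterates the expected-frequency recursion (the
infinite-population limit): pools are computed from genotype frequencies
instead of counts and the zygote product distribution is carried forward
without sampling. The stochastic engine is validated against it in the
test suite. Two statistical cautions shape that test. First, within-sex
genotype frequencies of a finite population are ratios of random counts,
so their replicate mean carries an O(1/N) bias relative to the
infinite-population iterate; the comparison therefore runs at N = 1000,
where the bias sits below the Monte-Carlo resolution of a 200-replicate
mean. Second, ~440 (generation × genotype) comparisons are made, so a
zero-exceedance 3-standard-error band would be violated by chance alone;
the test requires the pooled Y^S share within 3 SE at every generation,
≥99% of per-genotype comparisons within 3 SE, and a worst absolute
frequency deviation below 0.01.

## Empirical procedures

Karyotype count tables (TSV: sex, genotype, count) are tallied into
within-sex genotype frequencies and exact integer chromosome totals; the
genotype string grammar is X's, then Y's, then "YS" tokens (XXYYS ↔
(2,1,1)), case-insensitive, with `^` accepted and ignored.

ddPCR calling converts copy-number ratios to integers. One copy of a Y
target reads ≈0.8 of the autosomal reference because of primer-efficiency
differences, so each ratio is divided by a per-assay efficiency (default
0.8 for the two Y assays, 1.0 for X — the X assay behaves as an ordinary
two-copy reference in females and there is no basis for a correction
there) and rounded half-up. Y^S count = total Y-type (Pp1-Y2) − full
length (PRY), floored at 0 with a flag when noise makes it negative.
Normalized values more than 0.25 from an integer set a low-confidence
flag rather than failing, so noisy real data degrade to flagged calls; an
X dose outside {1, 2} is an error since no modeled karyotype fits.
Droplet-level Poisson statistics are out of scope — the ratios arriving
here are already vendor-software estimates.

## Synthetic data

The generator emulates the two empirical inputs. Karyotype tables are
multinomial draws per sex from a stated distribution (defaults: the
observed strain frequencies, n = 48 females / 50 males). ddPCR ratios are
efficiency × true copy number plus independent additive Gaussian noise per
assay, truncated at 0 — the simplest model consistent with single-copy
measurements clustering near 0.8. At zero noise the generator is the exact
inverse of the caller, which the round-trip tests exploit. What passing
these tests does not show: real ddPCR noise is closer to
count-proportional than additive, real karyotype samples can contain
genotypes outside the modeled set, and the generator cannot reveal
systematic biases shared by caller and generator (the efficiency model
itself).

## Problem sizes and numerics

Defaults follow the study conditions: N = 100, 200 generations,
h = h′ = h″ = 0.5, m3 = 0.1, observed initial frequencies. The analysis
sweep driver uses an 11 × 11 grid (step 0.1) with 40 replicates per cell
as its standard configuration and offers `--fine` for the 21 × 21 /
100-replicate grid; the persistence checks in the test suite use 100
replicates per cell, giving a binomial standard error of ≈3% at the 90%
persistence level. Gamete distributions are exact rational-valued floats
(denominators ≤ 14), pools normalize by direct summation, and probability
sums are kept to 1 within 1e−12. Trajectory TSVs round-trip losslessly
when read with pandas' `float_precision="round_trip"`.

## Known limitations

The model omits everything that made the real populations interesting
beyond Y^S maintenance: de novo Y truncations, X–Y fusions (the X*/X**
chromosomes that ultimately freed females from the Y), X nondisjunction,
autosomes, and varying population size. Quadrivalent segregation is an
extrapolated rule (see above). Persistence is defined at the end of the
100-generation window; the alternative reading — presence at generation
200 — is available by passing a different window.
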