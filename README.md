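# invgen — population genomics of chromosomal inversion polymorphisms

`invgen` is a toolkit for analysing polymorphic paracentric inversions in
*Drosophila melanogaster*-style population genomic data.  Because
recombination with the standard arrangement is strongly suppressed near
inversion breakpoints, the haplotypes sampled just inside a breakpoint record
the genealogical history of the inversion itself.  The package estimates how
old an inversion is and where it arose, and tests two selective hypotheses
about why young inversions spread — all from breakpoint-region haplotype
alignments plus ordinary annotation and cross-count tables.

It is aimed at population geneticists who have phased, pre-aligned haplotype
panels (an African-diversity panel plus a bottlenecked cosmopolitan panel)
with known inversion genotypes.

## What it computes

**Inversion ages by rejection ABC.**  Each inversion is modelled as a
population founded at the inversion event that has grown exponentially ever
since.  With time in units of 4N₀ generations (growth rate α in 1/(4N₀)),
parameters are drawn from

  θ ~ U(0, 10·θ̂),  α ~ U(0, α_max),  θ̂ = 4(N_e f)·μ_region,
  μ_region = d/(2 t_gen) · L,

where d is per-site divergence to the sister species, t_gen the species split
in generations (3×10⁷ by default), N_e = 10⁶, f the inversion's sample
frequency, and L the aligned region length.  A draw is accepted when the
simulated segregating-site count S and region diversity π both fall within 5%
of the observed values (exact match for zero observations); sampling runs to
at least 10,000 acceptances.  Accepted draws convert to ages in years as

  age = T_MRCA · θ / μ_region-per-year.

**Divergence-based ages**: T = (π_between − π_standard) / (2μ), the classical
net-divergence clock, with negative values flagged as consistent with a very
recent origin.

**Geographic origin**: an inversion is called cosmopolitan only when its
nearest-neighbour standard haplotype is French *and* its mean divergence to
French standards is below its mean divergence to African standards;
otherwise African (ties escalate to ambiguous).

**Exchange-tract masking**: gene flux between arrangements shows up as runs
of shared polymorphisms on an inverted haplotype.  Runs of ≥3 consecutive
shared alleles (excluding SNPs within 10 columns of an indel) are masked,
and heavily masked haplotypes are dropped.

**Summary statistics and scans**: π, Watterson's θ_W, Tajima's D, D′ (D
rescaled by its all-singleton minimum), between-group π, unweighted Hudson
F_ST = 1 − H_w/H_b, in fixed-bp or fixed-segregating-site windows.

**Selection tests**: a permutation test for whether breakpoints interrupt
genes less often than uniform placement predicts (add-one lower-tail p), and
one-sided exact binomial tests for sex-ratio distortion in crosses
(K = proportion of females), with Bonferroni correction and a conservative
variant charging all egg-to-adult mortality to males.

**Assembly QC arithmetic**: divergence = mismatches/aligned-bases accounting,
exact Poisson upper bounds on consensus error counts, Phred conversion, a
minimum-depth-3 pileup consensus, and a depth-titration bootstrap.

**Synthetic data**: `invgen.synthetic` generates complete datasets (African
and bottlenecked cosmopolitan standards, an inverted clade of configurable
age and origin, exchange tracts, indels, missing data, annotation, cross
tables) together with a ground-truth ledger, so the whole pipeline is
testable without any external downloads.

## Worked example

Estimate the age of an inversion observed with S = 12 segregating sites and
π = 4.2 among n = 8 inverted haplotypes over a 20 kb breakpoint region, at
sample frequency f = 0.2:

```python
from invgen import ABCConfig, InversionAgeModel

cfg = ABCConfig(L=20_000, d=0.06, f=0.2, min_accept=2000, seed=7)
res = InversionAgeModel(obs_s=12, obs_pi=4.2, n=8, config=cfg).fit()
print(res.summary())
```

```
Inversion age model (exponential-growth coalescent, rejection ABC)
====================================================================
observations: S = 12, pi = 4.2, n = 8
theta_hat = 16   priors: theta ~ U(0, 160), alpha ~ U(0, 100)
tolerance = 0.05   accepted = 2094   acceptance rate = 0.00419
--------------------------------------------------------------------
parameter       median        q2_5        q97_5
    theta    41.300597   11.750606    88.342249
    alpha    62.026776    8.989562    98.336372
   t_mrca     0.063159    0.036793     0.233362
age_years 13787.229423 7251.307936 24369.681552
--------------------------------------------------------------------
age median = 13,787 years   95% CI = (7,251.3, 24,369.7)
```

The posterior median says this inversion arose roughly 14 thousand years ago
(95% credible interval 7.3–24 ky): S and π this low over 20 kb are far below
the mutation–drift expectation for the whole population, so the inverted
clade must be young.  The acceptance rate (4.2×10⁻³) is itself a diagnostic —
rates orders of magnitude lower signal that the growth model fits the
observation poorly.

The same analysis is scriptable end to end from the shell:

```sh
invgen make-data --out demo --seed 7          # synthetic dataset + truth
invgen mask-exchange demo/breakpoint.fasta demo/meta.tsv --inversion "In(1)Sim"
invgen stats masked.fasta --groups demo/meta.tsv --inversion "In(1)Sim"
invgen abc-age --obs-s 12 --obs-pi 4.2 --n 8 -L 20000 --d 0.06 --f 0.2 --seed 7
invgen distortion demo/crosses.tsv --bonferroni-m 11
```

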