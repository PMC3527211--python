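# Methods

This note documents the models, conventions, and design choices behind
`invgen`, and what the synthetic-data experiments do and do not establish.

## Coalescent simulator

Time is measured in units of 4N₀ generations, as in ms.  Under exponential
growth at rate α (units 1/(4N₀)), the backward population size is
N(t) = N₀e^{−αt} and the total coalescence rate with k lineages is
k(k−1)e^{αt}.  Waiting times are drawn by inverting the time change,
s = ln(1 + αE e^{−αt₀}/k(k−1))/α with E ~ Exp(1), evaluated with `log1p` so
large α·t never overflows; growth is unbounded into the past (no floor
population size).  Mutations follow infinite sites: Poisson(θ·branch length)
per branch, carriers the leaves below, so every column has 1..n−1 carriers
and E[S] = θ·a_{n−1}, E[π] = θ, E[T_MRCA] = 1 − 1/n at α = 0.  Site positions
are uniform(0,1) and carried only for ms-format compatibility.

Two code paths exist: a per-replicate path returning the full genealogy and
haplotype matrix, and a vectorized path returning only (S, π, T_MRCA) used by
the ABC loop (~50,000 replicates of n = 10 in under a second).  The test
suite checks the two paths against each other, against the closed forms
above, and against msprime as an independent implementation (chi-square test
on the S distribution at n = 3, θ = 1).

## ABC age estimation

The estimator treats an inversion as a panmictic population founded at the
inversion event, growing exponentially at an unknown constant rate.  The
expected scaled mutation rate of the current inverted population is
reconstructed as

    theta_hat = 4 (Ne f) mu_region,   mu_region = d/(2 t_gen) * L,

i.e. per-site mutation rate d/(2·t_gen) (divergence to the sister species
accrues on two lineages) times region length, times an inverted effective
size Ne·f.  Priors are θ ~ U(0, 10·θ̂) and α ~ U(0, α_max).  The α prior
bound is a package choice (default 100 in 1/(4N₀) units); sensitivity to it
should be reported alongside results, and the `summary()` output always
prints the priors used.  Acceptance requires simulated S and π each within a
5% relative tolerance of the observed values.  The π tolerance is applied on
the per-region scale (scale-invariant under matched definitions).  A zero
observation degenerates the relative tolerance, so exact matching is used
there — required for inversions with no segregating sites at all, where the
posterior is driven purely by the probability of mutation-free genealogies.

Ages convert per draw as age = T_MRCA·θ/μ_region-per-year with
μ_region-per-year = d/(2 t_gen)·L·g (g generations per year, default 10,
consistent with a ≈3 My species split at t_gen = 3×10⁷ generations).
Posterior summaries are the empirical median and 2.5/97.5 percentiles with
linear interpolation.  The acceptance rate is reported as a model diagnostic:
a run whose rate is orders of magnitude below its peers indicates the growth
model fits that region poorly.

The divergence-based alternative is T = (π_between − π_std)/(2μ_site-per-
year).  The factor 2 (two diverging lineages) is the package's documented
convention.  Negative estimates are returned as computed with a flag: they
are expected for very young inversions, since π_between then barely exceeds
within-standard diversity.

## Sequence handling

Coordinates are 0-based half-open everywhere internally; 1-based breakpoint
positions from cytological tables are converted on input
(`points_from_positions(..., one_based=True)`).  IUPAC ambiguity codes —
residual heterozygosity in inbred-line assemblies — are normalized to N with
a logged warning rather than rejected, matching the policy of masking
putatively heterozygous sites before analysis; lowercase is uppercased.
Breakpoint-region statistics use complete deletion (every column containing
any gap or N is removed first); genome-scan diversity uses pairwise deletion
with no sample-size threshold.  The deletion mode is recorded in every
`SummaryStats`.  Residual-heterozygosity arm masking scans 0.5 Mb windows
and excludes a (sample, arm) when ≥3 consecutive windows exceed a 0.5%
heterozygous fraction; the window size is standard, the run/fraction cutoffs
are package defaults (the qualitative criterion "obvious under cursory
inspection" is not algorithmic) and are configurable.

Tajima's D uses the standard a₁…e₂ constants; at n = 3 the variance
constants vanish identically (π is then a deterministic function of S), so D
is reported as undefined.  D′ is D divided by |D_min|, D_min computed by
evaluating D at the all-singleton configuration (π = 2S/n) with the same S —
a documented convention, since the original rescaling reference is not
reproducible from the source.  Hudson's F_ST is 1 − H_w/H_b with H_w the
*unweighted* mean of the two within-group per-site diversities and H_b the
between-group per-site diversity, both as ratios of total mismatches to
total compared columns; negative values are reported, not clamped, and
H_b = 0 yields an undefined flag.  Note that for tiny samples the
finite-sample H_b of two identical groups is below H_w (self-comparisons
dominate), so the "F_ST ≈ 0 under panmixia" property is an expectation over
genealogies, verified by simulation, not an algebraic identity.

## Exchange-tract detection

A site is a shared polymorphism when it is biallelic and its minor allele is
observed in both arrangement classes.  For each inverted haplotype, variant
sites are the informative polymorphic columns (gap-free, not within 10
columns of an indel) where it departs from the inverted-class majority
allele; a run of ≥3 consecutive variant sites whose carried alleles are all
present among standards is called an exchange tract.  min_run = 3 encodes
"a shared site flanked by shared sites" and is configurable, since the
underlying criterion was a manual-inspection rule.  Tract boundaries extend
halfway toward the nearest non-shared flanking variant site: the true
recombination breakpoint is unidentifiable between informative sites.
Masked spans become N; haplotypes masked beyond 50% are dropped, and a
warning fires when more than half of the inverted class is dropped —
exchange that extensive means the ancestral inverted haplotype cannot be
recovered and the breakpoint should be excluded from age estimation.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
organismal realism.  African standards come from a neutral coalescent at
θ_site·L; cosmopolitan standards are a shallow clade grafted onto one
African haplotype with within-clade θ reduced to `bottleneck_severity`
(default 0.2) of the African level — the two features (shared recent
ancestry, reduced diversity) that make the origin classifier's conditions
informative.  The inverted class is a clade founded on one standard
haplotype (African or cosmopolitan, fixing the true origin), with
stem mutations Poisson(μ_region-per-year · age) and a within-clade
genealogy rescaled so its root sits exactly at the requested age; expected
inverted–standard net divergence then matches 2μT.  Exchange tracts are
copied from random standard haplotypes into inverted ones; indels are single
contiguous gap runs; missing data are N runs; no alignment ambiguity is
simulated (inputs are pre-aligned by construction).

Two deliberate calibration choices:

* The standard population's per-site diversity defaults to 0.008
  (`theta_site_std`), the level observed in ancestral-range panels, rather
  than the 4·N_e·μ = 0.004 implied by the age-calibration constants;
  diversity-based and census-style effective sizes are known to disagree in
  this species, and the standards' observed diversity is what exchange
  detection and origin classification actually operate on.  The inverted
  clade's θ stays on the (d, t_gen, N_e, f) calibration so requested ages are
  commensurate with the age estimators.
* The truth ledger records each exchange event's *realized footprint* — the
  first through last column actually changed by the copy — and omits copies
  that change nothing.  A silent exchange leaves the dataset literally
  identical, so it has no coordinates to recover; flanking sequence
  identical to the founder's is unattributable even in principle.

Because mutations are infinite-sites on distinct columns, the generator
produces no recurrent mutation; real data would add a small false-positive
floor to shared-polymorphism detection that these tests do not measure.
Likewise the bottleneck is a caricature (one founder haplotype, rescaled θ),
so passing origin-recovery tests shows the classifier implements its rule
correctly under the assumed structure, not that the rule is robust to real
admixture — African standards are assumed pre-masked for admixture by the
caller.

## Recovery experiments and problem sizes

The age-recovery experiment simulates inversions aged 500, 5,000, and 50,000
years (n = 8 inverted haplotypes) and checks that posterior medians
rank-order the truth and fall within a factor of 3.  It uses 50 kb regions:
at the package's 20 kb default a 500-year inversion leaves E[S] ≈ 0.3, so
the observation collapses onto S = 0 and, when a stray singleton does occur,
the posterior honestly reflects an age several times larger — an
identifiability ceiling of short regions, not an estimator property.  At
50 kb the youngest age leaves E[S] ≈ 0.7 and an S = 1 observation is itself
consistent with ~500–700 years.  Each ABC run in the experiment uses the
post-filter effective aligned length for its θ̂ and μ calibration (the
length the analyst actually observes) and 200 acceptances; the library
default remains 10,000 acceptances for production use.  The
zero-polymorphism configuration is run alongside and always yields the
smallest posterior median.

Other sizes used by the test suite and acceptance script: 50,000 replicates
for the simulator closed forms; 1,000 panmictic replicates for the F_ST
null; 10⁵ permutations for the breakpoint test (closed-form binomial
comparison P(Bin(2, 0.3) ≤ 0) = 0.49); ten generator seeds for the
exchange-tract round trip; 10⁴ replicates per sample size for the binomial
test's size (the exact test is slightly conservative near α = 0.05).

## Numerical and degenerate-case conventions

* Permutation p-values use the add-one estimator (1 + #{null ≤ obs})/(B+1),
  never zero; breakpoints are permuted independently and uniformly on their
  own arms.
* "Associated regulatory regions" around genes are a configurable flank,
  default 0, since no width is prescribed.
* The published cross table stores reconstructed female counts
  round(K·N); one control row is ambiguous at the printed precision, and the
  egg-assay female count (1428) comes from the paired adult cross.  The
  egg-assay p-value printed in the original table is not reproduced by a
  one-sided exact binomial on these counts (0.0060 vs 0.0054, with the
  accompanying text quoting 0.0248); only K is anchored, and both
  computations are exposed.
* Poisson error bounds use the exact chi-square inversion
  λ = χ²(confidence, 2(obs+1))/2, reported after ceiling when quoted as
  whole errors; Q = −10log₁₀(errors/bases) with an explicit `Qinf` sentinel
  for zero errors rather than a silent cap.
* The pileup consensus emits the majority base only at depth ≥3 and
  consensus quality ≥50, ties → N; consensus quality is the Phred sum of
  supporting minus conflicting qualities, a simplification of the full
  samtools consensus model.  The surrounding reassembly pipeline (read
  mapping, mate recruitment, de novo assembly) is out of scope; the
  depth-titration harness exercises the statistics, with this simple caller
  standing in for the assembler.
* CLI subcommands derive one RNG stream each from (user seed, crc32 of the
  subcommand name), so adding a stage to a workflow never perturbs the draws
  of earlier stages.

## Known limitations

* The growth model is deliberately simple; discordant posteriors between two
  breakpoints of one inversion (hitchhiking, selection on linked sites) are
  expected in real data, and the convention of preferring the older
  breakpoint's posterior is left to the analyst.
* Ages from polymorphism are lower bounds if selection has purged variation;
  the divergence-based estimator is only informative against a low-diversity
  (bottlenecked) standard panel.
* No recombination within simulated regions (breakpoint loci are treated as
  single rarely-recombining loci) and no multi-population island models.
* Origin classification is a divergence rule, not model-based assignment; it
  reports Ambiguous on mixed nearest-neighbour ties and on disagreement
  between breakpoints.
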