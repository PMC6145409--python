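# Methods

`craterscan` tests whether a crater-lake species radiation received gene flow
from nearby riverine populations, and if so whether that gene flow arrived
*after* in-lake diversification began (secondary contact into single species)
or *before* it (a founding hybrid swarm whose variants sorted differentially
among descendant species). The package implements the full analysis chain —
genome-wide f4 tests, sliding-window fd scans calibrated by no-migration
coalescent simulations, window diversity statistics, per-window topology
classification, and region categorization — together with a synthetic-data
generator that produces all three competing histories with known truth, so
every stage is testable end to end without any external dataset.

## Statistics

**Allele frequencies and polarization.** All statistics run on per-population
allele frequencies from biallelic SNPs. For the frequency-based ABBA-BABA
statistics the derived allele at each site is defined as the allele that is
minor in the designated distant outgroup; at an exact 0.5 tie the alt allele
is treated as derived so results are deterministic. Sites with an entirely
uncalled outgroup cannot be polarized and are skipped. The f4 statistic is
polarization-invariant (both factors flip sign together), so it uses raw
alt-allele frequencies.

**D and fd.** For the quartet tree ((P1,P2),P3,O) with derived frequencies
p1..p4, each site contributes ABBA = (1-p1)p2p3(1-p4) and
BABA = p1(1-p2)p3(1-p4); D = (ΣABBA-ΣBABA)/(ΣABBA+ΣBABA). The window-scale
fd normalizes the same numerator by its value under complete donor sharing,
substituting the per-site dynamic donor pD = max(p2,p3) for both P2 and P3.
fd is reported only when both sums are positive: a window with a zero or
negative ABBA-BABA excess carries no interpretable admixture fraction in the
tested P3→P2 direction and can never be a candidate. A window enters a scan
only if it has at least `min_sites` (default 100) variant sites at which
*every* member of *every* quartet population is genotyped — the strictest
reading of "no missing data within a population" — and at least one quartet
population is polymorphic or fixed different from another.

**f4 with block jackknife.** f4(A,B;C,D) is the mean over usable sites
(every population with ≥1 called genotype — the genome-wide test is not tied
to windows) of (pA-pB)(pC-pD). Its standard error comes from a
delete-one-block jackknife over blocks of 1000 adjacent usable SNPs, never
spanning chromosomes, which absorbs linkage disequilibrium. A trailing
partial block keeps its own identity if it holds at least half a block,
otherwise it merges into the previous block; a short chromosome always forms
at least one block. Z = f4/SE is referred to the standard normal,
p = 2Φ(-|Z|). Because published tables of this statistic are internally
inconsistent in sign (printed Z occasionally disagrees in sign with the
printed f4/SE ratio), only |Z| and p are meaningful comparison targets.

**π and Dxy.** Over the same windows, within-population diversity is
π = Σ_sites [n/(n-1)]·2p(1-p)/L with n the called allele copies, and
between-population divergence Dxy = Σ_sites [pX(1-pY)+pY(1-pX)]/L. L is the
full window length in bp by default; since invariant sites are absent from a
VCF this is a lower-bound estimator, and a genotyped-sites denominator
(`denominator="sites"`) is provided as the alternative reading.

**Windows.** 50-kb sliding windows advanced in 5-kb steps (configurable),
0-based half-open internally, 1-based inclusive in all exports. The 5-kb
step is inferred from the fact that published candidate-region lengths run
from 50 to 95 kb in 5-kb increments, which only merged 5-kb-stepped 50-kb
windows can produce.

## Null calibration and region logic

Significance of fd is assessed against windows simulated under the fitted
demography with *no* migration. The default threshold rule is the maximum of
the simulated fd values (matching the verbatim thresholding description the
scan reproduces); because a sample maximum grows with the number of
simulated windows, a quantile rule (default q = 0.95) is provided and is the
rule under which calibration is checkable: fresh null windows must exceed a
quantile(q) threshold at rate 1-q. Exceedance rates are computed among
windows with a defined fd (positive numerator and denominator), the same
population the threshold was built from.

Windows above threshold are merged (overlapping or abutting) into maximal
candidate regions per focal species and donor; when a species appears as P2
in several directed tests against the same donor, its tests are pooled
before merging, so a region is "the species is a candidate in *some* test",
as in per-species candidate tables. Regions are then categorized across
species for the same donor: PRIVATE (no overlap with any other species'
region), SHARED_SUBCLADE (≥1 bp overlap with a region of a same-subclade
species), SHARED_CLADE (overlap across subclades; takes precedence).
Overlap, not identical window sets, defines sharing because merged regions
have unequal lengths across species. Two further flags: a region overlapping
any candidate region from the other donor's scan is hybrid-swarm-flagged
(dual-donor signal), and a region whose focal-species mean π is strictly
below 0.1× the mean π of that species over the usable windows of the same
chromosome is sweep-flagged (order-of-magnitude diversity drop).

## Topology painting

As a deterministic stand-in for HMM genome segmentation, every window gets an
allele-sharing distance matrix (mean |dosage_i - dosage_j|/2 over co-called
sites), a neighbor-joining tree (scikit-bio; labels sorted before
agglomeration so ties break lexicographically and the topology is invariant
to input order), and a class after rooting on the outgroup attachment edge:
LAKE_MONOPHYLETIC, GROUP_WITH_RIVERINE(g) for the largest configured
species/subclade g whose minimal clade with a riverine sample contains no
other lake samples, OTHER_POLYPHYLETIC, or UNINFORMATIVE (too few sites, a
pair with no co-called sites, or a non-monophyletic outgroup). Adjacent
same-class windows merge into runs; class proportions are merged-run spans
over the total painted span. The UNINFORMATIVE rule is a pragmatic stand-in
for the conservative segment filtering such screens require, not a
reconstruction of any particular filter.

## The coalescent simulator

A backwards-time Hudson coalescent over labelled demes: within a deme
holding k lineages at time t, pairs coalesce at rate k(k-1)/2/(2Ne(t)) with
piecewise-constant Ne handled by treating epoch boundaries as events; at a
split all lineages of the derived deme move to its ancestor; at a pulse each
lineage in the recipient moves to the donor independently with probability
f. Mutations are infinite-sites: Poisson(μ·L·branch length) per branch at
fresh uniform integer positions (collisions redrawn). Times are generations;
sizes are diploid Ne.

**Recombination surrogate.** A window is the concatenation of independent
non-recombining sub-blocks (default 10 per 50-kb window). This preserves the
intra-window averaging the null thresholds depend on at a fraction of the
cost of an ancestral recombination graph; an exact-ARG backend could be
slotted in behind `simulate_window` unchanged. Consequence: intra-window LD
structure is only block-wise, so LD-decay analyses are out of scope.

**Default radiation.** Six lake species in two subclades of three
(((X1,X2),X3) per subclade; three-species subclades are what makes
within-subclade sharing expressible, since a species pair tested against
each other cannot both be candidates for the same donor), an MM-like and a
CR-like riverine deme, and one distant outgroup. Defaults: lake Ne 2×10⁴,
riverine Ne 5×10⁴, μ = 3.5×10⁻⁹/bp/gen, sister splits 3 kgen, subclade
roots 6 kgen, radiation root 10 kgen, MM/CR split 10× deeper (100 kgen),
lake joining the riverine ancestor at 150 kgen (must postdate the MM/CR
split for the ((P1,P2),(MM,CR)) quartet topology), distant outgroup 50×
deeper (500 kgen), two diploids per deme. Above the radiation root the lake
lineage reverts to the riverine Ne — the pre-colonization ancestor was a
riverine population — which supplies the incomplete lineage sorting a
realistic null fd distribution requires. These are order-of-magnitude
choices for a young crater-lake radiation, not estimates fitted to any real
dataset.

**Scenarios.** `none` adds no pulses anywhere. `secondary_pulse` adds, in
truth windows only, a pulse (default f = 0.8) from the MM-like deme into one
lake species at 1 kgen, i.e. after that species began diverging from its
sister. `hybrid_swarm` adds, in truth windows only, two pre-divergence
pulses into the lake ancestor just above the radiation root (11/11.5 kgen):
a fraction (default 0.5) of lineages to the MM-like deme and *all* remaining
lineages to the CR-like deme — a founding swarm means the lake population is
the mixture of its colonists, so no phantom third ancestry remains.

**Tract coherence.** Which sampled haplotypes carry donor ancestry in a
truth window is drawn once per window and pinned across its sub-blocks via
designated-lineage pulses (a lineage migrates iff the majority of its
descendant haplotypes are designated; ties resolve by the smallest
descendant id). A real introgressed tract is one recombination-free ancestry
decision per chromosome; redrawing migration independently in every
sub-block would average the species' ancestry difference toward zero by
roughly the square root of the block count and is not what a tract means.
Plain pulses (no designated set) keep the independent per-lineage semantics.

**What the generator does not emulate:** recombination within blocks,
selection (sweep flags are exercised on constructed fixtures, not simulated
sweeps), sequencing error or missing data (missingness handling is covered
by unit fixtures instead), and real chromosome-scale LD. Passing recovery
suites therefore demonstrate the statistical machinery and its calibration
under the stated demography, not performance on real short-read data.

## Numerical choices and degenerate inputs

- fd undefined (NaN) when the window is unusable, s_num ≤ 0 or s_den ≤ 0;
  undefined windows are never candidates.
- Jackknife with fewer than two blocks is a fatal error (the SE would be
  meaningless); SE exactly 0 reports p = 0 with a degeneracy warning.
- Quantiles use numpy's default linear interpolation.
- A population with no called genotypes at a site has undefined frequency;
  windows where a population is entirely uncalled yield NaN π/Dxy with a
  flag rather than 0.
- Sweep comparison uses strict `<` at the 0.1× boundary.
- Region merging treats abutting (end == start) windows as one region;
  sharing between regions requires ≥1 bp of true overlap.
- VCF contigs may appear in any order, but sites must be position-sorted and
  contiguous per contig, without duplicates.

## Problem sizes used in the shipped checks

Null calibration uses 1000 simulated training windows and 1000 fresh
windows; scenario recovery uses 200 windows with 10% truth; simulator sanity
uses 2000 single-deme replicates; topology painting uses 100 windows. These
sizes put binomial error comfortably inside the asserted tolerances while
keeping a full run in the low minutes on one core.

## Known limitations

- The max-rule threshold is sample-size dependent (it grows with the number
  of simulated null windows); the quantile rule is preferred whenever
  thresholds must be comparable across runs.
- The polarization tie rule (alt derived at outgroup frequency 0.5) is a
  documented convention, not an inference about any real dataset.
- With two diploids per population, allele frequencies take coarse steps of
  0.25; power figures from the recovery suites do not transfer to larger
  sample sizes.
- The hybrid-swarm detection rests on differential sorting among extant
  species; a swarm whose variants fixed uniformly across the radiation is
  invisible to fd by construction (the shared pattern cancels), which is a
  property of the statistic, not of this implementation.
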