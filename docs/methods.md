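# Methods

`founderhap` implements the computational chain used to characterize a
recessive founder variant whose homozygotes are conspicuously rare: how
many homozygotes a population should contain under Hardy-Weinberg
equilibrium, whether the risk allele descends from one ancestor or
several (IBD streak mapping and tag-SNP haplotype classification), and a
semi-quantitative model of how a variant that disturbs oligomerization
reduces the flux of a dimeric bifunctional enzyme. The motivating case is
the GNE c.620A>T (p.D207V) variant in the Japanese population, and the
package ships that case's marker panel and score presets as defaults,
but every stage is parameterized for reuse.

## Homozygote-deficit statistics (`popgen`)

For a variant at population allele frequency `q`, random mating predicts
`N q²` homozygotes among `N` persons. The **detection rate** is the
number of identified homozygous patients divided by that expectation; a
value far below 1 indicates that homozygotes mostly never present as
patients, while a value near or above 1 says ascertainment is roughly
complete. `q` is estimated as an exact fraction `alt/total` from a
genotyped cohort (e.g. 22/13,686 alleles = 0.00161).

Parameters and conventions:

* `population_n` — persons at risk; default 91,800,000, an estimate of
  the Japanese population older than the mean onset age (~28 y) from
  national statistics. Required for any other cohort.
* Display rounding is decimal **half-up** at fixed precision
  (frequencies 5 dp, percentages 1 dp, rates 3 dp); raw values are kept
  at full precision alongside. Python's bankers' rounding would not
  reproduce printed report values deterministically.
* Expected counts default to the display-rounded frequency (the number a
  reader can recompute from a printed table); `use_display_freq=False`
  switches to the exact fraction. The detection rate divides by the
  rounded integer expectation by default
  (`rate_from_rounded_expected=False` for full precision).
* Allele-share tables count **alleles, not persons**: both alleles of a
  homozygote count toward `homozygous_alleles` (so 92 homozygous
  patients contribute 184 alleles), and homozygous + compound-het
  alleles partition each variant's patient alleles.
* `compare_groups` defaults to the unpaired two-sample rank-sum
  (Mann-Whitney U) test, exact when samples are small and tie-free,
  normal-approximated otherwise. The matched-pairs signed-rank form is
  available via `paired=True` but is not the default because the group
  comparisons this package targets (onset ages across genotype classes)
  are between unrelated samples. Student's t is provided for
  measurements where it is conventional (e.g. sialylation levels).

## SNP-streak IBD detection (`ibd`)

Two individuals sharing a haplotype IBD can never be opposite
homozygotes inside the shared segment, whatever the phase. The detector
reports all maximal runs of consecutive markers satisfying that
compatibility, per chromosome, with these rules:

* missing genotypes are neutral — they never break a run and never count
  as markers (a no-call carries no evidence either way);
* up to `max_mismatches` incompatible sites may be absorbed per run
  (genotyping-error tolerance); runs are trimmed so both boundary
  markers are informative and compatible, and a trimmed run strictly
  contained in another valid run is discarded (maximality);
* runs shorter than `min_markers` informative markers or `min_span_bp`
  base pairs are suppressed. Defaults (0 mismatches, 100 markers,
  100 kb) are conservative against chance streaks at array-like marker
  density: with background frequencies uniform on [0.05, 0.95] the
  per-site opposite-homozygote probability is ~0.07, so a chance run of
  100 compatible markers has probability ~10⁻³ per start site.
* Segment boundaries are reported as the first/last compatible marker
  position (not midpoints to the flanking incompatible markers), 1-based
  inclusive; BED export converts to 0-based half-open. Spans are
  displayed in kb rounded half-up to the nearest 10 kb.

`multiway_shared_segments` intersects the pairwise segments of every
pair in a sample group and re-applies the marker/span filters on the
intersected intervals; for two samples it reduces exactly to the
pairwise detector. The original streak literature's mismatch and density
thresholds are not fixed here — they are exposed as `StreakParams`.

The unit and acceptance suites validate the detector against an
independent brute-force enumeration of all maximal compatible windows on
panels up to 200 sites across a parameter grid.

## Founder-diplotype classification (`haplotype`)

The default rule is the chromosome-9 panel distinguishing the two
c.620A>T founder haplotypes: four discriminating variants
(36,214,971 / 36,216,426 / 36,217,798 / 36,220,134) with alpha pattern
[G,G,G,C], beta pattern [A,A,A,T], background pattern [G,G,G,T], and the
risk site 36,246,117 (risk allele A on the genomic plus strand — the
gene lies on the minus strand, so the cDNA A>T change is genomic T>A).

Classification is purely combinatorial: given the risk-allele dosage
(0/1/2), the candidate diplotypes are enumerated (hom-alt: alpha/alpha,
beta/beta, alpha/beta; het: alpha or beta over background) and a call is
made only when exactly one candidate reproduces the observed unphased
allele multiset at every discriminating site. This resolves unphased
carriers without statistical phasing because alpha, beta and background
differ at every panel site in a mutually distinguishable way. Anything
else — missing markers, conflicting patterns, ambiguity — yields
`unknown` with a reason; the classifier never forces a call. Because
alpha and beta patterns differ at all four sites, corrupting a single
site can only move a call to `unknown`, never flip alpha to beta (the
tests verify this exhaustively over all single-site corruptions).

Haplotype frequencies count haplotype copies (a hom call contributes
two) among classifiable calls and display 1-decimal percentages.

## Dimer route-flux model (`flux`)

ManNAc 6-phosphate production of an enzyme dimer is scored as the sum of
four production routes — intramolecular in each monomer and both
intermonomer directions — each route the product of the source monomer's
epimerase score, a transfer score, and the destination monomer's kinase
score. All components are unitless efficiencies in [0, 1]; wild type
scores 1 everywhere, so the wild-type total is 4 (relative total 1; both
are reported because a "score 1" convention can denote either reading).

Ranged scores propagate by interval arithmetic (endpoint-wise products
and sums of non-negative intervals), giving sharp bounds rather than a
midpoint collapse; Monte-Carlo containment is verified in the tests.
Preset component scores: D207V leaves both enzymatic reactions at 1 but
halves intramolecular transfer (0.5) and, because it partially disrupts
oligomerization, makes intermonomer transfer variable (0.3–0.5) for any
dimer containing it (a dimer-level property; a per-dimer override is
exposed). Catalytic-site mutants score 0.1 and V603L 0.2 on both
enzymatic reactions, transfer untouched. An alternative
`D207V_invitro` preset (epimerase 0.18, from the reported in vitro
activity of the corresponding short-isoform mutant) is provided but
never default, since the default model deliberately attributes the
D207V defect to transfer, not catalysis. Under these presets the model
reproduces the qualitative ordering that motivates it: a
D207V/catalytic compound heterozygous dimer (total 0.57–0.61) produces
strictly less than a D207V homodimer (1.6–2.0).

## Synthetic data (`simulate`)

The generator emulates the structure the analyses assume, with exact
known truth:

* background haplotypes are site-wise independent (linkage equilibrium)
  with per-site alt frequencies drawn uniformly on [0.05, 0.95] unless
  overridden — sufficient to exercise streak detection and analytically
  checkable; real LD structure is deliberately not modeled;
* a founder haplotype is a fixed ancestral allele vector defined inside
  its planted span (plus its marker pattern at named panel sites);
  outside the span a founder chromosome decays to fresh background.
  Truncation is deterministic at the configured endpoints rather than
  modeled through recombination meioses, so tests have exact planted
  boundaries; span endpoints are always emitted as marker sites.
  `forced_genotypes` lets a scenario plant incompatible markers directly
  flanking a span (with random backgrounds, the first chance
  opposite-homozygote would otherwise fall beyond the endpoint);
* genotype errors are symmetric single-step code perturbations
  (0↔1↔2, het errors split evenly) at a configured rate, applied after
  assembly; missingness last;
* HWE cohorts are multinomial draws over (q², 2q(1−q), (1−q)²);
  measurement groups are independent normal draws (defaults in the demo
  follow onset-age-like parameters: mean 34.8 SD 8.8 vs mean 36.7
  SD 12.2).

One seeded generator is consumed in a fixed documented order, so equal
seeds give byte-identical VCF output.

Passing tests on these panels demonstrate correctness of the algorithms
under the generator's assumptions (independent background sites, exact
planted boundaries, unbiased errors); they do not certify performance on
real genomes with LD, allele-frequency structure, or systematic
genotyping artifacts.

The bundled `founder_demo_config` scenario mirrors the founder topology
of the motivating study: founders alpha (span 36,118,198–37,898,880;
1780 kb) and beta (36,137,298–36,818,382; 680 kb) on chromosome 9, two
homozygotes each (P1/P2, P3/H1) plus unphased carriers, with panel-site
background frequencies pinned to 0 so non-founder chromosomes carry the
background pattern. The demo panel uses ~1200 markers over 2.8 Mb
(~2.4 kb/marker, array-like density), with the streak thresholds set to
150 markers / 100 kb — far below the ~760 and ~290 markers inside the
planted spans but far above what chance streaks reach at this density.

## Numerical and degenerate-input choices

* Half-up display rounding throughout (see above); comparisons in tests
  are made on the displayed values where a printed value is the target.
* Zero-denominator allele frequencies, non-positive expected counts,
  undersized comparison groups, unknown samples/presets and unsorted
  site tables raise `ValueError` rather than returning sentinels; a
  variant with zero patient alleles reports a missing homozygous rate.
* Zero-length segments (start = end) are legal and report span 0.
* Multiallelic or non-SNV VCF records are skipped with a counted
  warning, never silently re-coded.

## Known limitations

* No phasing, LD modeling, or probabilistic (HMM) IBD scoring; streak
  detection is deterministic and rule-based.
* The flux model is a static score algebra, not kinetics: no
  concentrations, no ODEs, no fitting to sialylation measurements, and
  no oligomers beyond the dimer.
* Confidence intervals on allele frequencies and multiple-testing
  control are out of scope.
* The HWE expectation ignores population structure, consanguinity and
  differential survival — which is exactly why a detection rate far
  from 1 is informative rather than a modeling failure.
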