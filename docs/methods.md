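# Methods

## The mapping design

The package models a classical recessive-mutant mapping experiment in rice.
A mutation arises in the MH86 background (here, from tissue culture) and is
carried forward through a heterozygote; crossing the carrier to the distant
indica cultivar 93-11 and selfing the F1 yields an F2 in which the mutant
phenotype segregates 3:1. Pooling 50 phenotyped mutants (M-pool) and 50
phenotypically normal plants (N-pool) and sequencing both pools (~12x) plus
the two parents (~50x and ~30x) gives, at every MH86/93-11 polymorphism, four
pairs of allele counts. Selection of the mutant class drags the MH86-derived
haplotype to fixation around the causal locus in the M-pool while the N-pool
stays near 1/3, producing the allele-frequency contrast the scan detects.

## CAAFD

The window statistic is the cube of the window-averaged difference between
the two pools' MH86-allele frequencies. The cube applies to the mean, not
marker-wise — the two differ whenever differences vary within a window, and
the implementation follows the mean-then-cube form exactly (a code comment
marks the distinction). Properties the tests pin down: values lie in
[-1, 1]; swapping the pools negates the profile bit-exactly (the cube is
computed by multiplication because numpy's vectorized `**3` is not
sign-symmetric at the last ulp); ranking windows by CAAFD equals ranking by
mean difference (cube is strictly increasing); and for the ideal recessive
design the peak expectation is (2/3)^3 = 8/27.

Windows are 2000 kb sliding in 10-kb steps, each represented by its center.
Centers run on the step grid from 0 while they are below the chromosome
extent (the configured length, else the last marker); spans are truncated at
the ends rather than dropped, and windows with no markers are omitted
(minimum marker count configurable, default 1). The scan is computed with
prefix sums; a brute-force per-window recomputation serves as the oracle in
tests and in the acceptance script (agreement to 1e-12).

The called target region is the maximal run of consecutive windows, on the
peak's chromosome and with its sign, whose magnitude stays above
`alpha * |peak|`. `alpha = 0.5` is this package's own operational choice —
the published analyses of this design read the region off the profile by
eye — and is exposed as a flag. Peak ties break by genomic order, for
determinism.

## Marker selection

A site enters the marker set when each parent has depth >= 10 with >= 90% of
reads on one allele, the parents' majority alleles differ, both pools have
depth >= 4, and the mean of the two pools' MH86-allele frequencies lies in
the closed interval [0.3, 0.7]. The frequency band is applied to
MH86-oriented frequencies; because the band is symmetric about 0.5 the
orientation convention cannot change the selected set (property-tested). The
purity/depth defaults are chosen to tolerate ~1% sequencing error at
parental 30-50x and pool ~12x without discarding most true polymorphisms;
they are package defaults, not claims about any published analysis.
Multi-allelic records are excluded at parse time and counted.

## Selected-recessive fine mapping

With only homozygous-mutant plants genotyped, every scored gamete carries
the mutation, so a 93-11 allele at a marker is one recombinant gamete:
R = H + 2B out of G = 2(A+H+B), r_hat = R/G (capped at 0.5 defensively —
by construction R <= G), LOD = R log10(r/0.5) + (G-R) log10((1-r)/0.5)
against free recombination, threshold 3.0. Kosambi's function converts r to
cM; its closed-form inverse (0.5 tanh(d/50)) round-trips to < 1e-12.
Analysis is two-point against the trait locus only: marker order is taken
from the physical map, which is what a sequenced-genome design provides, and
the trait interval — innermost recombinant-bearing markers bracketing the
zero-recombinant (or minimum-recombinant) block — is the quantity of
interest. When several separate minimum-R runs exist the longest (first on
ties) anchors the interval; a side with no recombinant marker is flagged
open rather than clipped. Missing genotypes are dropped per marker and
tallied. Multipoint likelihood ordering is out of scope.

## Candidate screen

A causal variant that postdates the MH86 parent line shows a unique
presence pattern: mutant allele only in the M-pool, both alleles in the
N-pool, wild-type only in both parents. An allele is "present" in a group
when it has >= 2 supporting reads and > 5% of the group's reads (both
flags); a group with zero depth, or where no allele reaches the bar, is
"no-data", and variants whose groups are compatible with the pattern but
include no-data go to a separate undetermined list instead of being
silently rejected. The screen operates per variant call with REF as the
wild-type allele and ALT as the candidate mutant allele.

Presence/absence of *both* alleles in a 12x pool is unreliable (the minor
N-pool allele at frequency 1/3 misses two reads ~9% of the time), so the
pipeline's region screen models the deeper scrutiny a 200-kb candidate
region actually receives (assembled-sequence comparison in the motivating
design) as a higher effective depth, `depth_region_screen` = 40x by default,
configurable.

The cosegregation test tabulates candidate genotype (-/-, -/+, +/+) against
phenotype across a random F2 sample and declares concordance when every
mutant is -/- and every normal plant carries a wild-type allele; discordant
plants are listed by id.

## Segregation statistics

The two-class segregation test uses chi-square with 1 df. The Yates
continuity correction is on by default: at one degree of freedom the
Pearson statistic is anti-conservative, and on the canonical 262:71 F2 the
corrected form reproduces the published 2.21 / P = 0.137 while Pearson
gives 2.403 — both are always reported. The correction term clamps at zero
when |O - E| < 0.5. Cross summaries report per-panicle seed-setting rates
with mean +- sample SD over panicles (n-1), plus the pooled rate; a single
panicle has no sample SD and is flagged.

## The synthetic experiment

The generator's defaults are the study conditions: bulks of 50 + 50 from an
F2, pools at mean 12x, parents at 50x/30x, 1% base-call error, no
phenotyping error. The study-scale genome is 5 chromosomes x 30 Mb with
markers every 5 kb (~30,000 markers — a deliberate scale-down from the
~656,000 markers a real indica x indica cross yields, keeping runs in
seconds); the F2 holds 900 plants so a 199-plant mutant fine-mapping panel
can be drawn alongside the bulks, matching the design in which the
fine-mapping mutants come from the same cross.

Meiosis is a Haldane (no-interference) process: crossovers per chromosome
per gamete ~ Poisson(map length in Morgans), positions uniform, with a
single genome-wide scale of 1 cM = 250 kb (rice-typical order of magnitude,
configurable). Each F2 plant fuses two independent gametes; phenotype is
mutant iff homozygous for the MH86-derived allele at the causal locus, then
flipped with the phenotyping-error probability. Bulks are drawn uniformly
without replacement within phenotype class — how "phenotypically normal"
pool members were chosen is not specified in the motivating design, so
random is the default and the choice is a parameter of the code.

Pooled counts: depth ~ Poisson per marker per pool; each read is an
independent uniform draw from the bulk's 2 x 50 haplotypes, reported
wrongly with the base-error probability. Since reads are i.i.d., this is
implemented as exact binomial thinning with success probability
f(1-e) + (1-f)e. Parents are fixed homozygotes sequenced the same way. A
truth sidecar always records the exact bulk haplotype frequencies for
parameter-recovery tests. Simulated marker TSVs use the convention REF =
MH86 allele; the marker-selection stage still derives orientation from the
parental counts, and the orientation symmetry is property-tested
separately. Region-variant tables for the candidate screen implant the
causal variant (absent from both parents) among background variants that
ride one parental haplotype each.

What the generator does not emulate: read pairs, mapping and alignment
artifacts, reference bias, depth heterogeneity beyond Poisson, structural
variants other than the single causal site, crossover interference, and
segregation distortion. Passing recovery tests therefore demonstrates the
statistical machinery, not robustness to alignment pathology.

## Validation scales and numerical choices

- Peak recovery: 10 study-scale runs; the highest-|CAAFD| window center must
  fall within 1 Mb of the true locus in >= 9. At 12x and ~400 markers per
  window the window-mean noise (~0.01) is far below the peak contrast.
- Ideal-case magnitude: 20 runs at 200x, zero error, and a tight genetic
  map (1 cM = 2.5 Mb) so that within-window recombination does not attenuate
  the peak; mean peak CAAFD is compared to 8/27 +- 0.03. At the default
  250 kb/cM scale the +-1 Mb window spans ~8 cM and the expected window mean
  drops to (2 - 4 r-bar)/3 with r-bar ~ 0.02, i.e. ~0.26 — the tight map
  isolates the statistic's asymptote from map-scale attenuation, which is
  the point of the check.
- Fine mapping: 200 panels of 199 mutants on a small single-chromosome
  genome (n_f2 = 1200, so the mutant class exceeds 199 by > 6 SD for any
  seed); mean r_hat must sit within 3 SE of the Haldane truth at a 10-cM
  marker.
- Candidate screen: error-free simulation at 40x region depth, 500+
  background variants, 10 seeds, unique recovery required each time; the
  280-plant cosegregation panel must be fully concordant.
- Determinism: the demo pipeline (3 x 6 Mb) run twice with one seed must
  produce identical sha256 digests for every stage output. One global seed
  is split per stage via `numpy.random.SeedSequence.spawn`.

Degenerate inputs are errors, not silent defaults: empty windows are
skipped, empty scans and panels raise, zero-depth pools are flagged and
excluded upstream of the scan, r = 0.5 has no Kosambi distance, and an
all-cosegregating marker set cannot delimit an interval.

## Known limitations

Two-point linkage only; no smoothing or permutation envelopes for the scan
(the cube-of-mean statistic is reported raw); the region-calling threshold
is a heuristic stand-in for eyeballing a profile; phenotyping error is
modeled as independent label flips; and the simulator's uniform marker grid
understates the clustering of real variant density.
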