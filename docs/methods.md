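# Methods

## The capture model

The assay observes meiotic heteroduplex DNA (hDNA) indirectly: embryo-sac
chromosome doubling blocks the first post-meiotic mitosis, so the two
hDNA-derived sister chromosomes of the functional megaspore end up in one
unreduced 2n egg, and hDNA at a screened SSR locus appears as maternal
heterozygosity in the resulting allotriploid. The simulator abstracts
exactly this observable rather than doing four-chromatid bivalent
bookkeeping:

1. the number of recombination events per meiosis is Poisson(λ);
2. event start positions are drawn from a recombination landscape (below);
   each event deposits an hDNA tract of geometric length (mean `tract_mean_bp`,
   support ≥ 1 bp) extending rightward from its start, clipped at the
   chromosome end;
3. each tract is repaired by mismatch repair before capture with probability
   `p_mmr`; a repaired tract resolves to a single allele over its whole
   length — the invading allele with probability `p_conversion`, the
   resident one otherwise (partial repair is out of scope);
4. loci inside a surviving (unrepaired) tract are maternally heterozygous
   (`ab`); all other loci carry the background megaspore haplotype, an
   aa/bb mosaic with one fair coin flip per segment between tract
   boundaries;
5. fertilization adds one paternal allele per locus (uniform over the
   father's one or two alleles), and cells are masked missing independently
   at `missing_rate`.

Chromatid-level detail (which chromatids exchange, interference, male
meiosis) is deliberately omitted: the data this assay produces cannot
constrain those parameters.

### Parameters

| parameter        | unit | default | meaning |
|------------------|------|---------|---------|
| `lambda_events`  | events/meiosis | 14 | Poisson mean RE count |
| `tract_mean_bp`  | bp   | 1.8e6   | mean geometric hDNA tract length |
| `p_mmr`          | —    | 0.15    | P(tract repaired before capture) |
| `p_conversion`   | —    | 0.5     | P(conversion to invading allele given repair) |

No published estimates exist for these quantities in this system; the
defaults are **illustrative**, chosen once so that per-locus hDNA
frequencies on the demo chromosome span roughly 0.1–0.9 — the range dense
SSR panels report in *Populus* triploid populations. Mean tract length on
the megabase scale is what makes per-locus frequencies of tens of percent
possible at all with λ of order ten on a ~16 Mbp chromosome; it should be
read as the effective footprint of a captured exchange event, not as a
molecular conversion-tract length.

### The recombination landscape

`build_landscape` combines feature tracks log-linearly: each track is
length-standardized (z-scored with segment-length weights) and multiplied
by its weight; the summed log-intensity is exponentiated, an additive
offset `w_centromere` is applied inside the centromere interval (−∞ masks
it to zero), and the result is normalized to a per-bp probability density.
Default weights (−2 centromere, −0.6 methylation, −0.6 LTR-Gypsy, +0.4
low-complexity, +0.4 gene density, 0 recombination-rate) encode the
qualitative biology: suppression at the centromere and in
methylated/repeat-rich chromatin, enhancement in gene-rich and
low-complexity regions. Because tracks are z-scored, weights are
scale-free log-fold effects per SD of the track.

A closed-form companion, `tract_coverage_probability`, computes the
probability that a locus is maternally heterozygous by summing the
geometric tract-length tail over each constant-density landscape segment
(the number of unrepaired covering tracts is Poisson-thinned). It shares no
sampling code with the simulator and is used as an independent oracle in
the tests.

## hDNA calling and frequency

Allele roles are assigned per locus from fragment sizes: a = smaller
maternal allele, c = smaller paternal allele. A cell is classified into the
six clean constitutions (`abc`, `abd`, `aac`, `bbc`, `aad`, `bbd`); a cell
with no (or two) paternal alleles, an off-parent allele, or no maternal
allele is *ambiguous* and treated as missing, so the frequency denominator
contains only the clean classes:

    HF = N_ab / (N_ab + N_aa + N_bb).

Matching is exact integer fragment-size equality by default; a configurable
±bin tolerance absorbs electropherogram jitter. Dosage is ignored (aac and
aaC are indistinguishable to an SSR peak caller). How unreadable genotypes
entered the published denominator is not documented anywhere we know of;
exclusion is this package's choice and is flagged here.

## RE counting

For one individual, loci are ordered by position, missing calls dropped
(adjacency is defined on observed loci — a missing locus neither extends
nor breaks a run), and the RE count is the number of maximal runs of
hDNA-positive loci. This is the minimum-event parsimony reading of "hDNA at
two adjacent loci implies at least one event". One exception implements the
centromere clause: a run containing an adjacent observed pair with the
centromere interval strictly between its two markers is split into two
events, one per arm, because a single event spanning the centromere is
implausible given the suppression there. With one centromere the split can
add at most one event; if a marker lies inside the centromere interval no
pair straddles it and no split occurs.

## Gaussian peak model

The population RE distribution p_k is summarized by nonlinear least squares
on

    y = y0 + A/(w·sqrt(pi/2)) · exp(−2 (x − x_c)² / w²),

so x_c is the mean RE count, sigma = w/2, FWHM = sqrt(2 ln 2)·w, and the
integral of the fitted curve over [x_c − σ, x_c + σ] estimates the central
probability mass (≈ 0.683·A + 2σ·y0; both the full-curve and
baseline-free variants are reported, since published tables do not say
which convention their line-integral column uses).

Numerical choices: initialization y0 = max(min p, 0), x_c = weighted mean,
w = 2·weighted SD (floored at 0.6), A = Σp·Δk; bounds y0 ∈ [0, max p],
A ∈ (0, 10], x_c within one data span of the data, w ∈ (0, 4·span];
trust-region reflective solver, tolerances 1e-12, up to 10⁴ evaluations.
The lower bound y0 ≥ 0 matters: on sparse histograms (4–6 bins, the shape a
population of ~83 individuals produces) an unbounded baseline admits a
degenerate solution — a very broad Gaussian riding on a negative offset —
that a proportion histogram cannot represent. Non-convergence returns a
diagnostics-carrying result object, never an exception. At least four
distinct bins are required (four free parameters).

Normality of RE counts is checked with a one-sample Kolmogorov–Smirnov test
against a normal with sample mean and SD, matching common statistical
packages' defaults; estimating the parameters from the sample makes the
p-value anti-conservative (the Lilliefors effect), so a corrected variant is
available via `lilliefors=True` and the caveat is attached to every result.
Note also that K-S on *integer* counts detects the discreteness itself at
large n; non-rejection claims are only meaningful at population-scale n.
(Published analyses of this assay have sometimes read "P < 0.05" as
*conforming* to normality; the standard reading — non-rejection means
consistency — is used here.)

## Subsampling and correlates

Marker-density ascertainment draws, for each panel size and replicate, a
uniform subset of markers without replacement (genomic order preserved),
recomputes RE counts and the Gaussian fit, and reports the per-size mean
x_c; replicate RNG streams derive from (seed, size index, rep). OLS of
mean x_c on panel size quantifies the ascertainment trend; detected events
can only be gained, never lost, as markers are added, so the expected count
is non-decreasing in panel size.

Correlate regressions express HF in percent (so intercepts read as
frequencies a breeder recognizes) against centromere distance in Mbp —
distance to the nearest interval *boundary*, 0 inside; the midpoint
convention is nowhere defined in the source material, and the boundary
convention is conservative — and against the containing-bin value of each
feature track (no interpolation; the tracks are coarse windowed summaries).
Plain R² = r² is reported, never adjusted R² (which can print below zero on
weak fits and is the likely origin of "R² < 0" entries in older software
output). Per-fit p-values carry no family-wise correction by default,
matching standard practice for these tables; Benjamini–Hochberg q-values
are available with `bh_adjust=True`.

Gene-density re-binning treats each input bin's value as a mass and
distributes it over output bins in proportion to overlap length, so total
mass is conserved exactly.

## What the synthetic data does and does not emulate

The generators reproduce the study's *structure*: a ~15.9 Mbp chromosome
with a 5.3–6.7 Mbp centromere, three marker-free repeat-rich gaps, screened
SSR panels of 14–87 loci, populations of ~45–85 triploids, and feature
tracks with realistic geography (methylation and LTR-Gypsy content peaked
at the centromere, gene density and AT-low-complexity fraction enriched on
the arms, regional megabase-scale variation). One consequence of the
physics is worth noting: because hDNA tracts average the landscape over
megabase windows, only track structure at that scale is observable in HF —
sub-megabase track wiggles cannot be recovered by any sample size.

They do **not** emulate: electropherogram artifacts (stutter, null alleles,
peak dropout beyond uniform missingness), segregation distortion, selection
among offspring, chromatid interference, or any particular real genotype's
allele sizes. Passing tests therefore validate the machinery and its
statistical behavior under the stated model, not any biological claim about
a real population.

## Problem sizes

Test and acceptance computations use: exhaustive RE-rule checks at 12 loci
× 13 centromere placements (53,248 cases); simulator/oracle agreement at
5,000 individuals × 79 loci; ascertainment at 2,000 individuals with 25
replicates per panel size; sign recovery over 10 seeded populations of 300
individuals. These sizes give binomial/OLS standard errors comfortably
inside the asserted margins while keeping a full run in tens of seconds.

## Known limitations

* Tract placement is start-anchored (tracts extend rightward from the
  sampled position), which shifts the effective landscape window ~one tract
  length leftward of each locus; symmetric anchoring would change per-locus
  coverage only at this lag scale.
* Repaired tracts resolve to one allele over their whole length; real
  repair can be patchy.
* The Gaussian peak model is a summary device, not a generative claim;
  RE counts are discrete and the fit treats bin proportions as homoscedastic.
* `w_recomb_rate` defaults to 0 because the recombination-rate track is an
  *output*-like quantity (LD-based cM/Mb); it is available as a predictor in
  the correlate table but excluded from the generating landscape by default.
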