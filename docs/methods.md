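# Methods

## Scope and data model

The package detects copy-number-changing karyotype events in an
allotetraploid from two resequencing observables and, separately, scans
a resequencing panel for windows of elevated nucleotide diversity
indicating interspecific introgression.  The two homoeologous subgenomes
are modelled as collinear over their non-repetitive fraction: every
chromosome pair shares one coordinate axis, a repeat mask, and a catalog
of homoeologous sites at which the subgenomes carry different alleles.
Real subgenomes diverge structurally inside repeats, but all statistics
here are computed on unmasked sequence only, where the collinear
approximation is the working assumption of the whole approach.
Coordinates are 0-based half-open internally and in BED output, 1-based
in VCF and in human-readable reports; everything is strandless.

## Window systems

Two window definitions are used:

* **Genomic windows** of variable physical span but fixed non-repetitive
  content (default W = 100 kb of unmasked sequence).  A window closes
  immediately after the base that completes W unmasked bp; trailing
  masked bases attach to the next window, so information content per
  window is constant while spans stretch over repeat-rich regions.  The
  terminal remainder window is retained and flagged by its actual
  content (downstream statistics normalise by actual content); a
  chromosome ending in fully masked sequence attaches that tail to the
  final window so windows tile the chromosome.
* **Sliding variant windows** of fixed site count (default 500 sites,
  step 250).  When a chromosome holds no more sites than one window, a
  single window is emitted; otherwise windows start at every multiple of
  the step, the trailing ones smaller.

## Genotype calling

Genotypes are deterministic functions of the alternative-allele read
fraction r = alt/(ref+alt): hom-ref for r ≤ 0.1, het for r in
[0.15, 0.85] (inclusive ends), hom-alt for r ≥ 0.9, missing otherwise or
below the depth minimum (10 reads; 5 for low-coverage data; GBS uses a
narrower het band [0.25, 0.75] and keeps sites informative in >50% of
individuals, strictly).  The fractions in (0.1, 0.15) and (0.85, 0.9)
are deliberately uncallable: no genotype class is defined there, and
treating them as missing keeps the partition of [0, 1] coherent.
Variant sites that are also called in a self-alignment of the reference
individual's reads are removed as assembly/misalignment artifacts.

## The karyotype scan

For copy numbers (c_ref, c_other) of the two homoeologs the expected
homoeologous variant frequency is f = c_ref/(c_ref+c_other) and the
expected per-homoeolog depth ratio against a two-copy euploid reference
is c_s/2.  Per genomic window the scan computes:

* f̄, the depth-weighted mean frequency (Σa / Σ(a+b) over catalog sites);
* the ROH_H statistic χ² = Σ (a−b)²/(a+b), the per-site chi-square
  against balanced sampling, with df = covered sites.  Windows are
  flagged when χ² exceeds the chi-square quantile at a genome-wide
  significance level (default α = 0.05) Bonferroni-corrected over the
  number of scored windows;
* DOC ratios per homoeolog.  Each accession's window coverage is divided
  by its genome-wide **median** window coverage for that subgenome
  before taking the accession/reference ratio — the median resists the
  very aberrations being detected, provided aberrant windows stay a
  minority of the genome (hence the 4-pair default genome in the
  simulator; a karyotype where half the genome is aberrant would defeat
  this normalisation).  Windows with |DOC − 1| > 0.25 on either
  homoeolog are flagged (0.25 is halfway between adjacent copy-number
  expectations at the scan's resolution).

**Copy-state fit.** Each window's (f̄, DOC_A, DOC_B) is fitted by
exhaustive search over integer states with total copy 1–5, minimising
R = w_f(f̄−f_exp)² + w_d(DOC_A−c_A/2)² + w_d(DOC_B−c_B/2)² with default
weights 1:1 (f and DOC are already on comparable natural scales); ties
resolve toward the state closest to (2,2) in L1 copy distance.  Totals
above 5 (tetrasomy and beyond) are outside the grid and would surface as
persistently high residuals.  Somatic mosaicism is then tested by
fitting one-parameter mixtures of each aberrant state with (2,2) on a
dense m grid (201 points).  The mixture expectation is the
depth-weighted cell-population average, e.g.
f(m) = (m·c_ref + (1−m)·2)/(m·total + (1−m)·4); for total-conserving
events this is exactly linear in m.  Mixture families overlap — a
constitutive 3:1 state is observationally identical to a 4:0 mosaic at
m = 0.5 — so equally good mixtures resolve by parsimony (smallest L1
distance from euploid, then largest m).  A window is labelled mosaic
only when the mixture beats the best integer state by more than a factor
of 2 (configurable) *and* the fitted m lies inside (0.15, 0.85); outside
that band the state is indistinguishable in practice from constitutive
or euploid.

**Event segmentation.** Runs of flagged windows sharing the same
aberrant integer state merge, tolerating one unflagged window
(configurable).  A window straddling an event breakpoint sees a mixture
of the event state with (2,2) and can fit an intermediate integer state
exactly (the edge of a homozygous 0:2 deletion looks like 1:2), so
single-window runs directly adjacent to a longer run are absorbed into
it rather than reported separately — a choice that keeps boundary error
within one window without inventing events.  Events shorter than 200 kb
are dropped (at typical panel coverages smaller events are not reliably
detectable).  An event's mosaic fraction is the median of its windows'
fitted m (non-mosaic windows counting m = 1).  Events covering ≥95% of
a chromosome with total copy ≠ 4 are reclassified as whole-chromosome
aneuploidies; a whole-chromosome exchange (total 4) keeps its type.
Zygosity follows the fitted state: a one-copy departure on the most
deviant homoeolog is heterozygous, two copies homozygous, and the mosaic
flag overrides both.

## Diversity and introgression

Per genomic window, nucleotide diversity is the per-site unbiased
heterozygosity π = Σ_j (n_j/(n_j−1))·2p̂_j(1−p̂_j) divided by the
window's non-repetitive content, with n_j the called allele count at
site j (missing genotypes reduce n_j).  Introgression flagging is a
robust threshold on per-accession window SNP counts — baseline
median + 10·MAD over the bona fide accessions, floor of 5 SNPs when the
baseline is degenerate — rather than an HMM, matching the window-count
scale of the phenomenon (donor blocks raise counts by roughly an order
of magnitude, so the threshold's exact k matters little).  Flagged
windows merge into blocks across single-window gaps; block zygosity is
the majority genotype class among the excess SNPs.

## The synthetic generator

The generator emulates the stated world the scans assume, at desk scale:

* chromosome pairs of 5 Mb (default 4 pairs — enough that one aneuploid
  chromosome stays a minority of the genome for the median DOC
  normalisation; real genomes have ~11 pairs of ~50 Mb, and all rates
  are per-bp so statistics carry over);
* a repeat mask built from alternating exponential-length blocks (mean
  block 10 kb) hitting a configurable masked fraction per region
  (default 0.5), with homoeologous sites placed Bernoulli-per-unmasked-bp
  at density 0.05 (~95% subgenome sequence identity in collinear
  regions);
* shotgun observables: site depth ~ Poisson(coverage-per-copy × total
  effective copies), subgenome-A reads ~ Binomial(depth, f(1−ε)+(1−f)ε)
  with symmetric error ε (default 0.001); window coverage per homoeolog
  ~ Poisson(coverage-per-copy × copies × unmasked bp), reported per
  unmasked bp, emulating unique-mapping coverage on non-repetitive
  sequence.  Default coverage is 2× per copy (8× per euploid accession,
  typical of shallow public panels);
* a panel at target π = 3.12×10⁻⁴/bp: background sites carried
  homozygously by k accessions (k uniform on 1..n−1 — a highly selfing
  panel), placed at the density that makes the expected per-bp unbiased
  heterozygosity equal the target; introgressed blocks add
  accession-private alleles (het or hom per the requested zygosity) at
  the density lifting local π to 10× the background.

All randomness derives from one integer seed through fixed-purpose
substreams; a fixed seed reproduces byte-identical outputs.  What the
generator does **not** model: read-level artifacts (mapping bias,
duplicate reads, GC bias), linkage between panel sites, indels or
breakpoint sequences, inter-site depth correlation.  A green recovery
test therefore establishes that the inference is correct under the
stated sampling model at the stated coverages — not that it is robust to
alignment pathologies of real data, which enter upstream of this
package's inputs.

## Numerical choices and degenerate inputs

Zero-depth sites contribute nothing to f̄ or χ²; windows with no covered
site are excluded from scoring.  Zero reference coverage makes a
window's DOC missing (NaN); missing observables simply drop their
residual term in the fit, and a window with every observable missing is
reported euploid-unknown and never flagged.  Division guards use
explicit masks, not epsilon fudging, except inside vectorised mixture
grids where masked NaNs are replaced by +inf before argmin.  The m grid
step (0.005) bounds the mosaic-fraction quantisation error well below
the 0.1 recovery tolerance.

## Known limitations

* Balanced/reciprocal exchanges leave both observables at their euploid
  expectations and are invisible by construction.
* Events in regions already fixed for an exchange produce no signal
  (the catalog has no heterozygous homoeologous sites there).
* The scan's resolution is one genomic window (~200 kb physical span at
  50% masking); boundary placement inherits that granularity.
* Aberrations covering half the genome or more distort the median DOC
  normalisation; the method presumes a mostly euploid karyotype.
* The mosaic mixture is identifiable only against the balanced state;
  mixtures of two aberrant states are fitted to the nearest
  single-aberration explanation.
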