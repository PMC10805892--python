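# allokaryo

Detection of chromosomal aberrations and homoeologous exchanges in an
allotetraploid species from whole-genome resequencing observables, plus a
windowed nucleotide-diversity / introgression scan over a resequencing
panel.

## The problem

An allotetraploid (such as *Coffea arabica*-type species) carries two
diploid subgenomes inherited from two progenitor species.  Corresponding
chromosomes of the two subgenomes — *homoeologs* — are collinear over
their non-repetitive fraction and differ at *homoeologous sites* (~5%
of aligned positions), so short reads covering such a site reveal which
subgenome they came from.  Meiotic irregularities generate karyotype
changes that segregate in germplasm: whole-chromosome aneuploidies,
segmental deletions and duplications, and *homoeologous exchanges* in
which a segment of one subgenome is replaced by its homoeologous
counterpart.  In a species with very low nucleotide diversity these
events are a major source of standing variation, and they are detectable
from cheap low-coverage resequencing.

## The model

For a genomic interval carried at integer copy numbers
(c<sub>ref</sub>, c<sub>other</sub>) of the two homoeologs, two window
observables have closed-form expectations:

* **Homoeologous variant frequency** (fraction of reads supporting the
  referenced subgenome's allele):
  f = c<sub>ref</sub> / (c<sub>ref</sub> + c<sub>other</sub>) —
  1, 0.75, 0.5, 0.25, 0 for 4:0, 3:1, 2:2, 1:3, 0:2.
  Deviations from the balanced 0.5 are scored per window by the ROH_H
  (reduction of homoeologous heterozygosity) statistic
  χ² = Σ<sub>sites</sub> (a−b)²/(a+b) with df = number of covered sites.
* **Depth-of-coverage (DOC) ratio** per homoeolog, median-normalised
  genome-wide and referenced to a euploid accession:
  E[DOC<sub>s</sub>] = c<sub>s</sub>/2 — 2, 1.5, 1, 0.5, 0 for
  4, 3, 2, 1, 0 copies.

Frequency alone cannot separate an exchange (total copy conserved) from
a deletion/duplication (total changed); DOC resolves the total.  The fit
searches all integer states with total 1–5, then one-parameter mixtures
of each aberrant state with the balanced state to capture somatic
mosaicism (mixture fraction m).  Flagged windows are merged into events,
classified (aneuploidy gain/loss, exchange, deletion, duplication) with
zygosity (heterozygous / homozygous / mosaic); events below 200 kb are
discarded.

Panel diversity uses the per-site unbiased estimator
π = Σ<sub>j</sub> (n<sub>j</sub>/(n<sub>j</sub>−1)) 2p̂<sub>j</sub>(1−p̂<sub>j</sub>)
per 100 kb of non-repetitive window content; introgressed donor
haplotypes appear as blocks of windows whose SNP count exceeds
median + 10·MAD of the bona fide panel baseline.

## Worked example

```sh
allokaryo demo --seed 3 --out demo_out
```

simulates a 4-chromosome-pair genome (2 Mb per chromosome, ~50%
repeat-masked, homoeologous sites at 5% of unmasked bp), injects a
heterozygous terminal exchange on chr1 and a trisomy of the chr2
B-homoeolog into one accession, sequences everything at 5× per copy, and
runs the scan against a simulated euploid reference accession:

```
Karyotype scan: demo
windows scored: 45 / 45
events detected: 2

pair    interval                  type                    state   zygosity      m      windows
chr1    1,174,683-2,000,000       homoeologous_exchange   3:1     heterozygous  1.00   4
chr2    1-2,000,000               aneuploidy_gain         2:3     heterozygous  1.00   12

Diversity scan: 20 accessions, 35354 variant sites, 45 windows
median window pi: 0.000321 /bp
flagging threshold: 93.0 SNPs/window
introgression blocks: 1
  acc01  chr1:1-1,174,682  heterozygous  mean 5325 SNPs/window  (6 windows)
```

Reading the output: the exchange is recovered as copy state 3:1 (the
accession carries three A-homoeolog and one B-homoeolog copies over the
terminal ~0.8 Mb, boundary resolved to one ~200 kb window), the trisomy
as a whole-chromosome 2:3 gain, and the injected donor-introgression
block in panel accession acc01 is flagged because its window SNP counts
(~5,000) dwarf the panel baseline (threshold 93).  The panel's median
window diversity (3.2×10⁻⁴/bp) matches the simulated target.

The same objects are available as a library:

```python
import allokaryo as ak

params = ak.SimulationParams(seed=1)
ref    = ak.simulate_reference(params)
truth  = ak.inject_karyotype(ref, [ak.exchange("acc", "chr1", 4_000_000, 5_000_000)],
                             accessions=["reference", "acc"])
obs    = ak.simulate_observables(ref, truth, params)
res    = ak.KaryotypeModel.from_observables(obs, "acc", "reference", ref).fit()
print(res.summary())        # events, states, zygosity
res.plot_chromosome("chr1") # frequency + DOC tracks with the state grid
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the copy-state model's DOC and
frequency expectation grid; the non-repetitive content of segmentation
windows on a seeded randomly masked 10 Mb chromosome; the mean
homoeologous variant frequency of a simulated heterozygous exchange
(~500 sites, 10× per copy); and the median-normalised DOC ratio of a
simulated whole-chromosome trisomy versus a euploid reference.  Results
are written as JSON keyed by target id.

## Layout

- `src/allokaryo/simulate.py` — seeded synthetic-data generator (reference,
  karyotype truth, observables, diversity panel)
- `src/allokaryo/windows.py` — fixed non-repetitive-content genomic windows
  and sliding variant-count windows
- `src/allokaryo/genotyping.py` — threshold genotype calling (WGS/low-coverage/GBS
  rule sets), reference self-alignment artifact filter, informativeness filter
- `src/allokaryo/karyotype.py` — copy-state model, ROH_H statistic, DOC
  ratios, mosaic mixture fit, event segmentation (`KaryotypeModel`)
- `src/allokaryo/diversity.py` — windowed π and introgression blocks
  (`DiversityScan`)
- `src/allokaryo/cli.py` — `allokaryo` command-line pipeline
- `docs/methods.md` — model assumptions, defaults and limitations
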