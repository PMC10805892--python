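"""Synthetic allotetraploid resequencing data with known karyotype truth.

The generator emulates the statistical structure that the karyotype and
diversity scans assume, at desk scale:

* two collinear homoeologous subgenomes with homoeologous sites at ~5%
  density in unmasked sequence (the progenitor species diverge by ~5% in
  collinear regions);
* a repeat mask covering a configurable fraction of each chromosome;
* injected karyotype events (aneuploidies, deletions, duplications,
  homoeologous exchanges) in heterozygous, homozygous or mosaic state;
* shotgun observables: Poisson site depth, Binomial subgenome-allele
  sampling with a symmetric error rate, Poisson per-window unique
  coverage of each homoeolog;
* a low-diversity panel (pi ~ 3e-4/bp, the level seen in a recently
  formed selfing allotetraploid) with optional introgressed blocks whose
  local diversity is ~10x higher, mimicking donor-species haplotypes.

No read-level data are produced: the simulator emits the summary
observables the analysis consumes (allele depths at catalog sites and
per-window coverage), not FASTQ.

Everything is driven by a single integer seed; fixing the seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .reference import ChromosomePair, ReferenceModel
from .windows import DEFAULT_WINDOW_CONTENT, genome_windows

# fixed stream ids so each generation stage has an independent substream
_STREAM_MASK = 1
_STREAM_SITES = 2
_STREAM_OBS = 4
_STREAM_PANEL = 5
_STREAM_FASTA = 6

BASES = np.array(list("ACGT"))


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Stated world of the generator.

    Parameters
    ----------
    n_chromosome_pairs
        Number of homoeologous chromosome pairs.  Default 4 (desk scale):
        enough that a single whole-chromosome aneuploidy remains a
        minority of the genome, which the median-based DOC normalisation
        of the scan requires.
    chromosome_length
        Length of every chromosome, bp.  Desk-scale default (5 Mb) rather
        than the ~50 Mb of a real chromosome; all rates are per-bp so the
        statistics scale.
    homoeologous_site_density
        Probability per unmasked bp of a homoeologous site (~0.05, i.e.
        ~95% sequence identity between subgenomes in collinear regions).
    repeat_fraction_profile
        Masked fraction, either one value for the whole genome or a
        sequence of per-region fractions applied to equal slices of each
        chromosome.
    coverage_per_copy
        Mean mapped depth per single chromosome copy (x-fold).  Default 2,
        i.e. 8x for a euploid tetraploid accession — typical of shallow
        public resequencing panels.
    sequencing_error
        Probability that a read supports the wrong subgenome at a site.
    panel_pi
        Target within-panel nucleotide diversity per bp.
    introgression_pi_multiplier
        Fold increase of local diversity inside introgressed blocks.
    seed
        Master seed; every stage derives its stream from it.
    """

    n_chromosome_pairs: int = 4
    chromosome_length: int = 5_000_000
    homoeologous_site_density: float = 0.05
    repeat_fraction_profile: float | Sequence[float] = 0.5
    coverage_per_copy: float = 2.0
    sequencing_error: float = 0.001
    panel_pi: float = 3.12e-4
    introgression_pi_multiplier: float = 10.0
    seed: int = 0
    mask_block_scale: int = 10_000  # mean repeat/non-repeat block length, bp

    def __post_init__(self) -> None:
        if self.n_chromosome_pairs < 1 or self.chromosome_length < 1:
            raise ValueError("counts and lengths must be positive")
        fractions = np.atleast_1d(np.asarray(self.repeat_fraction_profile, dtype=float))
        for name, v in [
            ("homoeologous_site_density", self.homoeologous_site_density),
            ("sequencing_error", self.sequencing_error),
        ]:
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if np.any(fractions < 0) or np.any(fractions > 1):
            raise ValueError("repeat fractions must be in [0, 1]")
        if self.coverage_per_copy < 0 or self.panel_pi < 0:
            raise ValueError("coverage and diversity must be non-negative")

    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, *extra])


@dataclasses.dataclass(frozen=True)
class TruthEvent:
    """One injected karyotype event.

    ``c_a``/``c_b`` are the copy numbers of the two homoeologs inside the
    interval in the aberrant cell population; ``m`` is the fraction of
    cells carrying the aberration (1 = constitutive, <1 = somatic
    mosaic).
    """

    accession: str
    pair: str
    start: int
    end: int
    c_a: int
    c_b: int
    m: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.c_a <= 4 and 0 <= self.c_b <= 4):
            raise ValueError("per-homoeolog copy number must be in 0..4")
        if not 0 <= self.c_a + self.c_b <= 5:
            raise ValueError("total copy number must be in 0..5")
        if not 0 <= self.m <= 1:
            raise ValueError("mosaic fraction must be in [0, 1]")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("event interval must be non-empty and non-negative")

    @property
    def total(self) -> int:
        return self.c_a + self.c_b


@dataclasses.dataclass
class SyntheticTruth:
    """Injected events plus the accessions they belong to."""

    accessions: list[str]
    events: list[TruthEvent]

    def events_for(self, accession: str, pair: str | None = None) -> list[TruthEvent]:
        out = [e for e in self.events if e.accession == accession]
        if pair is not None:
            out = [e for e in out if e.pair == pair]
        return out


# ----------------------------------------------------------------------
# reference
# ----------------------------------------------------------------------

def _simulate_mask(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Alternating repeat/non-repeat blocks with per-region masked fraction."""
    fractions = np.atleast_1d(np.asarray(params.repeat_fraction_profile, dtype=float))
    L = params.chromosome_length
    edges = np.linspace(0, L, fractions.size + 1).astype(np.int64)
    intervals: list[tuple[int, int]] = []
    for frac, lo, hi in zip(fractions, edges[:-1], edges[1:]):
        if frac <= 0:
            continue
        if frac >= 1:
            intervals.append((int(lo), int(hi)))
            continue
        pos = int(lo)
        masked = rng.random() < frac
        scale = params.mask_block_scale
        while pos < hi:
            mean = scale * (frac if masked else (1 - frac))
            run = int(rng.exponential(mean)) + 1
            end = min(pos + run, int(hi))
            if masked:
                intervals.append((pos, end))
            pos = end
            masked = not masked
    # merge touching intervals
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64).reshape(-1, 2)


def simulate_reference(params: SimulationParams) -> ReferenceModel:
    """Generate the two-subgenome reference: pairs, repeat mask and site catalog.

    Homoeologous sites are placed only in unmasked sequence, each unmasked
    bp independently hosting a site with probability
    ``homoeologous_site_density``; the two subgenomes receive distinct
    alleles at every site.
    """
    pairs = [
        ChromosomePair(f"chr{i + 1}", f"chr{i + 1}a", f"chr{i + 1}b", params.chromosome_length)
        for i in range(params.n_chromosome_pairs)
    ]
    mask: dict[str, np.ndarray] = {}
    rows = []
    for i, p in enumerate(pairs):
        mask_rng = params.rng(_STREAM_MASK, i)
        site_rng = params.rng(_STREAM_SITES, i)
        iv = _simulate_mask(params, mask_rng)
        mask[p.name] = iv
        is_masked = np.zeros(p.length, dtype=bool)
        for s, e in iv:
            is_masked[s:e] = True
        unmasked_pos = np.flatnonzero(~is_masked)
        if unmasked_pos.size and params.homoeologous_site_density > 0:
            if unmasked_pos.size * params.homoeologous_site_density < 1:
                raise ValueError(
                    f"{p.name}: site density x unmasked length yields <1 expected site"
                )
            keep = site_rng.random(unmasked_pos.size) < params.homoeologous_site_density
            pos = unmasked_pos[keep]
            allele_a = site_rng.integers(0, 4, size=pos.size)
            shift = site_rng.integers(1, 4, size=pos.size)
            allele_b = (allele_a + shift) % 4
            rows.append(
                pd.DataFrame(
                    {
                        "pair": p.name,
                        "pos": pos,
                        "allele_a": BASES[allele_a],
                        "allele_b": BASES[allele_b],
                    }
                )
            )
    if rows:
        catalog = pd.concat(rows, ignore_index=True)
    else:
        catalog = pd.DataFrame(columns=["pair", "pos", "allele_a", "allele_b"])
    return ReferenceModel(pairs=pairs, mask=mask, catalog=catalog)


def reference_sequences(ref: ReferenceModel, params: SimulationParams) -> dict[str, str]:
    """Random chromosome sequences carrying the catalog alleles (for FASTA output)."""
    out: dict[str, str] = {}
    base_index = {b: i for i, b in enumerate(BASES)}
    for i, p in enumerate(ref.pairs):
        rng = params.rng(_STREAM_FASTA, i)
        seq = rng.integers(0, 4, size=p.length)
        sel = ref.catalog[ref.catalog["pair"] == p.name]
        pos = sel["pos"].to_numpy()
        seq_a = seq.copy()
        seq_b = seq.copy()
        if pos.size:
            seq_a[pos] = [base_index[a] for a in sel["allele_a"]]
            seq_b[pos] = [base_index[b] for b in sel["allele_b"]]
        out[p.name_a] = "".join(BASES[seq_a])
        out[p.name_b] = "".join(BASES[seq_b])
    return out


# ----------------------------------------------------------------------
# karyotype injection
# ----------------------------------------------------------------------

def inject_karyotype(
    ref: ReferenceModel,
    requests: Sequence[TruthEvent] | None = None,
    accessions: Sequence[str] | None = None,
) -> SyntheticTruth:
    """Validate event requests against the reference and record the truth.

    Events of one accession on the same chromosome pair must not overlap;
    copy numbers are validated by :class:`TruthEvent`.  An empty request
    list yields an all-euploid (2,2) truth.
    """
    requests = list(requests or [])
    for ev in requests:
        pair = ref.pair(ev.pair)  # KeyError if unknown
        if ev.end > pair.length:
            raise ValueError(f"event on {ev.pair} exceeds chromosome bounds")
    by_key: dict[tuple[str, str], list[TruthEvent]] = {}
    for ev in requests:
        by_key.setdefault((ev.accession, ev.pair), []).append(ev)
    for (acc, pair), evs in by_key.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping events for {acc} on {pair}")
    accs = list(accessions) if accessions is not None else []
    for ev in requests:
        if ev.accession not in accs:
            accs.append(ev.accession)
    return SyntheticTruth(accessions=accs, events=requests)


def trisomy(accession: str, ref: ReferenceModel, pair: str, subgenome: str = "A") -> TruthEvent:
    """Whole-chromosome gain of one homoeolog: copy state (3,2) or (2,3)."""
    length = ref.pair(pair).length
    c_a, c_b = (3, 2) if subgenome == "A" else (2, 3)
    return TruthEvent(accession, pair, 0, length, c_a, c_b)


def monosomy(accession: str, ref: ReferenceModel, pair: str, subgenome: str = "A") -> TruthEvent:
    """Whole-chromosome loss of one homoeolog: copy state (1,2) or (2,1)."""
    length = ref.pair(pair).length
    c_a, c_b = (1, 2) if subgenome == "A" else (2, 1)
    return TruthEvent(accession, pair, 0, length, c_a, c_b)


def exchange(
    accession: str,
    pair: str,
    start: int,
    end: int,
    toward: str = "A",
    homozygous: bool = False,
    m: float = 1.0,
) -> TruthEvent:
    """Homoeologous exchange: total copy number 4 conserved, ratio shifted.

    Heterozygous exchange toward A gives (3,1); homozygous gives (4,0).
    """
    if homozygous:
        c_a, c_b = (4, 0) if toward == "A" else (0, 4)
    else:
        c_a, c_b = (3, 1) if toward == "A" else (1, 3)
    return TruthEvent(accession, pair, start, end, c_a, c_b, m)


def deletion(
    accession: str, pair: str, start: int, end: int, subgenome: str = "A",
    homozygous: bool = False, m: float = 1.0,
) -> TruthEvent:
    """Segmental loss of one homoeolog: (1,2) heterozygous or (0,2) homozygous."""
    lost = 0 if homozygous else 1
    c_a, c_b = (lost, 2) if subgenome == "A" else (2, lost)
    return TruthEvent(accession, pair, start, end, c_a, c_b, m)


def duplication(
    accession: str, pair: str, start: int, end: int, subgenome: str = "A", m: float = 1.0
) -> TruthEvent:
    """Segmental gain of one homoeolog copy: (3,2) or (2,3)."""
    c_a, c_b = (3, 2) if subgenome == "A" else (2, 3)
    return TruthEvent(accession, pair, start, end, c_a, c_b, m)


# ----------------------------------------------------------------------
# observables
# ----------------------------------------------------------------------

@dataclasses.dataclass
class Observables:
    """Simulated resequencing observables for a set of accessions.

    site_depth
        Columns: accession, pair, pos (0-based), a_depth, b_depth —
        reads supporting the subgenome-A and subgenome-B allele at each
        catalog site.
    coverage
        Columns: accession, pair, start, end, subgenome ('A'/'B'),
        depth — mean per-bp unique-mapping coverage of that homoeolog in
        the window.
    windows
        The genomic windows used for the coverage table.
    """

    site_depth: pd.DataFrame
    coverage: pd.DataFrame
    windows: pd.DataFrame

    def accession_site_depth(self, accession: str) -> pd.DataFrame:
        return self.site_depth[self.site_depth["accession"] == accession].reset_index(drop=True)

    def accession_coverage(self, accession: str) -> pd.DataFrame:
        return self.coverage[self.coverage["accession"] == accession].reset_index(drop=True)


def _effective_copies(
    ref: ReferenceModel, truth: SyntheticTruth, accession: str, pair: str,
    positions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-population-averaged copy numbers of the two homoeologs per position."""
    c_a = np.full(positions.shape, 2.0)
    c_b = np.full(positions.shape, 2.0)
    for ev in truth.events_for(accession, pair):
        inside = (positions >= ev.start) & (positions < ev.end)
        c_a[inside] = ev.m * ev.c_a + (1 - ev.m) * 2.0
        c_b[inside] = ev.m * ev.c_b + (1 - ev.m) * 2.0
    return c_a, c_b


def _window_mean_copies(
    ref: ReferenceModel, truth: SyntheticTruth, accession: str, pair: str,
    starts: np.ndarray, ends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Span-weighted mean copy number of each homoeolog per window."""
    c_a = np.full(starts.shape, 2.0)
    c_b = np.full(starts.shape, 2.0)
    span = (ends - starts).astype(float)
    for ev in truth.events_for(accession, pair):
        ov = np.clip(np.minimum(ends, ev.end) - np.maximum(starts, ev.start), 0, None)
        frac = ov / span
        ea = ev.m * ev.c_a + (1 - ev.m) * 2.0
        eb = ev.m * ev.c_b + (1 - ev.m) * 2.0
        c_a += frac * (ea - 2.0)
        c_b += frac * (eb - 2.0)
    return c_a, c_b


def simulate_observables(
    ref: ReferenceModel,
    truth: SyntheticTruth,
    params: SimulationParams,
    window_content: int = DEFAULT_WINDOW_CONTENT,
    windows: pd.DataFrame | None = None,
) -> Observables:
    """Draw site allele depths and per-window coverage for every accession.

    At each catalog site the total depth is Poisson with mean
    ``coverage_per_copy x total effective copies``; reads supporting the
    subgenome-A allele are Binomial with success probability equal to the
    copy-number allele fraction perturbed by the symmetric error rate
    (observed f = f(1-e) + (1-f)e).  Window coverage of homoeolog s is
    Poisson with mean ``coverage_per_copy x c_s x nonrepetitive_bp``,
    reported per unmasked bp — emulating unique-mapping coverage counted
    on non-repetitive sequence only.
    """
    if windows is None:
        windows = genome_windows(ref, window_content)
    eps = params.sequencing_error
    depth_rows = []
    cov_rows = []
    for ai, acc in enumerate(truth.accessions):
        rng = params.rng(_STREAM_OBS, ai)
        for p in ref.pairs:
            pos = ref.sites(p.name)
            c_a, c_b = _effective_copies(ref, truth, acc, p.name, pos)
            total = c_a + c_b
            depth = rng.poisson(params.coverage_per_copy * total)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(total > 0, c_a / np.maximum(total, 1e-12), 0.0)
            f_obs = f * (1 - eps) + (1 - f) * eps
            a = rng.binomial(depth, f_obs)
            b = depth - a
            depth_rows.append(
                pd.DataFrame(
                    {"accession": acc, "pair": p.name, "pos": pos, "a_depth": a, "b_depth": b}
                )
            )
            w = windows[windows["pair"] == p.name]
            starts = w["start"].to_numpy()
            ends = w["end"].to_numpy()
            nonrep = w["nonrepetitive_bp"].to_numpy().astype(float)
            wc_a, wc_b = _window_mean_copies(ref, truth, acc, p.name, starts, ends)
            for sub, wc in (("A", wc_a), ("B", wc_b)):
                counts = rng.poisson(params.coverage_per_copy * wc * nonrep)
                cov = np.where(nonrep > 0, counts / np.maximum(nonrep, 1.0), 0.0)
                cov_rows.append(
                    pd.DataFrame(
                        {
                            "accession": acc,
                            "pair": p.name,
                            "start": starts,
                            "end": ends,
                            "subgenome": sub,
                            "depth": cov,
                        }
                    )
                )
    site_depth = pd.concat(depth_rows, ignore_index=True) if depth_rows else pd.DataFrame(
        columns=["accession", "pair", "pos", "a_depth", "b_depth"]
    )
    coverage = pd.concat(cov_rows, ignore_index=True) if cov_rows else pd.DataFrame(
        columns=["accession", "pair", "start", "end", "subgenome", "depth"]
    )
    return Observables(site_depth=site_depth, coverage=coverage, windows=windows)


# ----------------------------------------------------------------------
# diversity panel
# ----------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class IntrogressionRequest:
    """A donor-haplotype block to inject into one panel accession."""

    accession: str
    pair: str
    start: int
    end: int
    zygosity: str = "heterozygous"  # or "homozygous"

    def __post_init__(self) -> None:
        if self.zygosity not in ("heterozygous", "homozygous"):
            raise ValueError("zygosity must be heterozygous or homozygous")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("block interval must be non-empty")


@dataclasses.dataclass
class Panel:
    """Simulated diversity panel.

    sites: DataFrame (pair, pos); genotypes: (n_sites x n_accessions)
    int8 code matrix (0 hom_ref / 1 het / 2 hom_alt); blocks: the
    injected introgression truth.
    """

    accessions: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    blocks: list[IntrogressionRequest]


def _unbiased_het(p: np.ndarray | float, n_alleles: int) -> np.ndarray | float:
    return (n_alleles / (n_alleles - 1)) * 2.0 * p * (1.0 - p)


def simulate_panel(
    ref: ReferenceModel,
    n_accessions: int,
    params: SimulationParams,
    blocks: Sequence[IntrogressionRequest] | None = None,
) -> Panel:
    """Simulate panel genotypes at target diversity, with optional donor blocks.

    Background variation: biallelic sites are placed on unmasked sequence
    at the per-bp density that makes the expected per-bp unbiased
    diversity equal ``panel_pi``; each site's derived allele is carried
    homozygously by k accessions, k uniform on 1..n-1 (a highly selfing,
    highly homozygous panel).  Introgressed blocks add accession-private
    alleles at the density that lifts local diversity to
    ``panel_pi x introgression_pi_multiplier``; block carriers are
    heterozygous or homozygous per the request, emulating unfixed versus
    fixed donor haplotypes.
    """
    if n_accessions < 2:
        raise ValueError("panel needs at least 2 accessions")
    blocks = list(blocks or [])
    accs = [f"acc{i + 1:02d}" for i in range(n_accessions)]
    acc_index = {a: i for i, a in enumerate(accs)}
    for b in blocks:
        if b.accession not in acc_index:
            raise ValueError(f"unknown accession {b.accession}")
        if b.end > ref.pair(b.pair).length:
            raise ValueError("block exceeds chromosome bounds")
    n = n_accessions
    n_alleles = 2 * n
    # expected per-site unbiased heterozygosity under k ~ U{1..n-1}, hom carriers
    exp_het = _unbiased_het((np.arange(1, n) / n), n_alleles)
    mean_het = float(np.mean(exp_het))
    base_density = params.panel_pi / mean_het if mean_het > 0 else 0.0

    sites_rows = []
    geno_cols = []
    for ci, p in enumerate(ref.pairs):
        rng = params.rng(_STREAM_PANEL, ci)
        is_masked = ref.mask_array(p.name)
        unmasked_pos = np.flatnonzero(~is_masked)
        if unmasked_pos.size == 0:
            continue
        keep = rng.random(unmasked_pos.size) < base_density
        pos = unmasked_pos[keep]
        geno = np.zeros((pos.size, n), dtype=np.int8)
        k = rng.integers(1, n, size=pos.size)
        for j in range(pos.size):
            carriers = rng.choice(n, size=k[j], replace=False)
            geno[j, carriers] = 2
        # introgressed blocks: accession-private donor alleles
        extra_pos = []
        extra_geno = []
        for b in blocks:
            if b.pair != p.name:
                continue
            hom = b.zygosity == "homozygous"
            p_one = (2 if hom else 1) / n_alleles
            het_one = _unbiased_het(p_one, n_alleles)
            add_density = params.panel_pi * (params.introgression_pi_multiplier - 1) / het_one
            in_block = unmasked_pos[(unmasked_pos >= b.start) & (unmasked_pos < b.end)]
            keep_b = rng.random(in_block.size) < add_density
            bp_pos = in_block[keep_b]
            g = np.zeros((bp_pos.size, n), dtype=np.int8)
            g[:, acc_index[b.accession]] = 2 if hom else 1
            extra_pos.append(bp_pos)
            extra_geno.append(g)
        if extra_pos:
            pos = np.concatenate([pos, *extra_pos])
            geno = np.vstack([geno, *extra_geno])
            order = np.argsort(pos, kind="stable")
            pos = pos[order]
            geno = geno[order]
        sites_rows.append(pd.DataFrame({"pair": p.name, "pos": pos}))
        geno_cols.append(geno)
    if sites_rows:
        sites = pd.concat(sites_rows, ignore_index=True)
        genotypes = np.vstack(geno_cols)
    else:
        sites = pd.DataFrame(columns=["pair", "pos"])
        genotypes = np.zeros((0, n), dtype=np.int8)
    truth_blocks = blocks if params.introgression_pi_multiplier > 1 else []
    return Panel(accessions=accs, sites=sites, genotypes=genotypes, blocks=truth_blocks)
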