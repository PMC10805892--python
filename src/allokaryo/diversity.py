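"""Windowed nucleotide diversity and introgression-block detection.

Nucleotide diversity (pi) is estimated per genomic window from a panel
genotype matrix with the per-site unbiased heterozygosity estimator

    pi = sum_j [ n_j/(n_j - 1) * 2 p_j (1 - p_j) ] / nonrepetitive_bp

where n_j is the number of called alleles and p_j the sample alternative
allele frequency at site j; missing genotypes reduce n_j.  Dividing by
the window's non-repetitive content (rather than its physical span)
matches the window definition: each window holds a fixed amount of
alignable sequence.

In a recently formed allotetraploid the within-species diversity is very
low (median pi ~ 3e-4/bp here), while the progenitor/donor species is an
order of magnitude more diverse.  An accession that carries an
introgressed donor haplotype therefore shows a block of consecutive
windows whose SNP count is far above the panel baseline; those windows
are flagged with a robust threshold (baseline median + k*MAD over
per-window counts of bona fide accessions) and merged into candidate
introgression blocks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotyping import HET, HOM_ALT, MISSING


@dataclasses.dataclass
class DiversityConfig:
    """Thresholds of the diversity scan.

    The flagging threshold is baseline median + mad_k * MAD of per-window
    SNP counts pooled over baseline accessions; with a degenerate all-zero
    baseline the threshold floor applies.  Adjacent flagged windows merge
    across up to gap_windows unflagged windows.
    """

    mad_k: float = 10.0
    threshold_floor: int = 5
    gap_windows: int = 1


@dataclasses.dataclass(frozen=True)
class IntrogressionBlock:
    """A run of consecutive high-diversity windows in one accession."""

    accession: str
    pair: str
    start: int
    end: int
    zygosity: str
    mean_snp_count: float
    n_windows: int


def window_pi(
    genotypes: np.ndarray, nonrepetitive_bp: int
) -> float:
    """Unbiased per-bp nucleotide diversity of one window.

    `genotypes` is a (sites x accessions) code matrix restricted to the
    window's sites.  Windows without callable sites return 0 (the caller
    should carry a missingness flag alongside).  Invariant under swapping
    the reference/alternative labelling of any site.
    """
    if nonrepetitive_bp <= 0:
        raise ValueError("window must contain non-repetitive sequence")
    g = np.asarray(genotypes)
    if g.size == 0:
        return 0.0
    called = g != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    ok = n_alleles >= 2
    if not ok.any():
        return 0.0
    n = n_alleles[ok].astype(float)
    p = alt[ok] / n
    het = (n / (n - 1)) * 2.0 * p * (1.0 - p)
    return float(het.sum() / nonrepetitive_bp)


def snp_counts(
    sites: pd.DataFrame, genotypes: np.ndarray, windows: pd.DataFrame,
    accessions: list[str],
) -> pd.DataFrame:
    """Per-accession homozygous and heterozygous SNP counts per window.

    Returns a long DataFrame: pair, start, end, accession, het_snps,
    hom_snps, snps.
    """
    rows = []
    for w in windows.itertuples():
        in_w = (
            (sites["pair"] == w.pair)
            & (sites["pos"] >= w.start)
            & (sites["pos"] < w.end)
        ).to_numpy()
        g = genotypes[in_w]
        het = (g == HET).sum(axis=0)
        hom = (g == HOM_ALT).sum(axis=0)
        for ai, acc in enumerate(accessions):
            rows.append(
                (w.pair, w.start, w.end, acc, int(het[ai]), int(hom[ai]))
            )
    out = pd.DataFrame(
        rows, columns=["pair", "start", "end", "accession", "het_snps", "hom_snps"]
    )
    out["snps"] = out["het_snps"] + out["hom_snps"]
    return out


def flag_introgressed_windows(
    counts: pd.DataFrame,
    baseline_accessions: list[str],
    config: DiversityConfig | None = None,
) -> pd.DataFrame:
    """Flag windows whose SNP count exceeds the baseline-derived threshold.

    `counts` is the long table from :func:`snp_counts`.  The threshold is
    a single genome-wide value: median + mad_k * MAD over the pooled
    per-window counts of the baseline (bona fide) accessions; if the
    baseline is degenerate (all zero) the floor applies.  A flagged
    window's zygosity is the dominant genotype class among its SNPs.
    """
    config = config or DiversityConfig()
    base = counts[counts["accession"].isin(baseline_accessions)]["snps"].to_numpy()
    if base.size == 0:
        raise ValueError("no baseline accessions found in the count table")
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    threshold = med + config.mad_k * mad
    if threshold <= 0:
        threshold = float(config.threshold_floor)
    out = counts.copy()
    out["threshold"] = threshold
    out["flagged"] = out["snps"] > threshold
    out["zygosity"] = np.where(
        out["hom_snps"] > out["het_snps"], "homozygous", "heterozygous"
    )
    return out


def merge_blocks(
    flags: pd.DataFrame, gap_windows: int = 1
) -> list[IntrogressionBlock]:
    """Merge consecutive flagged windows into introgression blocks.

    Windows are grouped per accession and chromosome in positional order;
    runs of flagged windows separated by at most `gap_windows` unflagged
    windows merge into one block spanning first to last flagged window.
    Block zygosity is the majority zygosity of its windows.
    """
    blocks: list[IntrogressionBlock] = []
    for (acc, pair), grp in flags.groupby(["accession", "pair"], sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        current: list = []
        gap = 0
        runs = []
        for row in grp.itertuples():
            if row.flagged:
                current.append(row)
                gap = 0
            else:
                gap += 1
                if current and gap > gap_windows:
                    runs.append(current)
                    current = []
        if current:
            runs.append(current)
        for run in runs:
            zyg = (
                "homozygous"
                if sum(r.zygosity == "homozygous" for r in run) > len(run) / 2
                else "heterozygous"
            )
            blocks.append(
                IntrogressionBlock(
                    accession=str(acc),
                    pair=str(pair),
                    start=int(run[0].start),
                    end=int(run[-1].end),
                    zygosity=zyg,
                    mean_snp_count=float(np.mean([r.snps for r in run])),
                    n_windows=len(run),
                )
            )
    return blocks


class DiversityScan:
    """Windowed diversity and introgression scan over a panel.

    Parameters
    ----------
    sites, genotypes, accessions
        Panel variant sites (pair, pos), the (sites x accessions) code
        matrix and the accession names.
    windows
        Genomic windows (pair, start, end, nonrepetitive_bp).
    baseline
        Accessions treated as bona fide (introgression-free) for the
        flagging threshold; defaults to all accessions, which is
        conservative when introgressed material is a small minority
        (the median/MAD baseline is robust to it).
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        genotypes: np.ndarray,
        accessions: list[str],
        windows: pd.DataFrame,
        baseline: list[str] | None = None,
        config: DiversityConfig | None = None,
    ):
        if len(accessions) != genotypes.shape[1]:
            raise ValueError("genotype matrix width must match accession count")
        self.sites = sites.reset_index(drop=True)
        self.genotypes = np.asarray(genotypes)
        self.accessions = list(accessions)
        self.windows = windows.reset_index(drop=True)
        self.baseline = list(baseline) if baseline is not None else list(accessions)
        self.config = config or DiversityConfig()

    @classmethod
    def from_panel(cls, panel, windows, baseline=None, config=None) -> "DiversityScan":
        return cls(
            panel.sites, panel.genotypes, panel.accessions, windows, baseline, config
        )

    def fit(self) -> "DiversityResults":
        pi_rows = []
        for w in self.windows.itertuples():
            in_w = (
                (self.sites["pair"] == w.pair)
                & (self.sites["pos"] >= w.start)
                & (self.sites["pos"] < w.end)
            ).to_numpy()
            g = self.genotypes[in_w]
            pi = window_pi(g, int(w.nonrepetitive_bp)) if w.nonrepetitive_bp > 0 else 0.0
            pi_rows.append(
                (w.pair, w.start, w.end, int(w.nonrepetitive_bp), int(in_w.sum()), pi)
            )
        pi_table = pd.DataFrame(
            pi_rows, columns=["pair", "start", "end", "nonrepetitive_bp", "n_sites", "pi"]
        )
        counts = snp_counts(self.sites, self.genotypes, self.windows, self.accessions)
        flags = flag_introgressed_windows(counts, self.baseline, self.config)
        blocks = merge_blocks(flags, self.config.gap_windows)
        return DiversityResults(self, pi_table, counts, flags, blocks)


class DiversityResults:
    """Per-window diversity, SNP counts, flags and merged blocks."""

    def __init__(self, model, pi_table, counts, flags, blocks):
        self.model = model
        self.pi_table = pi_table
        self.counts = counts
        self.flags = flags
        self.blocks = blocks

    def median_pi(self) -> float:
        """Median per-window nucleotide diversity across the genome."""
        return float(self.pi_table["pi"].median())

    def blocks_frame(self) -> pd.DataFrame:
        cols = ["accession", "pair", "start", "end", "zygosity", "mean_snp_count", "n_windows"]
        return pd.DataFrame(
            [[getattr(b, c) for c in cols] for b in self.blocks], columns=cols
        )

    def summary(self) -> str:
        lines = [
            f"Diversity scan: {len(self.model.accessions)} accessions,"
            f" {len(self.model.sites)} variant sites, {len(self.pi_table)} windows",
            f"median window pi: {self.median_pi():.3g} /bp",
            f"flagging threshold: {self.flags['threshold'].iloc[0]:.1f} SNPs/window",
            f"introgression blocks: {len(self.blocks)}",
        ]
        for b in self.blocks:
            lines.append(
                f"  {b.accession}  {b.pair}:{b.start + 1:,}-{b.end:,}"
                f"  {b.zygosity}  mean {b.mean_snp_count:.0f} SNPs/window"
                f"  ({b.n_windows} windows)"
            )
        return "\n".join(lines)
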