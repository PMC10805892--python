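"""Genome segmentation into the two window systems used by the scans.

Two complementary window definitions:

* **Genomic windows** of variable physical size but fixed *non-repetitive*
  content (default 100 kb of unmasked sequence per window).  Repeat-rich
  regions are unreliable for both read mapping and variant calling, so
  normalising window content by unmasked sequence keeps the information
  content per window roughly constant along the chromosome.
* **Variant windows**: sliding windows containing a fixed number of
  variant sites (default 500) advancing by a fixed step (default 250
  sites), used by the chi-square scan over homoeologous allele
  frequencies.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .reference import ReferenceModel, intervals_complement

DEFAULT_WINDOW_CONTENT = 100_000  # unmasked bp per genomic window
DEFAULT_N_SITES = 500
DEFAULT_STEP = 250


@dataclasses.dataclass(frozen=True)
class GenomicWindow:
    """A window of fixed non-repetitive content (0-based half-open)."""

    chrom: str
    start: int
    end: int
    nonrepetitive_bp: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class VariantWindow:
    """A window over a run of variant sites (indices into the sorted site list)."""

    chrom: str
    first: int          # index of the first site
    last: int           # index past the last site (half-open)
    start: int          # genomic position of the first site (0-based)
    end: int            # genomic position past the last site

    @property
    def n_sites(self) -> int:
        return self.last - self.first


def segment_by_nonrepetitive(
    length: int,
    mask: np.ndarray | None,
    content: int = DEFAULT_WINDOW_CONTENT,
    chrom: str = "chr",
) -> list[GenomicWindow]:
    """Tile a chromosome into windows each holding `content` unmasked bp.

    A window closes immediately after the base that completes `content`
    unmasked bp, so every window except possibly the last holds exactly
    `content` bp of non-repetitive sequence; trailing masked bases attach
    to the next window.  A terminal remainder window is emitted iff it
    contains unmasked sequence; a fully-masked chromosome yields no
    windows.  If the chromosome ends in masked sequence, those trailing
    bases attach to the final emitted window so that the windows tile the
    chromosome.
    """
    if content <= 0:
        raise ValueError("window content must be positive")
    if length <= 0:
        raise ValueError("chromosome length must be positive")
    if mask is None:
        mask = np.empty((0, 2), dtype=np.int64)
    unmasked = intervals_complement(mask, length)
    if unmasked.size == 0:
        return []
    seg_len = unmasked[:, 1] - unmasked[:, 0]
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    total = int(cum[-1])

    boundaries = []
    for target in range(content, total + 1, content):
        i = int(np.searchsorted(cum, target, side="left")) - 1
        pos = int(unmasked[i, 0] + (target - cum[i]))
        boundaries.append(pos)

    windows: list[GenomicWindow] = []
    prev = 0
    for b in boundaries:
        windows.append(GenomicWindow(chrom, prev, b, content))
        prev = b
    remainder = total - len(boundaries) * content
    if remainder > 0:
        windows.append(GenomicWindow(chrom, prev, length, remainder))
    elif windows:
        # attach trailing fully-masked tail to the last window
        last = windows[-1]
        if last.end < length:
            windows[-1] = GenomicWindow(chrom, last.start, length, last.nonrepetitive_bp)
    return windows


def genome_windows(
    ref: ReferenceModel, content: int = DEFAULT_WINDOW_CONTENT
) -> pd.DataFrame:
    """Segment every chromosome pair of a reference model.

    Returns a DataFrame with columns pair, start, end, nonrepetitive_bp.
    """
    rows = []
    for p in ref.pairs:
        for w in segment_by_nonrepetitive(p.length, ref.mask.get(p.name), content, p.name):
            rows.append((w.chrom, w.start, w.end, w.nonrepetitive_bp))
    return pd.DataFrame(rows, columns=["pair", "start", "end", "nonrepetitive_bp"])


def sliding_variant_windows(
    positions: np.ndarray,
    n_sites: int = DEFAULT_N_SITES,
    step: int = DEFAULT_STEP,
    chrom: str = "chr",
) -> list[VariantWindow]:
    """Sliding windows of `n_sites` variant sites advancing by `step` sites.

    Consecutive full windows share ``n_sites - step`` sites.  When the
    chromosome has no more than `n_sites` sites a single window holds them
    all; otherwise windows start at every multiple of `step` below the
    site count and the trailing windows may be smaller.
    """
    if n_sites <= 0 or step <= 0:
        raise ValueError("n_sites and step must be positive")
    if n_sites < step:
        raise ValueError("n_sites must be >= step (windows must overlap or abut)")
    positions = np.asarray(positions)
    if positions.size and np.any(np.diff(positions) < 0):
        raise ValueError("site positions must be sorted")
    n = positions.size
    if n == 0:
        return []
    if n <= n_sites:
        starts = [0]
    else:
        starts = list(range(0, n, step))
    out = []
    for s in starts:
        e = min(s + n_sites, n)
        out.append(
            VariantWindow(chrom, s, e, int(positions[s]), int(positions[e - 1]) + 1)
        )
    return out
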