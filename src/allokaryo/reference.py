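"""Two-subgenome reference model for an allotetraploid.

An allotetraploid carries two complete diploid chromosome sets inherited
from two progenitor species.  Corresponding chromosomes of the two sets
(*homoeologs*) are collinear over much of their length but differ at
*homoeologous sites*: positions where the two subgenomes carry different
alleles, so that short reads covering such a site reveal which subgenome
they came from.  The :class:`ReferenceModel` is the coordinate universe
for all downstream analyses: the chromosome pairs, the repeat mask, and
the catalog of homoeologous sites.

Coordinates are 0-based half-open internally and in BED output; 1-based
in human-readable reports.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class ChromosomePair:
    """One pair of homoeologous chromosomes sharing a coordinate system.

    The two homoeologs are modelled as collinear: positions on subgenome A
    correspond 1:1 to positions on subgenome B.  Real subgenomes diverge
    structurally in repeat-rich regions, but those regions are masked out
    of every analysis here, so the collinear approximation only has to
    hold for the non-repetitive fraction.
    """

    name: str
    name_a: str
    name_b: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be positive")


@dataclasses.dataclass
class ReferenceModel:
    """Chromosome pairs, repeat mask and homoeologous-site catalog.

    Parameters
    ----------
    pairs
        Chromosome pairs, in karyotype order.
    mask
        Repeat-mask intervals per pair name: an ``(n, 2)`` integer array of
        0-based half-open ``[start, end)`` intervals, sorted and
        non-overlapping.
    catalog
        Homoeologous-site catalog: DataFrame with columns ``pair``,
        ``pos`` (0-based), ``allele_a``, ``allele_b``.  Alleles differ
        between subgenomes at every site.
    """

    pairs: list[ChromosomePair]
    mask: dict[str, np.ndarray]
    catalog: pd.DataFrame

    def __post_init__(self) -> None:
        names = [p.name for p in self.pairs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome pair names")
        for name, iv in self.mask.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            self.mask[name] = iv
            if iv.size:
                if np.any(iv[:, 0] >= iv[:, 1]):
                    raise ValueError(f"{name}: empty/inverted mask interval")
                if np.any(iv[1:, 0] < iv[:-1, 1]):
                    raise ValueError(f"{name}: mask intervals overlap or unsorted")
                length = self.pair(name).length
                if iv[0, 0] < 0 or iv[-1, 1] > length:
                    raise ValueError(f"{name}: mask interval out of bounds")

    def pair(self, name: str) -> ChromosomePair:
        for p in self.pairs:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def pair_names(self) -> list[str]:
        return [p.name for p in self.pairs]

    def masked_bp(self, name: str) -> int:
        iv = self.mask.get(name)
        if iv is None or iv.size == 0:
            return 0
        return int((iv[:, 1] - iv[:, 0]).sum())

    def unmasked_bp(self, name: str) -> int:
        return self.pair(name).length - self.masked_bp(name)

    def mask_array(self, name: str) -> np.ndarray:
        """Boolean repeat indicator over the pair's coordinate axis."""
        out = np.zeros(self.pair(name).length, dtype=bool)
        for s, e in self.mask.get(name, np.empty((0, 2), dtype=np.int64)):
            out[s:e] = True
        return out

    def sites(self, name: str) -> np.ndarray:
        """Sorted 0-based catalog positions on one chromosome pair."""
        sel = self.catalog[self.catalog["pair"] == name]
        return np.sort(sel["pos"].to_numpy())

    # ------------------------------------------------------------------
    # on-disk layout (plain text, used by the CLI)
    # ------------------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chrom = pd.DataFrame(
            {
                "pair": [p.name for p in self.pairs],
                "chrom_a": [p.name_a for p in self.pairs],
                "chrom_b": [p.name_b for p in self.pairs],
                "length": [p.length for p in self.pairs],
            }
        )
        chrom.to_csv(outdir / "chromosomes.tsv", sep="\t", index=False)
        rows = []
        for p in self.pairs:
            for s, e in self.mask.get(p.name, np.empty((0, 2), dtype=np.int64)):
                rows.append((p.name, int(s), int(e)))
        pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
            outdir / "repeat_mask.bed", sep="\t", index=False, header=False
        )
        self.catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "ReferenceModel":
        indir = Path(indir)
        chrom = pd.read_csv(indir / "chromosomes.tsv", sep="\t")
        pairs = [
            ChromosomePair(r.pair, r.chrom_a, r.chrom_b, int(r.length))
            for r in chrom.itertuples()
        ]
        mask: dict[str, np.ndarray] = {p.name: np.empty((0, 2), dtype=np.int64) for p in pairs}
        bed = indir / "repeat_mask.bed"
        if bed.exists() and bed.stat().st_size:
            b = pd.read_csv(bed, sep="\t", header=None, names=["chrom", "start", "end"])
            for name, grp in b.groupby("chrom"):
                mask[str(name)] = grp[["start", "end"]].to_numpy(dtype=np.int64)
        catalog = pd.read_csv(indir / "catalog.tsv", sep="\t")
        return cls(pairs=pairs, mask=mask, catalog=catalog)


def intervals_complement(intervals: np.ndarray, length: int) -> np.ndarray:
    """Complement of sorted non-overlapping intervals within [0, length)."""
    intervals = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    out = []
    prev = 0
    for s, e in intervals:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return np.array(out, dtype=np.int64).reshape(-1, 2)
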