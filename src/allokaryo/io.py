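"""Plain-text interchange: FASTA, BED, VCF and TSV readers/writers.

Coordinates are 0-based half-open in BED and in all internal tables,
1-based in VCF and in the site-depth TSV exchanged with external
pipelines.  Every table written by the CLI carries a provenance comment
header (tool version, seed, config hash) as ``#``-prefixed lines, which
the readers skip.
"""

from __future__ import annotations

import hashlib
import textwrap
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import Panel


def provenance_header(seed: int | None = None, config_hash: str | None = None) -> str:
    parts = [f"# allokaryo v{__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config_hash is not None:
        parts.append(f"# config_sha256={config_hash}")
    return "\n".join(parts) + "\n"


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path, header: str = "", **kwargs) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, sep="\t", index=False, **kwargs)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, width) + "\n")


def write_bed(
    intervals: pd.DataFrame, path: str | Path, header: str = ""
) -> None:
    """BED (0-based half-open); expects chrom/start/end plus optional name columns."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        intervals.to_csv(fh, sep="\t", index=False, header=False)


def read_bed(path: str | Path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = list(names)[: df.shape[1]]
    return df


# ----------------------------------------------------------------------
# site depths
# ----------------------------------------------------------------------

def write_site_depth(site_depth: pd.DataFrame, path: str | Path, header: str = "") -> None:
    """Site-depth TSV: chrom, pos (1-based), ref_allele_count, alt_allele_count.

    ``ref`` is the referenced subgenome's allele (internal column a_depth).
    """
    out = pd.DataFrame(
        {
            "chrom": site_depth["pair"],
            "pos": site_depth["pos"] + 1,
            "ref_allele_count": site_depth["a_depth"],
            "alt_allele_count": site_depth["b_depth"],
        }
    )
    write_table(out, path, header)


def read_site_depth(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    return pd.DataFrame(
        {
            "pair": df["chrom"],
            "pos": df["pos"] - 1,
            "a_depth": df["ref_allele_count"],
            "b_depth": df["alt_allele_count"],
        }
    )


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_panel_vcf(panel: Panel, path: str | Path, ref_alleles=None) -> None:
    """Panel genotypes as an uncompressed VCF with GT fields.

    Synthetic alleles (A>T) are written when the panel does not carry
    sequence context; only coordinates and genotypes matter downstream.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=allokaryo v{__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for pair in pd.unique(panel.sites["pair"]):
            fh.write(f"##contig=<ID={pair}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.accessions)
            + "\n"
        )
        for j, row in enumerate(panel.sites.itertuples()):
            gts = "\t".join(_GT_CODE[int(g)] for g in panel.genotypes[j])
            fh.write(f"{row.pair}\t{row.pos + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_genotypes(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a VCF's GT fields into (sites, genotype code matrix, accessions)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    accessions = list(vf.header.samples)
    rows = []
    geno = []
    for rec in vf:
        rows.append((rec.chrom, rec.pos - 1))
        codes = []
        for s in accessions:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                codes.append(-1)
            else:
                codes.append(int(sum(gt)))
        geno.append(codes)
    sites = pd.DataFrame(rows, columns=["pair", "pos"])
    return sites, np.asarray(geno, dtype=np.int8), accessions


def read_vcf_allele_depths(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Read per-sample AD fields into a site-depth table (pair, pos, a_depth, b_depth)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if sample is None:
        if len(samples) != 1:
            raise ValueError("VCF has multiple samples; specify one")
        sample = samples[0]
    rows = []
    for rec in vf:
        ad = rec.samples[sample].get("AD")
        if ad is None:
            continue
        rows.append((rec.chrom, rec.pos - 1, int(ad[0]), int(ad[1])))
    return pd.DataFrame(rows, columns=["pair", "pos", "a_depth", "b_depth"])


def write_coverage(coverage: pd.DataFrame, path: str | Path, header: str = "") -> None:
    write_table(coverage, path, header, float_format="%.6g")


def read_coverage(path: str | Path) -> pd.DataFrame:
    return read_table(path)
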