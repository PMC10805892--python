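"""Deterministic genotype calling from allele depths.

Genotypes are assigned from the alternative-allele read fraction
``r = alt / (ref + alt)`` by fixed thresholds rather than by genotype
likelihoods.  This reproduces the rule sets of reference-guided
resequencing pipelines for a highly homozygous, recently-formed
allopolyploid: a call is made only when the read fraction is clearly
consistent with one of the three diploid genotype classes, otherwise the
site is left missing for that individual.

Three presets are provided:

* ``WGS``: minimum depth 10, heterozygous when r in [0.15, 0.85].
* ``LOWCOV``: same intervals, minimum depth relaxed to 5 for shallow
  public resequencing data.
* ``GBS``: minimum depth 10, heterozygous when r in [0.25, 0.75]
  (reduced-representation data are noisier per site), and sites kept
  only when informative in more than half of the individuals.

Fractions falling in the uncovered gaps (0.1, 0.15) and (0.85, 0.9) —
or (0.1, 0.25)/(0.75, 0.9) for GBS — yield a missing call: no genotype
class is defined there.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1
CALL_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}


@dataclasses.dataclass(frozen=True)
class GenotypeRuleset:
    """Thresholds on depth and alternative-allele fraction."""

    min_depth: int = 10
    het_lo: float = 0.15
    het_hi: float = 0.85
    homref_max: float = 0.10
    homalt_min: float = 0.90
    informativeness_min: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.homref_max < self.het_lo <= self.het_hi < self.homalt_min <= 1):
            raise ValueError(
                "ruleset thresholds must satisfy homref_max < het_lo <= het_hi < homalt_min"
            )
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


WGS = GenotypeRuleset(min_depth=10, het_lo=0.15, het_hi=0.85)
LOWCOV = GenotypeRuleset(min_depth=5, het_lo=0.15, het_hi=0.85)
GBS = GenotypeRuleset(min_depth=10, het_lo=0.25, het_hi=0.75)

RULESETS = {"wgs": WGS, "lowcov": LOWCOV, "gbs": GBS}


def call_genotypes(
    ref_count: np.ndarray, alt_count: np.ndarray, ruleset: GenotypeRuleset = WGS
) -> np.ndarray:
    """Vectorised genotype calls; returns int codes (HOM_REF/HET/HOM_ALT/MISSING)."""
    ref_count = np.asarray(ref_count)
    alt_count = np.asarray(alt_count)
    if np.any(ref_count < 0) or np.any(alt_count < 0):
        raise ValueError("read counts must be non-negative")
    depth = ref_count + alt_count
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(depth > 0, alt_count / np.maximum(depth, 1), np.nan)
    out = np.full(np.shape(depth), MISSING, dtype=np.int8)
    ok = depth >= ruleset.min_depth
    out[ok & (r <= ruleset.homref_max)] = HOM_REF
    out[ok & (r >= ruleset.het_lo) & (r <= ruleset.het_hi)] = HET
    out[ok & (r >= ruleset.homalt_min)] = HOM_ALT
    return out


def call_genotype(ref_count: int, alt_count: int, ruleset: GenotypeRuleset = WGS) -> str:
    """Single-site convenience wrapper returning the call name.

    Zero depth is a missing call, never an error.
    """
    code = call_genotypes(np.array([ref_count]), np.array([alt_count]), ruleset)[0]
    return CALL_NAMES[int(code)]


def filter_reference_artifacts(
    panel_sites: pd.DataFrame, reference_self_sites: pd.DataFrame
) -> pd.DataFrame:
    """Remove panel variant sites that also appear in a reference self-alignment.

    Variants called when the reference individual's own reads are aligned
    back to its assembly cannot be real segregating variation: they mark
    assembly errors or systematic misalignment, and any panel call at the
    same site and alleles is discarded as a false positive.

    Both frames are keyed by (chrom, pos) plus, when present in *both*
    inputs, the ref/alt allele columns.
    """
    keys = ["chrom", "pos"]
    for extra in ("ref", "alt"):
        if extra in panel_sites.columns and extra in reference_self_sites.columns:
            keys.append(extra)
    if reference_self_sites.empty:
        return panel_sites.copy()
    merged = panel_sites.merge(
        reference_self_sites[keys].drop_duplicates(), on=keys, how="left", indicator=True
    )
    out = merged[merged["_merge"] == "left_only"].drop(columns="_merge")
    return out.reset_index(drop=True)


def site_informativeness_filter(
    genotypes: np.ndarray, min_fraction: float = 0.5
) -> np.ndarray:
    """Boolean mask of sites informative in strictly more than `min_fraction` of individuals.

    `genotypes` is a (sites x individuals) code matrix; MISSING marks an
    uninformative call.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2:
        raise ValueError("genotype matrix must be 2-D (sites x individuals)")
    called = (genotypes != MISSING).mean(axis=1)
    return called > min_fraction


def category_counts(genotypes: np.ndarray) -> pd.Series:
    """Audit table: number of calls per category across a genotype matrix."""
    genotypes = np.asarray(genotypes)
    return pd.Series(
        {name: int((genotypes == code).sum()) for code, name in CALL_NAMES.items()}
    )
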