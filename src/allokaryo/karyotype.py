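"""Karyotype aberration and homoeologous-exchange detection.

The scan combines two orthogonal window-level observables, each compared
against the expectation under the balanced allotetraploid state of two
copies per homoeolog:

* **homoeologous variant frequency** — the fraction of reads supporting
  the referenced subgenome's allele at homoeologous sites.  With ``c_ref``
  copies of the referenced homoeolog and ``c_other`` of the other, the
  expectation is ``f = c_ref / (c_ref + c_other)``: 0.5 for the balanced
  2:2 state, 0.75 for a heterozygous exchange (3:1), 1 for a homozygous
  replacement (4:0), 0.25 for 1:3 and 0 for 0:2.  Deviations from 0.5
  are scored per window with a chi-square statistic (the "reduction of
  homoeologous heterozygosity", ROH_H, scan).
* **depth of coverage (DOC) ratio** — per-homoeolog unique-mapping
  coverage in a window, median-normalised genome-wide and divided by the
  same quantity in a euploid reference accession.  Expectation is
  ``c_s / 2`` per homoeolog: 1 for two copies, 1.5 for three (trisomy or
  the gained side of an exchange), 2 for four, 0.5 for one, 0 for zero.

Variant frequency alone cannot distinguish an exchange (total copy
number conserved) from a deletion or duplication (total changed); the
DOC ratio resolves the total, and the two observables jointly identify
the integer copy state.  Somatic mosaicism — a mixture of aberrant and
normal cell populations — produces intermediate signals and is fitted as
a one-parameter mixture of the aberrant state with the balanced state.

The scan is wrapped as a model/results pair: build a
:class:`KaryotypeModel` from an accession's observables, call
:meth:`~KaryotypeModel.fit`, and read events and per-window fits off the
returned :class:`KaryotypeResults`.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

EUPLOID = (2, 2)


# ----------------------------------------------------------------------
# copy-state expectation model
# ----------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CopyState:
    """Integer copy numbers of the two homoeologs, with mosaic fraction.

    ``m`` is the fraction of cells carrying this state, the remainder
    being balanced (2,2); ``m = 1`` is a constitutive (non-mosaic) state.
    Expectations are those of the cell mixture, with read depth
    proportional to copy number.
    """

    c_ref: int
    c_other: int
    m: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.c_ref <= 4 and 0 <= self.c_other <= 4):
            raise ValueError("per-homoeolog copy number must be in 0..4")
        if not 0 <= self.c_ref + self.c_other <= 5:
            raise ValueError("total copy number must be in 0..5")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("mosaic fraction must be in [0, 1]")

    @property
    def total(self) -> int:
        return self.c_ref + self.c_other

    def expected_frequency(self) -> float:
        """Expected referenced-subgenome allele fraction at homoeologous sites."""
        num = self.m * self.c_ref + (1 - self.m) * 2.0
        den = self.m * self.total + (1 - self.m) * 4.0
        if den == 0:
            raise ValueError("frequency undefined at total copy number 0")
        return num / den

    def expected_doc(self) -> tuple[float, float]:
        """Expected DOC ratio of the two homoeologs versus a 2-copy reference."""
        a = (self.m * self.c_ref + (1 - self.m) * 2.0) / 2.0
        b = (self.m * self.c_other + (1 - self.m) * 2.0) / 2.0
        return a, b


def expected_frequency(c_ref: int, c_other: int) -> float:
    """Reference-subgenome allele fraction for a constitutive copy state."""
    return CopyState(c_ref, c_other).expected_frequency()


def expected_doc(copies: int, reference_copies: int = 2) -> float:
    """Normalised depth-of-coverage expectation: test copies over reference copies."""
    if reference_copies <= 0:
        raise ValueError("reference copy number must be positive")
    if copies < 0:
        raise ValueError("copy number must be non-negative")
    return copies / reference_copies


def state_grid(max_total: int = 5) -> list[tuple[int, int]]:
    """All integer copy states searched by the fit, (0,0) excluded."""
    return [
        (a, b)
        for a in range(5)
        for b in range(5)
        if 0 < a + b <= max_total
    ]


# ----------------------------------------------------------------------
# window observables
# ----------------------------------------------------------------------

def homoeologous_frequency(a_depth: np.ndarray, b_depth: np.ndarray) -> float:
    """Depth-weighted mean referenced-subgenome allele fraction over sites.

    Returns NaN when the window has zero total depth (flagged missing by
    the caller).
    """
    a = np.asarray(a_depth, dtype=float)
    b = np.asarray(b_depth, dtype=float)
    tot = a.sum() + b.sum()
    if tot == 0:
        return float("nan")
    return float(a.sum() / tot)


def roh_h_statistic(a_depth: np.ndarray, b_depth: np.ndarray) -> tuple[float, int]:
    """Per-site chi-square against balanced allele sampling, summed over a window.

    Each covered site contributes ``(a - b)^2 / (a + b)``, the one-degree
    chi-square for a binomial split against p = 0.5; the window statistic
    is the sum and its degrees of freedom the number of covered sites.
    Sites with zero depth contribute nothing.  Raises on an empty window.
    """
    a = np.asarray(a_depth, dtype=float)
    b = np.asarray(b_depth, dtype=float)
    if a.size == 0:
        raise ValueError("ROH_H statistic undefined for an empty window")
    tot = a + b
    covered = tot > 0
    if not covered.any():
        raise ValueError("ROH_H statistic undefined when no site has coverage")
    chi2 = float((((a - b) ** 2)[covered] / tot[covered]).sum())
    return chi2, int(covered.sum())


def doc_ratio(
    coverage: pd.DataFrame, reference_coverage: pd.DataFrame
) -> pd.DataFrame:
    """Per-window per-homoeolog DOC ratio of an accession versus a reference.

    Both inputs carry columns pair, start, end, subgenome, depth over the
    same window set.  Each accession's window coverage is first divided
    by its genome-wide *median* window coverage for that subgenome (the
    median resists the very aberrations being detected), and the ratio of
    the two normalised values is returned in wide form with columns
    ``doc_A`` and ``doc_B``.  Windows with zero reference coverage are
    returned as NaN.
    """
    key = ["pair", "start", "end", "subgenome"]
    merged = coverage[key + ["depth"]].merge(
        reference_coverage[key + ["depth"]], on=key, suffixes=("_acc", "_ref")
    )
    if len(merged) != len(coverage):
        raise ValueError("accession and reference coverage window sets differ")
    med_acc = merged.groupby("subgenome")["depth_acc"].transform("median")
    med_ref = merged.groupby("subgenome")["depth_ref"].transform("median")
    with np.errstate(invalid="ignore", divide="ignore"):
        norm_acc = merged["depth_acc"] / med_acc
        norm_ref = merged["depth_ref"] / med_ref
        ratio = np.where(merged["depth_ref"] > 0, norm_acc / norm_ref, np.nan)
    merged["doc"] = ratio
    wkey = ["pair", "start", "end"]
    a = merged[merged["subgenome"] == "A"][wkey + ["doc"]].rename(columns={"doc": "doc_A"})
    b = merged[merged["subgenome"] == "B"][wkey + ["doc"]].rename(columns={"doc": "doc_B"})
    return a.merge(b, on=wkey, how="outer").sort_values(wkey).reset_index(drop=True)


def derive_homoeologous_catalog(
    site_depth: pd.DataFrame,
    band: tuple[float, float] = (0.35, 0.65),
    min_depth: int = 10,
) -> pd.DataFrame:
    """Retain candidate homoeologous sites validated in a euploid reference accession.

    Under the balanced (2,2) state the referenced-subgenome allele
    fraction at a genuine homoeologous site is centred on 0.5; candidate
    sites whose observed fraction in the (assumed euploid) reference
    accession falls outside the band, or whose depth is below
    ``min_depth``, are dropped as unreliable or spurious.
    """
    if site_depth.empty:
        return site_depth.copy()
    a = site_depth["a_depth"].to_numpy(dtype=float)
    b = site_depth["b_depth"].to_numpy(dtype=float)
    depth = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(depth > 0, a / np.maximum(depth, 1), np.nan)
    keep = (depth >= min_depth) & (f >= band[0]) & (f <= band[1])
    return site_depth[keep].reset_index(drop=True)


# ----------------------------------------------------------------------
# copy-state fitting
# ----------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CopyStateFit:
    """Best-fitting copy state for one window."""

    c_ref: int
    c_other: int
    m: float            # 1.0 when not mosaic
    mosaic: bool
    residual: float
    integer_residual: float

    @property
    def state(self) -> tuple[int, int]:
        return (self.c_ref, self.c_other)


def _residual(
    f_exp: float | np.ndarray,
    doc_a_exp: float | np.ndarray,
    doc_b_exp: float | np.ndarray,
    f_bar: float,
    doc_a: float,
    doc_b: float,
    w_f: float,
    w_d: float,
) -> float | np.ndarray:
    r = 0.0
    if np.isfinite(f_bar):
        r = r + w_f * (np.asarray(f_exp) - f_bar) ** 2
    if np.isfinite(doc_a):
        r = r + w_d * (np.asarray(doc_a_exp) - doc_a) ** 2
    if np.isfinite(doc_b):
        r = r + w_d * (np.asarray(doc_b_exp) - doc_b) ** 2
    return r


def fit_copy_state(
    f_bar: float,
    doc_a: float,
    doc_b: float,
    w_f: float = 1.0,
    w_d: float = 1.0,
    max_total: int = 5,
    mosaic_band: tuple[float, float] = (0.15, 0.85),
    mosaic_improvement: float = 0.5,
    m_grid_points: int = 201,
) -> CopyStateFit:
    """Fit the integer copy state, then test a mosaic mixture with (2,2).

    The integer fit minimises
    ``R = w_f (f_bar - f_exp)^2 + w_d (doc_A - c_A/2)^2 + w_d (doc_B - c_B/2)^2``
    over all states with total copy number 1..``max_total``; ties are
    broken toward the state closest to (2,2) in L1 copy distance
    (parsimony).  One-dimensional mixtures of each non-euploid state with
    (2,2) are then fitted on a dense grid of the mosaic fraction m and
    the best mixture kept.  Mixture families overlap — a constitutive
    (3,1) is observationally identical to a (4,0) mosaic at m = 0.5 — so
    equally good mixtures resolve by parsimony (smallest L1 copy
    distance, then largest m).  The window is labelled mosaic when the
    best mixture residual falls below ``mosaic_improvement`` times the
    integer residual and its fitted m lies inside ``mosaic_band``.  NaN
    observations drop the corresponding residual term; with every
    observable missing no fit is possible and a ValueError is raised.
    """
    if not (np.isfinite(f_bar) or np.isfinite(doc_a) or np.isfinite(doc_b)):
        raise ValueError("cannot fit a copy state with all observations missing")
    candidates = []
    for ca, cb in state_grid(max_total):
        st = CopyState(ca, cb)
        r = float(
            _residual(
                st.expected_frequency(), *st.expected_doc(),
                f_bar, doc_a, doc_b, w_f, w_d,
            )
        )
        l1 = abs(ca - 2) + abs(cb - 2)
        candidates.append((r, l1, ca, cb))
    candidates.sort()
    r_int, _, best_a, best_b = candidates[0]

    m = np.linspace(0.0, 1.0, m_grid_points)
    mixtures = []  # (r, l1, -m, state)
    for _, l1, ca, cb in candidates:
        if (ca, cb) == EUPLOID:
            continue
        total = ca + cb
        num = m * ca + (1 - m) * 2.0
        den = m * total + (1 - m) * 4.0
        with np.errstate(invalid="ignore", divide="ignore"):
            f_mix = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
        doc_a_mix = (m * ca + (1 - m) * 2.0) / 2.0
        doc_b_mix = (m * cb + (1 - m) * 2.0) / 2.0
        r_mix = np.asarray(
            _residual(f_mix, doc_a_mix, doc_b_mix, f_bar, doc_a, doc_b, w_f, w_d)
        )
        r_mix = np.where(np.isfinite(r_mix), r_mix, np.inf)
        i = int(np.argmin(r_mix))
        mixtures.append((float(r_mix[i]), l1, -float(m[i]), ca, cb))
    r_best = min(x[0] for x in mixtures)
    tol = 1e-9 + 1e-6 * r_best
    tied = sorted(x for x in mixtures if x[0] <= r_best + tol)
    r_hat, _, neg_m, mix_a, mix_b = tied[0]
    m_hat = -neg_m
    is_mosaic = (
        r_hat < mosaic_improvement * r_int
        and mosaic_band[0] < m_hat < mosaic_band[1]
    )
    if is_mosaic:
        return CopyStateFit(mix_a, mix_b, m_hat, True, r_hat, r_int)
    return CopyStateFit(best_a, best_b, 1.0, False, r_int, r_int)


# ----------------------------------------------------------------------
# event segmentation
# ----------------------------------------------------------------------

EVENT_TYPES = (
    "aneuploidy_gain",
    "aneuploidy_loss",
    "homoeologous_exchange",
    "deletion",
    "duplication",
)


@dataclasses.dataclass
class KaryotypeConfig:
    """Tunable thresholds of the karyotype scan.

    alpha is the genome-wide significance level of the ROH_H chi-square
    flag, Bonferroni-corrected over the number of scored windows;
    doc_tolerance flags windows whose DOC ratio departs from 1 by more
    than this amount on either homoeolog (0.25 is halfway between
    adjacent copy-number expectations); events shorter than
    min_event_size bp are discarded; events spanning at least
    aneuploidy_span of a chromosome with a changed total copy number are
    reclassified as whole-chromosome aneuploidies.
    """

    alpha: float = 0.05
    doc_tolerance: float = 0.25
    min_event_size: int = 200_000
    gap_windows: int = 1
    aneuploidy_span: float = 0.95
    w_f: float = 1.0
    w_d: float = 1.0
    max_total: int = 5
    mosaic_band: tuple[float, float] = (0.15, 0.85)
    mosaic_improvement: float = 0.5
    catalog_band: tuple[float, float] = (0.35, 0.65)
    catalog_min_depth: int = 10


@dataclasses.dataclass(frozen=True)
class KaryotypeEvent:
    """A classified chromosomal interval (0-based half-open)."""

    accession: str
    pair: str
    start: int
    end: int
    type: str
    zygosity: str  # heterozygous / homozygous / mosaic
    c_ref: int
    c_other: int
    m: float
    residual: float
    n_windows: int

    @property
    def span(self) -> int:
        return self.end - self.start


def classify_state(
    c_ref: int, c_other: int, mosaic: bool, whole_chromosome: bool
) -> tuple[str, str]:
    """Event type and zygosity implied by a fitted copy state."""
    total = c_ref + c_other
    if total == 4:
        etype = "homoeologous_exchange"
    elif total > 4:
        etype = "aneuploidy_gain" if whole_chromosome else "duplication"
    else:
        etype = "aneuploidy_loss" if whole_chromosome else "deletion"
    if mosaic:
        zyg = "mosaic"
    else:
        dev = max(abs(c_ref - 2), abs(c_other - 2))
        zyg = "heterozygous" if dev <= 1 else "homozygous"
    return etype, zyg


def segment_events(
    window_fits: pd.DataFrame,
    chrom_lengths: dict[str, int],
    config: KaryotypeConfig | None = None,
    accession: str = "",
) -> list[KaryotypeEvent]:
    """Merge flagged windows into classified karyotype events.

    `window_fits` carries one row per genomic window, ordered along each
    chromosome, with columns pair, start, end, n_sites, chi2, doc_A,
    doc_B, c_ref, c_other, m, mosaic, residual.  A window is flagged when
    its ROH_H chi-square exceeds the Bonferroni-corrected chi-square
    quantile for its site count, or its DOC departs from 1 beyond
    tolerance — and its fitted state is not balanced (2,2).  Runs of
    flagged windows sharing the same aberrant integer state merge,
    tolerating up to `gap_windows` unflagged windows between them; runs
    spanning less than `min_event_size` bp are dropped.  An event's
    mosaic fraction is the median over its windows (windows not labelled
    mosaic count as m = 1); events covering at least `aneuploidy_span` of
    the chromosome with total copy number != 4 become whole-chromosome
    aneuploidies.
    """
    config = config or KaryotypeConfig()
    n_tests = int((window_fits["n_sites"] > 0).sum())
    if n_tests == 0:
        return []
    alpha_per_window = config.alpha / n_tests

    wf = window_fits.copy()
    with np.errstate(invalid="ignore"):
        chi2_thr = stats.chi2.isf(alpha_per_window, np.maximum(wf["n_sites"], 1))
    chi2_flag = (wf["n_sites"] > 0) & (wf["chi2"] > chi2_thr)
    doc_flag = (
        (np.abs(wf["doc_A"] - 1.0) > config.doc_tolerance)
        | (np.abs(wf["doc_B"] - 1.0) > config.doc_tolerance)
    ).fillna(False)
    aberrant = (wf["c_ref"] != 2) | (wf["c_other"] != 2)
    wf["flagged"] = (chi2_flag | doc_flag) & aberrant

    events: list[KaryotypeEvent] = []
    for pair, grp in wf.groupby("pair", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        runs: list[dict] = []
        current: dict | None = None
        gap = 0
        for idx, row in enumerate(grp.itertuples()):
            if row.flagged:
                state = (int(row.c_ref), int(row.c_other))
                if current is not None and state == current["state"] and gap <= config.gap_windows:
                    current["rows"].append(row)
                    current["last"] = idx
                else:
                    if current is not None:
                        runs.append(current)
                    current = {"state": state, "rows": [row], "first": idx, "last": idx}
                gap = 0
            else:
                gap += 1
                if current is not None and gap > config.gap_windows:
                    runs.append(current)
                    current = None
        if current is not None:
            runs.append(current)

        # A window straddling an event breakpoint sees a mixture of the
        # event state and (2,2) and can fit an intermediate integer state
        # (e.g. the edge of a homozygous 0:2 deletion looks like 1:2).
        # Absorb single-window runs directly adjacent to a longer run into
        # that run rather than reporting them as separate events.
        absorbed: set[int] = set()
        for i, run in enumerate(runs):
            if len(run["rows"]) != 1:
                continue
            for j, other in enumerate(runs):
                if j == i or len(other["rows"]) < 2 or j in absorbed:
                    continue
                if run["first"] == other["last"] + 1 or run["last"] == other["first"] - 1:
                    other["rows"] = sorted(
                        other["rows"] + run["rows"], key=lambda r: r.start
                    )
                    other["first"] = min(other["first"], run["first"])
                    other["last"] = max(other["last"], run["last"])
                    absorbed.add(i)
                    break
        runs = [r for i, r in enumerate(runs) if i not in absorbed]

        length = chrom_lengths[pair]
        for run in runs:
            rows = run["rows"]
            start = int(rows[0].start)
            end = int(rows[-1].end)
            if end - start < config.min_event_size:
                continue
            c_ref, c_other = run["state"]
            m_vals = [float(r.m) if r.mosaic else 1.0 for r in rows]
            m_med = float(np.median(m_vals))
            lo, hi = config.mosaic_band
            mosaic = lo < m_med < hi
            whole = (end - start) >= config.aneuploidy_span * length and (c_ref + c_other) != 4
            etype, zyg = classify_state(c_ref, c_other, mosaic, whole)
            events.append(
                KaryotypeEvent(
                    accession=accession,
                    pair=str(pair),
                    start=start,
                    end=end,
                    type=etype,
                    zygosity=zyg,
                    c_ref=c_ref,
                    c_other=c_other,
                    m=m_med if mosaic else 1.0,
                    residual=float(np.mean([r.residual for r in rows])),
                    n_windows=len(rows),
                )
            )
    return events


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------

class KaryotypeModel:
    """Joint ROH_H / DOC karyotype scan for one accession.

    Parameters
    ----------
    site_depth
        Allele depths of the test accession at homoeologous catalog
        sites: columns pair, pos, a_depth, b_depth (reads supporting the
        referenced and the other subgenome's allele).
    coverage, reference_coverage
        Per-window per-homoeolog coverage tables (columns pair, start,
        end, subgenome, depth) for the test accession and for the euploid
        reference accession, over the same window set.
    windows
        Genomic windows (columns pair, start, end, nonrepetitive_bp);
        the unit of the scan.
    chrom_lengths
        Chromosome-pair lengths, for whole-chromosome classification.
    config
        Scan thresholds; defaults in :class:`KaryotypeConfig`.
    """

    def __init__(
        self,
        site_depth: pd.DataFrame,
        coverage: pd.DataFrame,
        reference_coverage: pd.DataFrame,
        windows: pd.DataFrame,
        chrom_lengths: dict[str, int],
        config: KaryotypeConfig | None = None,
        accession: str = "accession",
    ):
        self.site_depth = site_depth.reset_index(drop=True)
        self.coverage = coverage
        self.reference_coverage = reference_coverage
        self.windows = windows.reset_index(drop=True)
        self.chrom_lengths = dict(chrom_lengths)
        self.config = config or KaryotypeConfig()
        self.accession = accession

    @classmethod
    def from_observables(
        cls,
        observables,
        accession: str,
        reference_accession: str,
        ref_model=None,
        config: KaryotypeConfig | None = None,
    ) -> "KaryotypeModel":
        """Build the model from a simulator :class:`~allokaryo.simulate.Observables`."""
        if ref_model is not None:
            chrom_lengths = {p.name: p.length for p in ref_model.pairs}
        else:
            w = observables.windows
            chrom_lengths = w.groupby("pair")["end"].max().to_dict()
        return cls(
            site_depth=observables.accession_site_depth(accession),
            coverage=observables.accession_coverage(accession),
            reference_coverage=observables.accession_coverage(reference_accession),
            windows=observables.windows,
            chrom_lengths=chrom_lengths,
            config=config,
            accession=accession,
        )

    def fit(self) -> "KaryotypeResults":
        cfg = self.config
        doc = doc_ratio(self.coverage, self.reference_coverage)
        rows = []
        for w in self.windows.itertuples():
            sel = self.site_depth[
                (self.site_depth["pair"] == w.pair)
                & (self.site_depth["pos"] >= w.start)
                & (self.site_depth["pos"] < w.end)
            ]
            a = sel["a_depth"].to_numpy()
            b = sel["b_depth"].to_numpy()
            covered = (a + b) > 0
            if covered.any():
                f_bar = homoeologous_frequency(a, b)
                chi2, df = roh_h_statistic(a, b)
            else:
                f_bar, chi2, df = np.nan, np.nan, 0
            rows.append((w.pair, w.start, w.end, df, f_bar, chi2))
        obs = pd.DataFrame(
            rows, columns=["pair", "start", "end", "n_sites", "f_bar", "chi2"]
        )
        obs = obs.merge(doc, on=["pair", "start", "end"], how="left")

        fits = []
        for r in obs.itertuples():
            f_bar = float(r.f_bar) if np.isfinite(r.f_bar) else np.nan
            da = float(r.doc_A) if np.isfinite(r.doc_A) else np.nan
            db = float(r.doc_B) if np.isfinite(r.doc_B) else np.nan
            if not (np.isfinite(f_bar) or np.isfinite(da) or np.isfinite(db)):
                fits.append((2, 2, 1.0, False, np.nan))
                continue
            fit = fit_copy_state(
                f_bar, da, db,
                w_f=cfg.w_f, w_d=cfg.w_d, max_total=cfg.max_total,
                mosaic_band=cfg.mosaic_band,
                mosaic_improvement=cfg.mosaic_improvement,
            )
            fits.append((fit.c_ref, fit.c_other, fit.m, fit.mosaic, fit.residual))
        obs[["c_ref", "c_other", "m", "mosaic", "residual"]] = pd.DataFrame(
            fits, index=obs.index
        )
        obs["c_ref"] = obs["c_ref"].astype(int)
        obs["c_other"] = obs["c_other"].astype(int)
        events = segment_events(obs, self.chrom_lengths, cfg, self.accession)
        return KaryotypeResults(self, obs, events)


class KaryotypeResults:
    """Fitted per-window copy states and segmented karyotype events."""

    def __init__(
        self, model: KaryotypeModel, window_fits: pd.DataFrame, events: list[KaryotypeEvent]
    ):
        self.model = model
        self.window_fits = window_fits
        self.events = events

    @property
    def accession(self) -> str:
        return self.model.accession

    def events_frame(self) -> pd.DataFrame:
        cols = [
            "accession", "pair", "start", "end", "type", "zygosity",
            "c_ref", "c_other", "m", "residual", "n_windows",
        ]
        return pd.DataFrame(
            [[getattr(e, c) for c in cols] for e in self.events], columns=cols
        )

    def to_bed(self) -> pd.DataFrame:
        """Events as BED (0-based half-open), name = type:state:zygosity."""
        rows = [
            (
                e.pair, e.start, e.end,
                f"{e.type}:{e.c_ref}:{e.c_other}:{e.zygosity}",
            )
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def to_dict(self) -> dict:
        """JSON-ready karyotype report for the accession."""
        chroms = {}
        for pair, grp in self.window_fits.groupby("pair", sort=False):
            states = grp[["c_ref", "c_other"]].value_counts()
            modal = states.index[0] if len(states) else (2, 2)
            chroms[str(pair)] = {
                "modal_state": [int(modal[0]), int(modal[1])],
                "n_windows": int(len(grp)),
                "events": [
                    {
                        "start": e.start,
                        "end": e.end,
                        "type": e.type,
                        "zygosity": e.zygosity,
                        "state": [e.c_ref, e.c_other],
                        "m": round(e.m, 4),
                        "residual": round(e.residual, 6),
                        "n_windows": e.n_windows,
                    }
                    for e in self.events
                    if e.pair == pair
                ],
            }
        return {"accession": self.accession, "chromosomes": chroms}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        """Human-readable summary table of the fitted karyotype."""
        lines = [
            f"Karyotype scan: {self.accession}",
            f"windows scored: {int((self.window_fits['n_sites'] > 0).sum())}"
            f" / {len(self.window_fits)}",
            f"events detected: {len(self.events)}",
            "",
            f"{'pair':<8}{'interval':<26}{'type':<24}{'state':<8}{'zygosity':<14}{'m':<7}{'windows'}",
        ]
        for e in self.events:
            iv = f"{e.start + 1:,}-{e.end:,}"  # 1-based inclusive in reports
            lines.append(
                f"{e.pair:<8}{iv:<26}{e.type:<24}"
                f"{e.c_ref}:{e.c_other:<6}{e.zygosity:<14}{e.m:<7.2f}{e.n_windows}"
            )
        if not self.events:
            lines.append("(euploid: no aberrant intervals at current thresholds)")
        return "\n".join(lines)

    def plot_chromosome(self, pair: str, ax=None):
        """Frequency and DOC tracks for one chromosome pair, with the state grid."""
        import matplotlib.pyplot as plt

        grp = self.window_fits[self.window_fits["pair"] == pair]
        if ax is None:
            _, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
        else:
            axes = ax
        mid = (grp["start"] + grp["end"]) / 2e6
        for y in (0.0, 0.25, 0.5, 0.75, 1.0):
            axes[0].axhline(y, color="0.85", lw=0.8, ls="--")
        axes[0].plot(mid, grp["f_bar"], color="tab:orange", lw=1)
        axes[0].set_ylabel("homoeologous\nvariant frequency")
        axes[0].set_ylim(-0.05, 1.05)
        for y in (0.0, 0.5, 1.0, 1.5, 2.0):
            axes[1].axhline(y, color="0.85", lw=0.8, ls="--")
        axes[1].plot(mid, grp["doc_A"], color="tab:blue", lw=1, label="homoeolog A")
        axes[1].plot(mid, grp["doc_B"], color="tab:green", lw=1, label="homoeolog B")
        axes[1].set_ylabel("DOC ratio")
        axes[1].set_xlabel(f"{pair} (Mbp)")
        axes[1].legend(frameon=False, fontsize=8)
        for e in self.events:
            if e.pair == pair:
                for a in axes:
                    a.axvspan(e.start / 1e6, e.end / 1e6, color="tab:red", alpha=0.12)
        return axes
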