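"""Karyotype report rendering: JSON plus a human-readable text ideogram.

The text ideogram depicts each chromosome pair as two vertical-bar
tracks (one per homoeolog) discretised into fixed-width bins; a bin's
glyph encodes the fitted copy number of that homoeolog.  Coordinates in
text output are 1-based inclusive; BED output stays 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .karyotype import KaryotypeEvent, KaryotypeResults

_GLYPH = {0: ".", 1: "-", 2: "=", 3: "#", 4: "@"}


def _ideogram_line(length: int, events: list[KaryotypeEvent], which: str, bins: int = 60) -> str:
    chars = []
    for i in range(bins):
        lo = i * length // bins
        hi = (i + 1) * length // bins
        copies = 2
        for e in events:
            if e.start < hi and e.end > lo:
                copies = e.c_ref if which == "ref" else e.c_other
        chars.append(_GLYPH.get(copies, "?"))
    return "".join(chars)


def render_karyotype_report(results: KaryotypeResults, bins: int = 60) -> str:
    """Per-chromosome copy-state table, event list and a text ideogram."""
    lines = [results.summary(), "", "Ideogram (A above, B below; . - = # @ : 0..4 copies):"]
    for pair, length in results.model.chrom_lengths.items():
        evs = [e for e in results.events if e.pair == pair]
        lines.append(f"{pair:<8}A {_ideogram_line(length, evs, 'ref', bins)}")
        lines.append(f"{'':<8}B {_ideogram_line(length, evs, 'other', bins)}")
    return "\n".join(lines) + "\n"


def write_reports(results: KaryotypeResults, outdir: str | Path, header: str = "") -> dict:
    """Write the JSON report, events BED and text ideogram; return the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = results.to_dict()
    with open(outdir / f"{results.accession}.karyotype.json", "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    bed = results.to_bed()
    with open(outdir / f"{results.accession}.events.bed", "w") as fh:
        if header:
            fh.write(header)
        bed.to_csv(fh, sep="\t", index=False, header=False)
    with open(outdir / f"{results.accession}.karyotype.txt", "w") as fh:
        if header:
            fh.write(header)
        fh.write(render_karyotype_report(results))
    return report


def events_from_bed(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the events BED written above."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "name"])
    parts = df["name"].str.split(":", expand=True)
    df["type"] = parts[0]
    df["c_ref"] = parts[1].astype(int)
    df["c_other"] = parts[2].astype(int)
    df["zygosity"] = parts[3]
    return df
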