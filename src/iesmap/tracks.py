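"""Browser-track style outputs: BED, site tables, JSON summaries.

BED output is 0-based half-open (the internal convention, so writing is a
straight dump); names mirror the genome-browser vocabulary of the original
resource ("Sanger Reads Left (unique)" and friends).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .classify import Classification, ReadClass
from .iescall import IesSite
from .junction import render_junction
from .pipeline import PipelineConfig, PipelineResult

TRACK_NAMES = {
    (ReadClass.FULL, True): "sanger_reads_fully_mapped_unique",
    (ReadClass.FULL, False): "sanger_reads_fully_mapped_multi",
    (ReadClass.ONE_END_L, True): "sanger_reads_left_unique",
    (ReadClass.ONE_END_L, False): "sanger_reads_left_multi",
    (ReadClass.ONE_END_R, True): "sanger_reads_right_unique",
    (ReadClass.ONE_END_R, False): "sanger_reads_right_multi",
    (ReadClass.DISCONTINUOUS, True): "sanger_reads_discontinuous_unique",
    (ReadClass.DISCONTINUOUS, False): "sanger_reads_discontinuous_multi",
    (ReadClass.EDGE_EXCLUDED, True): "sanger_reads_edge_excluded_unique",
    (ReadClass.EDGE_EXCLUDED, False): "sanger_reads_edge_excluded_multi",
}


def write_read_tracks(
    classifications: Iterable[Classification], outdir: str | Path, chrom: str = "conMAC"
) -> list[Path]:
    """One BED file of aligned spans per (category, uniqueness) cell."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list[tuple]] = {}
    for cl in classifications:
        if cl.primary is None:
            continue
        name = TRACK_NAMES.get((cl.category, cl.unique))
        if name is None:
            continue
        rows.setdefault(name, []).append(
            (chrom, cl.primary.ref_start, cl.primary.ref_end, cl.read_id)
        )
    written = []
    for name, items in sorted(rows.items()):
        path = outdir / f"{name}.bed"
        with open(path, "w") as fh:
            for row in sorted(items, key=lambda r: (r[1], r[2], r[3])):
                fh.write("\t".join(map(str, row)) + "\n")
        written.append(path)
    return written


def write_sites_bed(sites: Sequence[IesSite], path: str | Path, chrom: str = "conMAC") -> None:
    """Sites as BED: category in the name field, supporting reads as score."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{chrom}\t{s.window[0]}\t{s.window[1]}\t{s.category}\t{s.support}\t.\n"
            )


def read_sites_bed(path: str | Path) -> list[IesSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            _chrom, start, end, name, score, _strand = line.rstrip("\n").split("\t")
            n = int(score)
            site = IesSite(window=(int(start), int(end)), category=name)
            # support counts are not attributable to sides after a round trip;
            # keep the total in l_support placeholders
            site.l_support = [f"read{i}" for i in range(n)]
            sites.append(site)
    return sites


def junctions_table(sites: Sequence[IesSite]) -> pd.DataFrame:
    """Tabular junction report mirroring a published junction-table layout."""
    rows = []
    for s in sites:
        jm = s.junction
        rows.append(
            {
                "window_start": s.window[0],
                "window_end": s.window[1],
                "category": s.category,
                "n_L": len(s.l_support),
                "n_R": len(s.r_support),
                "junction": render_junction(jm) if jm else "",
                "microhomology": jm.microhomology if jm else "",
                "has_TA": jm.has_TA if jm else None,
                "has_TTAA": jm.has_TTAA if jm else None,
                "ies_len": jm.ies_len if jm else None,
                "length_is_exact": jm.length_is_exact if jm else None,
            }
        )
    return pd.DataFrame(rows)


def write_ies_fasta(sites: Sequence[IesSite], path: str | Path) -> None:
    """Assembled IES core sequences (win1 sites with an exact assembly)."""
    with open(path, "w") as fh:
        for s in sites:
            jm = s.junction
            if jm is not None and jm.ies_seq:
                fh.write(f">ies_{s.window[0]}_{s.window[1]}\n{jm.ies_seq}\n")


def write_summary_json(
    result: PipelineResult, cfg: PipelineConfig, path: str | Path
) -> None:
    summary = {
        "config": cfg.as_dict(),
        "tally": result.tally.as_dict(),
        "n_sites": {
            cat: sum(1 for s in result.sites if s.category == cat)
            for cat in ("win1", "win2", "win3")
        },
        "n_vetoed": len(result.vetoed),
        "coverage_bp": result.coverage,
        "n_discarded_reads": result.n_discarded,
    }
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
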