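"""From outlier windows to interpretable candidate regions.

Outlier windows are annotated with overlapping and flanking genes
(±200 kb by default), compared across breeds, merged into contiguous
sweep regions, and cross-checked between the heterozygosity and F_ST
scans.  All intervals here are 0-based half-open; GFF3 input (1-based
inclusive) is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pyranges as pr

__all__ = [
    "GeneModel",
    "AnnotatedWindow",
    "SweepRegion",
    "read_gff3_genes",
    "read_bed_genes",
    "annotate_window",
    "shared_windows",
    "merge_regions",
    "concordant_signals",
]

Window = tuple[str, int, int]  # (chrom, start0, end0)


@dataclass(frozen=True)
class GeneModel:
    """A gene span (0-based half-open)."""

    gene_id: str
    gene_name: str
    chrom: str
    start0: int
    end0: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.end0 <= self.start0:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")


@dataclass
class AnnotatedWindow:
    """One window with its overlapping and flanking genes and sharing breeds."""

    window: Window
    genes_within: list[GeneModel]
    genes_flanking: list[GeneModel]
    breeds: set[str] = field(default_factory=set)

    def gene_names(self) -> list[str]:
        return [g.gene_name for g in self.genes_within + self.genes_flanking]


@dataclass
class SweepRegion:
    """Merged run of outlier windows on one chromosome."""

    chrom: str
    start0: int
    end0: int
    member_windows: list[Window]
    breeds: set[str] = field(default_factory=set)

    def contains(self, chrom: str, pos1: int) -> bool:
        """Containment of a 1-based position (half-open on the region)."""
        return chrom == self.chrom and self.start0 <= pos1 - 1 < self.end0


# ---------------------------------------------------------------------------
# Gene-model input
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str, feature: str = "gene") -> list[GeneModel]:
    """Protein-coding-style gene records from a GFF3 file (via pyranges)."""
    df = pr.read_gff3(path).df
    df = df[df["Feature"] == feature]
    genes = []
    for _, r in df.iterrows():
        gid = str(r.get("ID") or r.get("gene_id") or f"{r.Chromosome}:{r.Start}")
        gid = gid.removeprefix("gene:")
        name = r.get("Name")
        if not isinstance(name, str) or not name:
            name = gid
        biotype = r.get("biotype") or r.get("gene_biotype") or "protein_coding"
        genes.append(GeneModel(gid, str(name), str(r.Chromosome),
                               int(r.Start), int(r.End), str(biotype)))
    return sorted(genes, key=lambda g: (g.chrom, g.start0))


def read_bed_genes(path: str) -> list[GeneModel]:
    """Gene spans from a 4+-column BED file (already 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = [
        GeneModel(str(r[3]), str(r[3]), str(r[0]), int(r[1]), int(r[2]))
        for _, r in df.iterrows()
    ]
    return sorted(genes, key=lambda g: (g.chrom, g.start0))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _overlaps(g: GeneModel, chrom: str, start0: int, end0: int) -> bool:
    return g.chrom == chrom and g.start0 < end0 and g.end0 > start0


def annotate_window(
    window: Window,
    genes: Sequence[GeneModel],
    flank: int = 200_000,
    chrom_length: int | None = None,
) -> AnnotatedWindow:
    """Genes overlapping the window, and genes within ±``flank`` of it.

    ``genes_within`` overlap ``[start0, end0)``; ``genes_flanking``
    overlap ``[start0 - flank, start0) ∪ [end0, end0 + flank)`` without
    overlapping the window itself, so the two lists are disjoint.  Flank
    intervals are clipped at 0 and (when known) the chromosome length.
    Gene input order does not affect the result.
    """
    chrom, start0, end0 = window
    lo = max(0, start0 - flank)
    hi = end0 + flank if chrom_length is None else min(end0 + flank, chrom_length)
    within, flanking = [], []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start0, g.gene_id)):
        if _overlaps(g, chrom, start0, end0):
            within.append(g)
        elif _overlaps(g, chrom, lo, start0) or _overlaps(g, chrom, end0, hi):
            flanking.append(g)
    return AnnotatedWindow(window, within, flanking)


# ---------------------------------------------------------------------------
# Cross-breed sharing and merging
# ---------------------------------------------------------------------------

def shared_windows(
    outlier_sets: Mapping[str, Iterable[Window]], min_breeds: int = 2
) -> list[tuple[Window, set[str]]]:
    """Windows appearing in at least ``min_breeds`` of the per-breed sets.

    Sorted by breed count descending, then by genomic order.
    """
    if len(outlier_sets) < 2:
        raise ValueError("need at least 2 outlier sets")
    counts: dict[Window, set[str]] = {}
    for breed, wins in outlier_sets.items():
        for w in wins:
            counts.setdefault(tuple(w), set()).add(breed)
    hits = [(w, b) for w, b in counts.items() if len(b) >= min_breeds]
    hits.sort(key=lambda wb: (-len(wb[1]), wb[0]))
    return hits


def merge_regions(
    windows: Sequence[Window],
    max_gap: int = 0,
    breeds: Mapping[Window, set[str]] | None = None,
) -> list[SweepRegion]:
    """Merge same-chromosome windows whose gap is at most ``max_gap``.

    Adjacent windows (gap 0) merge by default; the output is a partition
    of the input windows whose spans cover all members.  Per-window breed
    sets, when given, are unioned into the region.
    """
    wins = sorted(set(map(tuple, windows)))
    regions: list[SweepRegion] = []
    for w in wins:
        chrom, s, e = w
        b = set(breeds.get(w, set())) if breeds else set()
        last = regions[-1] if regions else None
        if last is not None and last.chrom == chrom and s - last.end0 <= max_gap:
            last.end0 = max(last.end0, e)
            last.member_windows.append(w)
            last.breeds |= b
        else:
            regions.append(SweepRegion(chrom, s, e, [w], b))
    return regions


def concordant_signals(
    hp_windows: Iterable[Window],
    fst_windows: Iterable[Window],
    max_distance: int = 500_000,
) -> list[tuple[Window, Window]]:
    """Pairs of H_P and F_ST outlier windows closer than ``max_distance``.

    Distance is between closest edges on the same chromosome (overlapping
    or adjacent windows have distance 0); the bound is strict (<).
    """
    out = []
    for hw in sorted(set(map(tuple, hp_windows))):
        for fw in sorted(set(map(tuple, fst_windows))):
            if hw[0] != fw[0]:
                continue
            gap = max(hw[1] - fw[2], fw[1] - hw[2], 0)
            if gap < max_distance:
                out.append((hw, fw))
    return out


def regions_to_frame(regions: Sequence[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom, "start0": r.start0, "end0": r.end0,
                "n_windows": len(r.member_windows),
                "breeds": ",".join(sorted(r.breeds)),
            }
            for r in regions
        ],
        columns=["chrom", "start0", "end0", "n_windows", "breeds"],
    )
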