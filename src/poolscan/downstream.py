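"""Gene-set enrichment and deleterious-variant contrasts.

Enrichment follows the Enrichr-style recipe: one-sided Fisher's exact
test of each term's 2x2 overlap table against a fixed gene universe,
Benjamini-Hochberg adjustment across terms, then the reporting filter
(>= 4 overlap genes drawn from >= 2 distinct genome windows, adjusted
p < 0.05).

The deleterious-variant analysis consumes an externally produced impact
table (consequence + SIFT-style score): harmful = stop gain, stop lost,
or non-synonymous with SIFT < 0.05 (strict).  The putative ancestral
allele at a site is whichever allele exceeds frequency 0.5 in the wild
pool; breed-vs-wild frequency contrasts flag near-fixed differences
(AF > 0.8 on one side, < 0.2 on the other), and surviving variants are
intersected with the sweep regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import SweepRegion

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "ImpactRecord",
    "read_gmt",
    "fisher_enrichment",
    "filter_enrichment",
    "classify_deleterious",
    "ancestral_allele",
    "frequency_contrast",
    "deleterious_in_sweeps",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a universe of annotatable genes."""

    sets: dict[str, list[str]]
    universe_size: int

    def __post_init__(self) -> None:
        if any(len(g) == 0 for g in self.sets.values()):
            raise ValueError("every gene set must be non-empty")
        if self.sets and self.universe_size < max(len(g) for g in self.sets.values()):
            raise ValueError("universe smaller than the largest set")
        # drop duplicate genes within a set, preserving order
        self.sets = {t: list(dict.fromkeys(g)) for t, g in self.sets.items()}

    def universe(self) -> set[str]:
        return set().union(*map(set, self.sets.values())) if self.sets else set()


def read_gmt(path: str, universe_size: int | None = None) -> GeneSetCollection:
    """GMT format: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if universe_size is None:
        universe_size = len(set().union(*map(set, sets.values()))) if sets else 0
    return GeneSetCollection(sets, universe_size)


def read_gene_sets_tsv(path: str, universe_size: int | None = None
                       ) -> GeneSetCollection:
    """Two-column TSV (term, gene), one pair per line."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"])
    sets = {t: list(g) for t, g in df.groupby("term")["gene"]}
    if universe_size is None:
        universe_size = len(set(df["gene"]))
    return GeneSetCollection(sets, universe_size)


@dataclass
class EnrichmentRow:
    """One term's enrichment result."""

    term: str
    overlap_genes: list[str]
    overlap_windows: int
    p_raw: float
    p_adj: float = float("nan")

    @property
    def n_overlap(self) -> int:
        return len(self.overlap_genes)


def fisher_enrichment(
    input_genes: Iterable[str], collection: GeneSetCollection
) -> list[EnrichmentRow]:
    """One-sided Fisher exact enrichment of each term, BH-adjusted.

    For a term of size S with overlap k against an input of size I in a
    universe of size U, the 2x2 table is ``[[k, I-k], [S-k, U-S-I+k]]``
    and p is the upper (enrichment) tail.  Input genes outside the
    collection's universe are dropped with a warning.  Rows come back
    sorted by raw p.  ``overlap_windows`` is filled by
    :func:`filter_enrichment` (0 here).
    """
    genes = set(input_genes)
    universe = collection.universe()
    outside = genes - universe
    if outside:
        warnings.warn(
            f"{len(outside)} input gene(s) outside the collection universe "
            "were dropped", stacklevel=2,
        )
        genes -= outside
    if not genes:
        raise ValueError("no input genes left after universe intersection")
    U, I = collection.universe_size, len(genes)
    rows = []
    for term, members in collection.sets.items():
        S = len(members)
        k = len(genes & set(members))
        table = [[k, I - k], [S - k, U - S - (I - k)]]
        p = float(stats.fisher_exact(table, alternative="greater").pvalue)
        rows.append(EnrichmentRow(term, sorted(genes & set(members)), 0, p))
    if rows:
        adj = multipletests([r.p_raw for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, adj):
            r.p_adj = float(q)
    rows.sort(key=lambda r: (r.p_raw, r.term))
    return rows


def filter_enrichment(
    rows: Sequence[EnrichmentRow],
    window_map: Mapping[str, Iterable],
    min_genes: int = 4,
    min_windows: int = 2,
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Keep terms with enough overlap genes spread over enough windows.

    ``window_map`` maps gene -> the genome windows it came from; a row
    survives when it has at least ``min_genes`` overlap genes, those
    genes trace back to at least ``min_windows`` distinct windows, and
    ``p_adj < alpha`` (strict).
    """
    kept = []
    for r in rows:
        wins = set()
        for g in r.overlap_genes:
            wins.update(map(tuple, window_map.get(g, ())))
        r.overlap_windows = len(wins)
        if (r.n_overlap >= min_genes and r.overlap_windows >= min_windows
                and r.p_adj < alpha):
            kept.append(r)
    return kept


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term": r.term, "n_genes": r.n_overlap,
             "n_windows": r.overlap_windows, "p_raw": r.p_raw, "p_adj": r.p_adj,
             "genes": ",".join(r.overlap_genes)}
            for r in rows
        ]
    )


# ---------------------------------------------------------------------------
# Deleterious variants
# ---------------------------------------------------------------------------

HARMFUL_CONSEQUENCES = ("stop_gain", "stop_lost")
SIFT_DELETERIOUS = 0.05  # strict upper bound for nsSNPs


@dataclass(frozen=True)
class ImpactRecord:
    """A variant's predicted protein impact plus derived annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    consequence: str  # nsSNP, stop_gain, stop_lost, other
    sift_score: float | None
    deleterious: bool
    ancestral_allele: str = "undetermined"  # ref / alt / undetermined


def classify_deleterious(impact: pd.DataFrame) -> tuple[list[ImpactRecord], dict]:
    """Mark harmful variants in an impact table.

    Expects columns ``chrom, pos, ref, alt, gene, consequence, sift_score``
    (sift may be NaN).  Deleterious = stop gain, stop lost, or nsSNP with
    SIFT strictly below 0.05; nsSNPs with a missing score are not
    deleterious and are counted separately.  The summary counts satisfy
    ``deleterious_total == deleterious_nsSNP + stop_gain + stop_lost``.
    """
    records = []
    counts = {"deleterious_nsSNP": 0, "stop_gain": 0, "stop_lost": 0,
              "nsSNP_missing_sift": 0, "deleterious_total": 0}
    for _, r in impact.iterrows():
        cons = str(r["consequence"])
        sift = r.get("sift_score")
        sift = None if pd.isna(sift) else float(sift)
        if cons in HARMFUL_CONSEQUENCES:
            dele = True
            counts[cons] += 1
        elif cons == "nsSNP":
            if sift is None:
                dele = False
                counts["nsSNP_missing_sift"] += 1
            else:
                dele = sift < SIFT_DELETERIOUS
                counts["deleterious_nsSNP"] += int(dele)
        else:
            dele = False
        records.append(ImpactRecord(
            str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"]),
            str(r["gene"]), cons, sift, dele,
        ))
    counts["deleterious_total"] = (
        counts["deleterious_nsSNP"] + counts["stop_gain"] + counts["stop_lost"]
    )
    return records, counts


def ancestral_allele(wild_af: float) -> str:
    """Putative ancestral form from the wild-pool alt-allele frequency.

    ``alt`` when the wild frequency of the alternative allele exceeds
    0.5, ``ref`` below 0.5, ``undetermined`` at exactly 0.5 or when the
    frequency is undefined (NaN).
    """
    if wild_af is None or np.isnan(wild_af):
        return "undetermined"
    if wild_af > 0.5:
        return "alt"
    if wild_af < 0.5:
        return "ref"
    return "undetermined"


def frequency_contrast(
    af_group: float, af_wild: float, hi: float = 0.8, lo: float = 0.2
) -> bool:
    """Near-fixed frequency difference between a group and the wild pool.

    True iff AF > ``hi`` on one side and AF < ``lo`` on the other (both
    inequalities strict), in either direction.
    """
    if np.isnan(af_group) or np.isnan(af_wild):
        raise ValueError("both allele frequencies must be defined")
    return ((af_group > hi and af_wild < lo)
            or (af_group < lo and af_wild > hi))


def deleterious_in_sweeps(
    records: Iterable[ImpactRecord], regions: Sequence[SweepRegion]
) -> list[ImpactRecord]:
    """Deleterious records whose position falls inside any sweep region.

    Containment is 0-based half-open: a record at the region start is
    included, one at the end coordinate is not.
    """
    out = []
    for rec in records:
        if not rec.deleterious:
            continue
        if any(reg.contains(rec.chrom, rec.pos) for reg in regions):
            out.append(rec)
    return out
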