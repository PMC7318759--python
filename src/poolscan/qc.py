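"""Variant quality control for pooled-sequencing SNP panels.

Implements a three-step filtering procedure standard in pool-seq studies:

1. hard site filters — bi-allelic SNPs only, per-pool depth within
   ``[rd_min, rd_max]`` (the upper bound from Li's heuristic
   ``RD_max = RD_mean + 4 * sqrt(RD_mean)``), a minimum total number of
   alternative reads across pools, and removal of flagged sites;
2. a catalogue-aware quality cutoff — rare variants (panel-wide minor
   allele frequency below the pool detection limit ``1/(ploidy * n)``) are
   split into catalogue-known and novel sub-classes, and the caller
   quality cutoff is chosen to minimise the two-sample Kolmogorov-Smirnov
   D between the two retained quality distributions;
3. the transition/transversion ratio as a global quality indicator.

Also provides the allele-frequency concordance check against external
per-pool genotype frequencies (array-genotyping style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import VariantTable

__all__ = [
    "FilterConfig",
    "KSResult",
    "rd_max_threshold",
    "maf_rare_limit",
    "step1_filter",
    "classify_variants",
    "ks_d_statistic",
    "select_quality_cutoff",
    "ts_tv_ratio",
    "af_concordance",
]


def rd_max_threshold(rd_mean: float) -> int:
    """Maximum-depth cutoff ``round(RD_mean + 4 * sqrt(RD_mean))``.

    Li's rule of thumb for excluding collapsed-repeat pileups: with a mean
    depth of 42x this gives 68.  Strictly increasing in ``rd_mean``.
    """
    if rd_mean <= 0:
        raise ValueError("rd_mean must be positive")
    return int(math.floor(rd_mean + 4.0 * math.sqrt(rd_mean) + 0.5))


def maf_rare_limit(n_individuals: int, ploidy: int = 2) -> float:
    """Ideal minor-allele detection limit ``1/(ploidy * n)`` of a pool.

    For 35 diploids this is 1/70 ~= 0.0143 (reported to 4 decimals).  A
    variant rarer than this cannot be carried by even a single chromosome
    of the pool, so lower observed frequencies are suspect.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    return round(1.0 / (ploidy * n_individuals), 4)


@dataclass
class FilterConfig:
    """Thresholds for the hard site filters (step 1) and the quality grid.

    Defaults reproduce a 42x pool-seq design: ``rd_min=10`` reads per pool,
    at least 3 alternative reads panel-wide, ``rd_max`` derived from the
    mean depth, and rarity below ``1/70``.
    """

    rd_min: int = 10
    min_alt_reads_total: int = 3
    rd_mean: float = 42.0
    rd_max: int | None = None  # derived from rd_mean when None
    maf_rare_limit: float = 0.0143
    q_grid: Sequence[int] = tuple(range(0, 51))
    excluded_flags: frozenset[str] = frozenset({"low_quality_region", "strand_bias"})
    excluded_chroms: frozenset[str] = frozenset()  # e.g. {"X", "Y", "MT"}

    def __post_init__(self) -> None:
        if self.rd_min < 1:
            raise ValueError("rd_min must be >= 1")
        if len(self.q_grid) == 0:
            raise ValueError("q_grid must be non-empty")
        if self.rd_max is None:
            self.rd_max = rd_max_threshold(self.rd_mean)
        if self.rd_max <= self.rd_min:
            raise ValueError("rd_max must exceed rd_min")


#: Attribution order for step-1 removal counts: a site failing several
#: rules is counted once, under the first failing rule in this order.
STEP1_RULES = ("excluded_chrom", "biallelic", "rd_min", "alt_reads", "rd_max", "flags")


def step1_filter(
    table: VariantTable, cfg: FilterConfig
) -> tuple[VariantTable, dict[str, int]]:
    """Apply the hard site filters; return survivors and per-rule removals.

    Retains sites satisfying all of: chromosome not excluded; bi-allelic
    (guaranteed by the table representation, counted as 0); depth >=
    ``rd_min`` in every pool; total alt reads across pools >=
    ``min_alt_reads_total``; depth <= ``rd_max`` in every pool; no
    excluded flag.  All depth bounds are inclusive.  Removal counts +
    survivors always sum to the input site count, and the filter is
    idempotent.
    """
    depth = table.depth()
    chrom = table.sites["chrom"].to_numpy()
    fails = {
        "excluded_chrom": np.isin(chrom, list(cfg.excluded_chroms)),
        "biallelic": np.zeros(len(table), dtype=bool),  # enforced at I/O
        "rd_min": (depth < cfg.rd_min).any(axis=1),
        "alt_reads": table.alt_reads.sum(axis=1) < cfg.min_alt_reads_total,
        "rd_max": (depth > cfg.rd_max).any(axis=1),
        "flags": np.array(
            [bool(f & cfg.excluded_flags) for f in table.sites["flags"]], dtype=bool
        ),
    }
    removed = np.zeros(len(table), dtype=bool)
    counts: dict[str, int] = {}
    for rule in STEP1_RULES:
        newly = fails[rule] & ~removed
        counts[rule] = int(newly.sum())
        removed |= fails[rule]
    return table.subset(~removed), counts


def classify_variants(
    table: VariantTable, maf_limit: float
) -> tuple[pd.DataFrame, np.ndarray]:
    """Partition sites into {in.dbSNP, novel} x {rare, common} classes.

    The panel-wide AF is total alt reads over total reads; ``rare`` means
    minor allele frequency strictly below ``maf_limit``.  Sites whose AF
    is undefined (zero total depth) are excluded from classification and
    returned as the second element (boolean mask of excluded sites).
    """
    af = table.pooled_af()
    excluded = np.isnan(af)
    maf = np.minimum(af, 1.0 - af)
    catalogue = np.where(table.sites["in_catalogue"], "in.dbSNP", "novel")
    rarity = np.where(maf < maf_limit, "rare", "common")
    df = pd.DataFrame({
        "chrom": table.sites["chrom"], "pos": table.sites["pos"],
        "af": af, "maf": maf,
        "catalogue": catalogue, "rarity": rarity,
    })
    df.loc[excluded, ["catalogue", "rarity"]] = None
    return df, excluded


def ks_d_statistic(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov D: sup |ECDF_a - ECDF_b| in [0, 1]."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


@dataclass
class KSResult:
    """Quality-cutoff scan: KS D per candidate cutoff and the minimiser."""

    grid: list[int]
    d_values: list[float]  # NaN where D is undefined (an empty sub-class)
    selected_q: int
    excluded: list[int] = field(default_factory=list)  # cutoffs with empty class

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Q": self.grid, "D": self.d_values})


def select_quality_cutoff(
    quality: Sequence[float],
    in_catalogue: Sequence[bool],
    grid: Sequence[int] = tuple(range(0, 51)),
) -> KSResult:
    """Choose the caller quality cutoff for rare variants by minimum KS D.

    ``quality`` and ``in_catalogue`` describe the *rare* variants only.
    For each candidate cutoff Q, variants with quality >= Q are retained
    and D is computed between the retained quality distributions of the
    catalogue-known and novel sub-classes; the selected cutoff minimises
    D, ties broken by the smallest Q.  Cutoffs at which either sub-class
    becomes empty are excluded from the argmin and reported.
    """
    q = np.asarray(quality, dtype=float)
    cat = np.asarray(in_catalogue, dtype=bool)
    grid = list(grid)
    if not grid:
        raise ValueError("empty cutoff grid")
    known, novel = q[cat], q[~cat]
    if known.size == 0 or novel.size == 0:
        raise ValueError("both sub-classes must be non-empty")
    d_values, excluded = [], []
    for cutoff in grid:
        ka, nv = known[known >= cutoff], novel[novel >= cutoff]
        if ka.size == 0 or nv.size == 0:
            d_values.append(float("nan"))
            excluded.append(cutoff)
        else:
            d_values.append(ks_d_statistic(ka, nv))
    d_arr = np.asarray(d_values)
    valid = ~np.isnan(d_arr)
    if not valid.any():
        raise ValueError("D undefined at every cutoff")
    best = int(np.flatnonzero(valid)[np.argmin(d_arr[valid])])  # first minimum
    return KSResult(grid=grid, d_values=d_values,
                    selected_q=grid[best], excluded=excluded)


_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def ts_tv_ratio(table: VariantTable) -> float:
    """Transition/transversion ratio, a panel-level quality indicator.

    Genome-wide mammalian values fall around 2.1-2.4; a markedly lower
    ratio suggests false-positive calls.  Raises ``ValueError`` when
    there are no transversions (the ratio is undefined, not infinite).
    """
    pairs = [frozenset((r, a))
             for r, a in zip(table.sites["ref"], table.sites["alt"])]
    ts = sum(p in _TRANSITIONS for p in pairs)
    tv = len(pairs) - ts
    if tv == 0:
        raise ValueError("no transversions: Ts/Tv undefined")
    return ts / tv


_STRAND_SYMMETRIC = {frozenset("CG"), frozenset("AT")}


def af_concordance(
    seq_af: pd.DataFrame,
    geno_af: pd.DataFrame,
    missingness: pd.DataFrame | None = None,
    max_missing: float = 0.10,
) -> dict[str, float]:
    """Pearson r per pool between sequencing AF and external genotype AF.

    Both frames are indexed by ``(chrom, pos, ref, alt)`` with one column
    per pool, oriented to the alternative allele.  Strand-symmetric
    substitutions (C<->G and A<->T), whose orientation cannot be
    harmonised between platforms, are excluded, as are sites exceeding
    ``max_missing`` genotype missingness in the pool (``missingness``
    frame, same shape as ``geno_af``).  Raises ``ValueError`` for a pool
    with fewer than 2 usable shared sites.
    """
    shared = seq_af.index.intersection(geno_af.index)
    alleles = pd.DataFrame(
        [(k[2], k[3]) for k in shared], index=shared, columns=["ref", "alt"]
    )
    symmetric = np.array(
        [frozenset((r, a)) in _STRAND_SYMMETRIC
         for r, a in zip(alleles["ref"], alleles["alt"])]
    )
    shared = shared[~symmetric]
    out: dict[str, float] = {}
    for pool in seq_af.columns:
        x = seq_af.loc[shared, pool].to_numpy(dtype=float)
        y = geno_af.loc[shared, pool].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if missingness is not None:
            miss = missingness.loc[shared, pool].to_numpy(dtype=float)
            ok &= miss <= max_missing
        if ok.sum() < 2:
            raise ValueError(f"pool {pool!r}: fewer than 2 usable shared sites")
        out[pool] = float(stats.pearsonr(x[ok], y[ok]).statistic)
    return out


def filter_report(counts: Mapping[str, int], retained: int) -> pd.DataFrame:
    """Step-1 removal accounting as a tidy frame (rule, removed, retained)."""
    rows = [{"rule": r, "removed": counts.get(r, 0)} for r in STEP1_RULES]
    rows.append({"rule": "retained", "removed": retained})
    return pd.DataFrame(rows)
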