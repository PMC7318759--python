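"""Synthetic pooled-sequencing panels with planted selection signals.

The generator emulates the statistical structure the scan assumes, not
sequence-level realism: independent bi-allelic SNPs whose ancestral
allele frequencies are uniform on (0.05, 0.95); per-pool frequencies
drifted around the ancestral value under the Balding-Nichols Beta model
with drift coefficient F; finite-pool sampling of 2n chromosomes per
pool; Poisson read depth (42x by default, 12x for a wild pool) and
binomial read sampling — so read-count allele frequencies carry both the
finite-pool and the sequencing noise that the 1/(2n) detection limit and
the depth filters are about.

Selection signals are planted two ways: *sweeps* force the alternative
allele to near-fixation in target pools over an interval (depressing
heterozygosity and raising differentiation there), and *group loci*
force opposite near-fixed frequencies between the pools of two group
labels (the KIT-like coat-colour situation).  A TruthSet records what
was planted so recovery can be scored.

The generator also emits the ancillary inputs the downstream stages
consume: synthetic gene models, gene sets, an impact table and pool
coordinates.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import GeneModel
from .variants import PoolPanel, PoolSample, VariantTable
from .windows import GenomeWindows, OutlierSet

__all__ = [
    "Sweep",
    "GroupLocus",
    "SimConfig",
    "TruthSet",
    "SimResult",
    "simulate_panel",
    "plant_sweeps",
    "truth_recovery_report",
]

#: Default toy genome: three 5-Mb chromosomes plus one short scaffold so
#: unplaced-scaffold handling is exercised; full-genome scale is a config
#: change, not a code change.
DEFAULT_CHROM_LENGTHS = {"1": 5_000_000, "2": 5_000_000, "3": 5_000_000,
                         "scaffold_1": 300_000}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"),
                  "C": ("A", "G"), "T": ("A", "G")}


@dataclass(frozen=True)
class Sweep:
    """A planted hard sweep: near-fixation of the alt allele in targets."""

    chrom: str
    start0: int
    end0: int
    target_pools: tuple[str, ...]
    final_af: float = 0.98


@dataclass(frozen=True)
class GroupLocus:
    """An interval differentiated between one group's pools and the rest."""

    chrom: str
    start0: int
    end0: int
    scheme: str
    label: str
    af_in: float = 0.97
    af_out: float = 0.03


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults mirror a 42x pool-seq design: 35 diploids per pool, mean
    depth 42 (12 for the wild pool), ~1148 SNPs per 100-kb window
    (density 0.01148/bp), transition:transversion sampling odds 2.4:1.
    ``drift_f`` is the Balding-Nichols drift coefficient per pool.
    """

    n_pools: int = 5
    n_individuals: int = 35
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    snp_density: float = 1148 / 100_000
    mean_depth: float = 42.0
    wild_depth: float = 12.0
    include_wild: bool = False
    drift_f: float | Sequence[float] = 0.10
    sweeps: tuple[Sweep, ...] = ()
    group_loci: tuple[GroupLocus, ...] = ()
    group_schemes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    ts_tv_odds: float = 2.4
    catalogue_rate: float = 0.7
    q_mean_good: float = 35.0
    q_sd_good: float = 5.0
    q_mean_bad: float = 10.0
    q_sd_bad: float = 4.0
    novel_bad_fraction: float = 0.5
    q_max: float = 50.0
    seed: int = 0

    def pool_names(self) -> list[str]:
        names = [f"breed_{i + 1}" for i in range(self.n_pools)]
        if self.include_wild:
            names.append("wild")
        return names

    def validate(self) -> None:
        for s in self.sweeps:
            if s.chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {s.chrom!r}")
            if not (0 <= s.start0 < s.end0 <= self.chrom_lengths[s.chrom]):
                raise ValueError(f"sweep {s} outside chromosome bounds")
        f = np.atleast_1d(np.asarray(self.drift_f, dtype=float))
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("drift_f must lie in (0, 1)")
        if self.mean_depth <= 0 or self.wild_depth <= 0:
            raise ValueError("depths must be positive")


@dataclass
class TruthSet:
    """What the generator planted, for scoring recovery."""

    ancestral_af: np.ndarray          # (n_sites,)
    pool_af: np.ndarray               # (n_sites, n_pools) post-sweep truth
    sample_af: np.ndarray             # (n_sites, n_pools) finite-pool truth
    sweeps: tuple[Sweep, ...]
    group_loci: tuple[GroupLocus, ...]

    def sweep_window_indices(self, gw: GenomeWindows, pool: str) -> set[int]:
        """Window indices overlapping any sweep targeting ``pool``."""
        out: set[int] = set()
        for s in self.sweeps:
            if pool not in s.target_pools:
                continue
            for i in range(len(gw)):
                if (gw.chrom[i] == s.chrom and gw.start0[i] < s.end0
                        and gw.end0[i] > s.start0):
                    out.add(i)
        return out

    def locus_window_indices(self, gw: GenomeWindows, scheme: str) -> set[int]:
        out: set[int] = set()
        for g in self.group_loci:
            if g.scheme != scheme:
                continue
            for i in range(len(gw)):
                if (gw.chrom[i] == g.chrom and gw.start0[i] < g.end0
                        and gw.end0[i] > g.start0):
                    out.add(i)
        return out


@dataclass
class SimResult:
    table: VariantTable
    panel: PoolPanel
    truth: TruthSet
    genes: list[GeneModel]
    gene_sets: dict[str, list[str]]
    impact: pd.DataFrame


def plant_sweeps(
    chrom_lengths: Mapping[str, int],
    n_sweeps: int,
    target_pools: Sequence[str],
    width: int = 100_000,
    final_af: float = 0.98,
    seed: int = 0,
) -> tuple[Sweep, ...]:
    """Place ``n_sweeps`` non-overlapping window-aligned sweep intervals.

    Intervals are aligned to the ``width`` grid so each sweep occupies
    exactly one scan window, which makes recovery scoring unambiguous.
    """
    rng = np.random.default_rng(seed)
    slots = [(c, k * width) for c, ln in chrom_lengths.items()
             for k in range(ln // width)]
    if n_sweeps > len(slots):
        raise ValueError("not enough windows to place the sweeps")
    chosen = rng.choice(len(slots), size=n_sweeps, replace=False)
    return tuple(
        Sweep(slots[i][0], slots[i][1], slots[i][1] + width,
              tuple(target_pools), final_af)
        for i in sorted(chosen)
    )


def _draw_positions(rng, chrom_lengths, density):
    chroms, pos = [], []
    for c, ln in chrom_lengths.items():
        n = int(round(ln * density))
        p = np.unique(rng.integers(1, ln + 1, size=int(n * 1.1) + 8))
        p = rng.permutation(p)[:n]
        p.sort()
        chroms.extend([c] * len(p))
        pos.append(p)
    return np.array(chroms, dtype=object), np.concatenate(pos)


def _in_interval(chrom, pos, iv_chrom, s0, e0):
    return (chrom == iv_chrom) & (pos - 1 >= s0) & (pos - 1 < e0)


def simulate_panel(cfg: SimConfig) -> SimResult:
    """Generate a full synthetic panel (see module docstring)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = cfg.pool_names()
    n_pools = len(names)
    n_chrom_copies = 2 * cfg.n_individuals

    # pool metadata: group labels round-robin per scheme, European-ish coords
    schemes = dict(cfg.group_schemes)
    pools = []
    for i, name in enumerate(names):
        labels = {}
        for scheme, lab_list in schemes.items():
            if name != "wild":
                labels[scheme] = lab_list[i % len(lab_list)]
        pools.append(PoolSample(
            name=name, n_individuals=cfg.n_individuals, ploidy=2,
            group_labels=labels,
            longitude=float(rng.uniform(-9.0, 25.0)),
            latitude=float(rng.uniform(36.0, 56.0)),
        ))
    panel = PoolPanel(pools, wild_pool="wild" if cfg.include_wild else None)

    chrom, pos = _draw_positions(rng, cfg.chrom_lengths, cfg.snp_density)
    n_sites = len(pos)

    # ancestral and drifted pool frequencies (Balding-Nichols)
    anc = rng.uniform(0.05, 0.95, size=n_sites)
    F = np.broadcast_to(np.atleast_1d(np.asarray(cfg.drift_f, float)),
                        (n_pools,)).copy()
    pool_af = np.empty((n_sites, n_pools))
    for j in range(n_pools):
        a = anc * (1.0 - F[j]) / F[j]
        b = (1.0 - anc) * (1.0 - F[j]) / F[j]
        pool_af[:, j] = rng.beta(a, b)

    # planted sweeps: alt allele near fixation in target pools
    for s in cfg.sweeps:
        m = _in_interval(chrom, pos, s.chrom, s.start0, s.end0)
        for t in s.target_pools:
            j = panel.index(t)
            pool_af[m, j] = rng.uniform(s.final_af, 1.0, size=int(m.sum()))

    # planted group-differentiated loci
    for g in cfg.group_loci:
        m = _in_interval(chrom, pos, g.chrom, g.start0, g.end0)
        in_group = set(panel.group(g.scheme, g.label))
        for j, name in enumerate(names):
            target = g.af_in if name in in_group else g.af_out
            jitter = rng.uniform(-0.02, 0.02, size=int(m.sum()))
            pool_af[m, j] = np.clip(target + jitter, 0.0, 1.0)

    # finite pool, then reads
    sample_count = rng.binomial(n_chrom_copies, pool_af)
    sample_af = sample_count / n_chrom_copies
    depths = np.full(n_pools, cfg.mean_depth)
    if cfg.include_wild:
        depths[panel.index("wild")] = cfg.wild_depth
    depth = rng.poisson(depths, size=(n_sites, n_pools))
    depth = np.maximum(depth, 1)  # truncation at >= 1
    alt_reads = rng.binomial(depth, sample_af)
    ref_reads = depth - alt_reads

    # substitution types with Ts:Tv odds
    ref = rng.choice(np.array(list("ACGT")), size=n_sites)
    is_ts = rng.random(n_sites) < cfg.ts_tv_odds / (cfg.ts_tv_odds + 1.0)
    tv_pick = rng.integers(0, 2, size=n_sites)
    alt = np.array([
        _TRANSITION[r] if t else _TRANSVERSIONS[r][k]
        for r, t, k in zip(ref, is_ts, tv_pick)
    ], dtype=object)

    # catalogue membership and caller quality (bimodal for novel sites)
    in_cat = rng.random(n_sites) < cfg.catalogue_rate
    qual = rng.normal(cfg.q_mean_good, cfg.q_sd_good, size=n_sites)
    bad = ~in_cat & (rng.random(n_sites) < cfg.novel_bad_fraction)
    qual[bad] = rng.normal(cfg.q_mean_bad, cfg.q_sd_bad, size=int(bad.sum()))
    qual = np.clip(qual, 0.0, cfg.q_max)

    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos.astype(np.int64),
        "ref": ref.astype(object), "alt": alt,
        "qual": np.round(qual, 2), "in_catalogue": in_cat,
        "flags": [frozenset()] * n_sites,
    })
    table = VariantTable(panel, sites, ref_reads, alt_reads)

    # the table constructor sorts by (chrom, pos); mirror that order in truth
    order = np.lexsort((pos, chrom))
    truth = TruthSet(anc[order], pool_af[order], sample_af[order],
                     cfg.sweeps, cfg.group_loci)

    genes = _synthetic_genes(rng, cfg.chrom_lengths)
    gene_sets = _synthetic_gene_sets(rng, genes)
    impact = _synthetic_impact(rng, table, genes)
    return SimResult(table, panel, truth, genes, gene_sets, impact)


def _synthetic_genes(rng, chrom_lengths, spacing: int = 60_000) -> list[GeneModel]:
    """Regular synthetic gene models (~1 gene / 60 kb, 5-30 kb long)."""
    genes = []
    i = 0
    for c, ln in chrom_lengths.items():
        for s in range(10_000, ln - 30_000, spacing):
            i += 1
            length = int(rng.integers(5_000, 30_000))
            genes.append(GeneModel(f"G{i:05d}", f"GENE{i:05d}", c, s,
                                   min(s + length, ln)))
    return genes


def _synthetic_gene_sets(rng, genes, n_terms: int = 40,
                         set_size: int = 25) -> dict[str, list[str]]:
    names = [g.gene_name for g in genes]
    return {
        f"TERM_{t + 1:03d}": sorted(
            rng.choice(names, size=min(set_size, len(names)),
                       replace=False).tolist())
        for t in range(n_terms)
    }


def _synthetic_impact(rng, table: VariantTable, genes,
                      fraction: float = 0.02) -> pd.DataFrame:
    """Impact rows (consequence + SIFT) for a random subset of sites."""
    n = len(table)
    take = np.flatnonzero(rng.random(n) < fraction)
    cons = rng.choice(["nsSNP", "stop_gain", "stop_lost", "other"],
                      size=len(take), p=[0.55, 0.04, 0.01, 0.40])
    sift = np.round(rng.random(len(take)), 3)
    sift[cons != "nsSNP"] = np.nan
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for idx, cq, sf in zip(take, cons, sift):
        r = table.sites.iloc[idx]
        gene = ""
        for g in by_chrom.get(r["chrom"], ()):
            if g.start0 <= r["pos"] - 1 < g.end0:
                gene = g.gene_name
                break
        rows.append({"chrom": r["chrom"], "pos": int(r["pos"]),
                     "ref": r["ref"], "alt": r["alt"], "gene": gene,
                     "consequence": cq, "sift_score": sf})
    return pd.DataFrame(rows)


def truth_recovery_report(
    truth: TruthSet, outliers: Mapping[str, OutlierSet]
) -> pd.DataFrame:
    """Sensitivity and precision of outlier calls against planted sweeps.

    Per pool: sensitivity = planted sweep windows recovered / planted;
    precision = outlier windows overlapping a planted window / called
    (NaN when no outlier was called).
    """
    rows = []
    for pool, oset in outliers.items():
        gw = oset.track.windows
        planted = truth.sweep_window_indices(gw, pool)
        called = set(int(i) for i in oset.windows)
        tp = len(planted & called)
        rows.append({
            "pool": pool,
            "n_planted": len(planted),
            "n_called": len(called),
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "precision": tp / len(called) if called else float("nan"),
        })
    return pd.DataFrame(rows)
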