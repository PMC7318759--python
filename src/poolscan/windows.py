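"""Window construction and the two selection-scan statistics.

Selective sweeps leave local footprints: depressed heterozygosity within
the selected population and elevated differentiation against others.  The
genome is tiled into fixed-size windows (100 kb by default) and two
statistics are computed per window:

* pooled heterozygosity ``H_P = 2 * SumMaj * SumMin / (SumMaj + SumMin)^2``
  where SumMaj / SumMin are sums of per-SNP major/minor read counts of one
  pool over the window (Rubin-style), optionally log2-transformed;

* the Karlsson et al. per-SNP unbiased F_ST, averaged over the SNPs of the
  window, in pairwise, single-breed (mean across all other pools) and
  group-contrast (read counts summed into super-pools) modes.

Outliers are the windows beyond the 99.95th percentile of the relevant
tail: low H_P, high F_ST.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import VariantTable

__all__ = [
    "GenomeWindows",
    "WindowTrack",
    "ContrastSpec",
    "OutlierSet",
    "make_windows",
    "window_size_diagnostic",
    "hp_window",
    "hp_transform",
    "hp_track",
    "fst_snp_karlsson",
    "fst_window",
    "fst_track",
    "single_breed_fst",
    "group_fst",
    "call_outliers",
]

#: Windows with fewer SNPs than this are discarded from every scan.
MIN_SNPS_PER_WINDOW = 20


class GenomeWindows:
    """Deterministic tiling of chromosomes into fixed windows.

    Window k of a chromosome spans ``[k*step, k*step + size)`` in 0-based
    half-open coordinates (truncated at the chromosome end), reported
    1-based inclusive as ``(k*step + 1, min(k*step + size, length))``.
    Unplaced scaffolds are simply short chromosomes.
    """

    def __init__(self, chrom_lengths: Mapping[str, int],
                 size: int = 100_000, step: int = 100_000):
        if size < 1 or step < 1:
            raise ValueError("size and step must be positive")
        for c, ln in chrom_lengths.items():
            if ln <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length")
        self.chrom_lengths = dict(chrom_lengths)
        self.size = size
        self.step = step
        chroms, starts, ends = [], [], []
        self._offset: dict[str, int] = {}
        for c, ln in self.chrom_lengths.items():
            self._offset[c] = len(starts)
            for s in range(0, ln, step):
                chroms.append(c)
                starts.append(s)
                ends.append(min(s + size, ln))
        self.chrom = np.array(chroms, dtype=object)
        self.start0 = np.array(starts, dtype=np.int64)
        self.end0 = np.array(ends, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.start0)

    @property
    def windows(self) -> list[tuple[str, int, int]]:
        return list(zip(self.chrom, self.start0.tolist(), self.end0.tolist()))

    def assign(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Global window index for each 1-based position (-1 = off-genome).

        A SNP at 1-based position p belongs to window ``(p - 1) // step``
        of its chromosome: position 100,000 falls in the first window,
        100,001 in the second.  Requires ``step == size`` (non-overlapping
        tiling) so that the assignment is unique.
        """
        if self.step != self.size:
            raise ValueError("assignment requires non-overlapping windows")
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), -1, dtype=np.int64)
        for c in pd.unique(chrom):
            if c not in self._offset:
                continue
            m = chrom == c
            local = (pos[m] - 1) // self.step
            n_local = -(-self.chrom_lengths[c] // self.step)
            ok = (pos[m] >= 1) & (local < n_local)
            idx = np.where(ok, self._offset[c] + local, -1)
            out[m] = idx
        return out

    def label(self, i: int) -> str:
        """1-based inclusive window label, e.g. ``'1:170300001:170400000'``."""
        return f"{self.chrom[i]}:{self.start0[i] + 1}:{self.end0[i]}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start0": self.start0,
                             "end0": self.end0})


def make_windows(chrom_lengths: Mapping[str, int],
                 size: int = 100_000, step: int = 100_000) -> GenomeWindows:
    """Tile chromosomes into windows (see :class:`GenomeWindows`)."""
    return GenomeWindows(chrom_lengths, size=size, step=step)


def window_size_diagnostic(
    table: VariantTable,
    chrom_lengths: Mapping[str, int],
    sizes: Sequence[int] = tuple(range(50_000, 300_001, 50_000)),
    min_snps: int = 10,
) -> dict[int, int]:
    """Count sparse windows (< ``min_snps`` SNPs) for each candidate size.

    The window size for the scans is chosen where this count starts to
    flatten out; it is non-increasing in the window size.
    """
    if len(table) == 0:
        raise ValueError("empty variant table")
    out = {}
    for size in sizes:
        gw = GenomeWindows(chrom_lengths, size=size, step=size)
        w = gw.assign(table.sites["chrom"].to_numpy(), table.sites["pos"].to_numpy())
        counts = np.bincount(w[w >= 0], minlength=len(gw))
        out[size] = int((counts < min_snps).sum())
    return out


# ---------------------------------------------------------------------------
# Pooled heterozygosity
# ---------------------------------------------------------------------------

def hp_window(ref_reads: np.ndarray, alt_reads: np.ndarray) -> float:
    """H_P of one window from one pool's per-SNP ref/alt read counts.

    Per SNP the major allele is whichever has more reads in this pool
    (ties contribute equally to both sums, so the split is irrelevant);
    ``H_P = 2 * SumMaj * SumMin / (SumMaj + SumMin)^2`` lies in [0, 0.5]
    and is NaN when the window has zero total depth.
    """
    ref = np.asarray(ref_reads, dtype=float)
    alt = np.asarray(alt_reads, dtype=float)
    smaj = float(np.maximum(ref, alt).sum())
    smin = float(np.minimum(ref, alt).sum())
    tot = smaj + smin
    if tot == 0:
        return float("nan")
    return 2.0 * smaj * smin / tot**2


def hp_transform(hp: float | np.ndarray):
    """log2 transform of raw H_P; 0 maps to NaN (window later discarded).

    Raises ``ValueError`` on negative input.
    """
    hp = np.asarray(hp, dtype=float)
    if np.any(hp < 0):
        raise ValueError("H_P must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.where(hp > 0, np.log2(np.where(hp > 0, hp, 1.0)), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class WindowTrack:
    """Per-window values of one statistic for one breed or contrast.

    ``values`` is NaN where the statistic is undefined; ``retained``
    marks windows that survive the sparse-window / incomputable filter
    (defined value and >= 20 SNPs by default).  F_ST values lie in
    [-1, 1]; raw H_P in [0, 0.5].
    """

    name: str
    statistic: str  # "HP", "HP_LOG2" or "FST"
    windows: GenomeWindows
    values: np.ndarray
    n_snps: np.ndarray
    retained: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.windows)
        assert self.values.shape == (n,) and self.n_snps.shape == (n,)
        # a retained window always has a defined value
        assert not np.any(self.retained & np.isnan(self.values))

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def mean(self) -> float:
        """Mean of the statistic over retained windows (breed-level scalar)."""
        return float(np.nanmean(self.values[self.retained]))

    def log2(self) -> "WindowTrack":
        """log2-transformed H_P track; zero-H_P windows become unretained."""
        if self.statistic != "HP":
            raise ValueError("log2 transform applies to raw HP tracks")
        vals = hp_transform(self.values)
        retained = self.retained & ~np.isnan(vals)
        return WindowTrack(self.name, "HP_LOG2", self.windows, vals,
                           self.n_snps, retained)

    def to_frame(self) -> pd.DataFrame:
        df = self.windows.to_frame()
        df["name"] = self.name
        df["value"] = self.values
        df["n_snps"] = self.n_snps
        df["retained"] = self.retained
        return df

    def to_manhattan_frame(self) -> pd.DataFrame:
        """Plot-ready frame: chrom, window midpoint (1-based), value."""
        mid = (self.windows.start0 + self.windows.end0) // 2 + 1
        return pd.DataFrame({"chrom": self.windows.chrom, "midpoint": mid,
                             "value": self.values})[self.retained]


def _window_sums(values: np.ndarray, widx: np.ndarray, n_windows: int) -> np.ndarray:
    ok = widx >= 0
    return np.bincount(widx[ok], weights=values[ok], minlength=n_windows)


def hp_track(
    table: VariantTable,
    windows: GenomeWindows,
    pool: str,
    min_snps: int = MIN_SNPS_PER_WINDOW,
) -> WindowTrack:
    """Raw H_P per window for one pool (vectorised over the genome)."""
    j = table.panel.index(pool)
    widx = windows.assign(table.sites["chrom"].to_numpy(),
                          table.sites["pos"].to_numpy())
    ref = table.ref_reads[:, j].astype(float)
    alt = table.alt_reads[:, j].astype(float)
    n = len(windows)
    smaj = _window_sums(np.maximum(ref, alt), widx, n)
    smin = _window_sums(np.minimum(ref, alt), widx, n)
    tot = smaj + smin
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = np.where(tot > 0, 2.0 * smaj * smin / np.maximum(tot, 1) ** 2, np.nan)
    n_snps = np.bincount(widx[widx >= 0], minlength=n)
    retained = (n_snps >= min_snps) & ~np.isnan(hp)
    return WindowTrack(pool, "HP", windows, hp, n_snps, retained)


# ---------------------------------------------------------------------------
# Karlsson per-SNP F_ST
# ---------------------------------------------------------------------------

def fst_snp_karlsson(a1, n1, a2, n2):
    """Karlsson et al. unbiased per-SNP F_ST between two pools.

    With ``a_i`` alternative-allele counts out of ``n_i`` sampled alleles
    (here: reads), ``p_i = a_i / n_i`` and the unbiased within-pool
    heterozygosity ``h_i = 2 a_i (n_i - a_i) / (n_i (n_i - 1))``:

        N = (p1 - p2)^2 - h1/n1 - h2/n2
        D = N + h1 + h2
        F = N / D

    Returns ``(N, D, F)``; F is NaN where D == 0 (both pools fixed for
    the same allele) or where either ``n_i < 2``.  Symmetric in the two
    pools; slightly negative under identical frequencies (the unbiased
    estimator's -h/(nD) finite-sample term).  Accepts scalars or arrays.
    """
    a1 = np.asarray(a1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    valid = (n1 >= 2) & (n2 >= 2)
    n1s = np.where(valid, n1, 2.0)
    n2s = np.where(valid, n2, 2.0)
    p1 = a1 / n1s
    p2 = a2 / n2s
    h1 = 2.0 * a1 * (n1s - a1) / (n1s * (n1s - 1.0))
    h2 = 2.0 * a2 * (n2s - a2) / (n2s * (n2s - 1.0))
    N = (p1 - p2) ** 2 - h1 / n1s - h2 / n2s
    D = N + h1 + h2
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(valid & (D != 0), N / np.where(D != 0, D, 1.0), np.nan)
    N = np.where(valid, N, np.nan)
    D = np.where(valid, D, np.nan)
    if F.ndim == 0:
        return float(N), float(D), float(F)
    return N, D, F


def fst_window(fs: np.ndarray, n: np.ndarray | None = None,
               d: np.ndarray | None = None, mode: str = "mean") -> float:
    """Window F_ST from per-SNP values: mean of defined F (default).

    ``mode="ratio"`` uses Karlsson's ratio-of-sums ``sum(N)/sum(D)``
    over SNPs with defined F instead.  NaN when no SNP qualifies.
    """
    fs = np.asarray(fs, dtype=float)
    ok = ~np.isnan(fs)
    if not ok.any():
        return float("nan")
    if mode == "mean":
        return float(fs[ok].mean())
    if mode == "ratio":
        if n is None or d is None:
            raise ValueError("ratio mode needs per-SNP N and D")
        return float(np.asarray(n)[ok].sum() / np.asarray(d)[ok].sum())
    raise ValueError(f"unknown mode {mode!r}")


def _fst_window_values(
    a1, n1, a2, n2, widx, n_windows, mode: str = "mean"
) -> np.ndarray:
    """Per-window F_ST (vectorised) from per-SNP counts of two (super-)pools."""
    N, D, F = fst_snp_karlsson(a1, n1, a2, n2)
    ok = ~np.isnan(F) & (widx >= 0)
    n_def = np.bincount(widx[ok], minlength=n_windows)
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "mean":
            s = np.bincount(widx[ok], weights=F[ok], minlength=n_windows)
            vals = np.where(n_def > 0, s / np.maximum(n_def, 1), np.nan)
        elif mode == "ratio":
            sn = np.bincount(widx[ok], weights=N[ok], minlength=n_windows)
            sd = np.bincount(widx[ok], weights=D[ok], minlength=n_windows)
            vals = np.where((n_def > 0) & (sd != 0),
                            sn / np.where(sd != 0, sd, 1.0), np.nan)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return vals


def fst_track(
    table: VariantTable,
    windows: GenomeWindows,
    pool_a: str,
    pool_b: str,
    min_snps: int = MIN_SNPS_PER_WINDOW,
    mode: str = "mean",
) -> WindowTrack:
    """Pairwise window F_ST track between two pools."""
    ja, jb = table.panel.index(pool_a), table.panel.index(pool_b)
    widx = windows.assign(table.sites["chrom"].to_numpy(),
                          table.sites["pos"].to_numpy())
    depth = table.depth()
    vals = _fst_window_values(
        table.alt_reads[:, ja], depth[:, ja],
        table.alt_reads[:, jb], depth[:, jb],
        widx, len(windows), mode=mode,
    )
    n_snps = np.bincount(widx[widx >= 0], minlength=len(windows))
    retained = (n_snps >= min_snps) & ~np.isnan(vals)
    return WindowTrack(f"{pool_a}~{pool_b}", "FST", windows, vals, n_snps, retained)


def single_breed_fst(
    table: VariantTable,
    windows: GenomeWindows,
    breed: str,
    others: Sequence[str] | None = None,
    min_snps: int = MIN_SNPS_PER_WINDOW,
    mode: str = "mean",
) -> tuple[WindowTrack, float]:
    """Averaged F_ST of one breed against each of the others.

    Per window, the mean of the pairwise window F_ST across the N - 1
    comparisons (pairs with an undefined window value are skipped); the
    breed-level scalar is the mean over retained windows.  ``others``
    defaults to every other pool in the panel.
    """
    if others is None:
        others = [n for n in table.panel.names if n != breed]
    others = list(others)
    if breed in others:
        raise ValueError("breed must be excluded from others")
    if not others:
        raise ValueError("empty comparison set")
    widx = windows.assign(table.sites["chrom"].to_numpy(),
                          table.sites["pos"].to_numpy())
    depth = table.depth()
    jb = table.panel.index(breed)
    acc = np.zeros(len(windows))
    n_def = np.zeros(len(windows), dtype=np.int64)
    for other in others:
        jo = table.panel.index(other)
        vals = _fst_window_values(
            table.alt_reads[:, jb], depth[:, jb],
            table.alt_reads[:, jo], depth[:, jo],
            widx, len(windows), mode=mode,
        )
        ok = ~np.isnan(vals)
        acc[ok] += vals[ok]
        n_def += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_vals = np.where(n_def > 0, acc / np.maximum(n_def, 1), np.nan)
    n_snps = np.bincount(widx[widx >= 0], minlength=len(windows))
    retained = (n_snps >= min_snps) & ~np.isnan(mean_vals)
    track = WindowTrack(breed, "FST", windows, mean_vals, n_snps, retained)
    return track, track.mean()


@dataclass(frozen=True)
class ContrastSpec:
    """Two disjoint groups of pools to compare as super-pools."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.label!r}: both groups non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.label!r}: groups must be disjoint")


def group_fst(
    table: VariantTable,
    windows: GenomeWindows,
    contrast: ContrastSpec,
    min_snps: int = MIN_SNPS_PER_WINDOW,
    mode: str = "mean",
    pooling: str = "sum",
) -> WindowTrack:
    """Window F_ST between two groups of pools.

    With ``pooling="sum"`` (default) each group's ref/alt read counts are
    summed into a super-pool at every SNP, preserving depth weighting;
    ``pooling="avg"`` instead averages the per-pool allele frequencies
    (equal pool weights) and carries the summed depth as sample size.
    A contrast of two single-pool groups reduces exactly to the pairwise
    track.
    """
    ia = [table.panel.index(p) for p in contrast.group_a]
    ib = [table.panel.index(p) for p in contrast.group_b]
    widx = windows.assign(table.sites["chrom"].to_numpy(),
                          table.sites["pos"].to_numpy())
    depth = table.depth()

    def super_pool(idx):
        n = depth[:, idx].sum(axis=1).astype(float)
        if pooling == "sum":
            a = table.alt_reads[:, idx].sum(axis=1).astype(float)
        elif pooling == "avg":
            af = table.af()[:, idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = np.nanmean(af, axis=1)
            a = np.where(np.isnan(p), 0.0, p) * n
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        return a, n

    a1, n1 = super_pool(ia)
    a2, n2 = super_pool(ib)
    vals = _fst_window_values(a1, n1, a2, n2, widx, len(windows), mode=mode)
    n_snps = np.bincount(widx[widx >= 0], minlength=len(windows))
    retained = (n_snps >= min_snps) & ~np.isnan(vals)
    return WindowTrack(contrast.label, "FST", windows, vals, n_snps, retained)


# ---------------------------------------------------------------------------
# Percentile outliers
# ---------------------------------------------------------------------------

@dataclass
class OutlierSet:
    """Windows beyond the percentile threshold of one track's tail."""

    label: str
    percentile: float
    tail: str  # "upper" or "lower"
    windows: np.ndarray  # global window indices, genomic order
    threshold_value: float
    track: WindowTrack = field(repr=False)

    def __len__(self) -> int:
        return len(self.windows)

    def window_labels(self) -> list[str]:
        return [self.track.windows.label(int(i)) for i in self.windows]

    def to_bed_frame(self) -> pd.DataFrame:
        gw = self.track.windows
        idx = self.windows
        return pd.DataFrame({
            "chrom": gw.chrom[idx], "start0": gw.start0[idx],
            "end0": gw.end0[idx], "name": self.label,
            "value": self.track.values[idx],
        })


def call_outliers(
    track: WindowTrack,
    percentile: float = 99.95,
    tail: str | None = None,
    k: int | None = None,
) -> OutlierSet:
    """Select the ``round((1 - percentile/100) * N_retained)`` extreme windows.

    ``tail`` defaults by statistic: lower for H_P (sweeps deplete
    heterozygosity), upper for F_ST.  Ties at the threshold are broken by
    genomic order so the selected set is a deterministic function of the
    track; an explicit ``k`` overrides the percentile count (used when
    benchmarking against a known number of planted sweeps).  Percentile
    selection is monotone-invariant, so raw and log2 H_P give the same
    windows.
    """
    if tail is None:
        tail = "lower" if track.statistic.startswith("HP") else "upper"
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    if track.n_retained == 0:
        raise ValueError("track has no retained window")
    if k is None:
        k = int(np.floor((1.0 - percentile / 100.0) * track.n_retained + 0.5))
    if k == 0:
        warnings.warn("percentile rule selects 0 windows", stacklevel=2)
    idx = np.flatnonzero(track.retained)
    vals = track.values[idx]
    sign = -1.0 if tail == "upper" else 1.0
    order = np.lexsort((idx, sign * vals))  # extreme first, ties by genome order
    chosen = idx[order[:k]]
    threshold = float(track.values[chosen[-1]]) if k > 0 else float("nan")
    return OutlierSet(
        label=track.name, percentile=percentile, tail=tail,
        windows=np.sort(chosen), threshold_value=threshold, track=track,
    )
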