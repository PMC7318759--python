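"""Data model for pooled-sequencing variant panels and VCF/TSV input-output.

A *pool* is a single sequencing library made from the pooled DNA of many
individuals of one breed or population; allele frequencies are estimated
from per-pool read counts rather than genotypes.  The central container,
:class:`VariantTable`, stores bi-allelic SNP sites as column arrays (one
row per site, one pair of ref/alt read-count columns per pool) so that the
window statistics downstream can operate on whole chromosomes at once.

Coordinate conventions: VCF positions are 1-based; every internal interval
computation (window assignment, gene overlap) uses 0-based half-open
coordinates, converted at I/O boundaries only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "PoolSample",
    "PoolPanel",
    "VariantSite",
    "VariantTable",
    "read_pool_vcf",
    "write_pool_vcf",
    "read_panel_tsv",
    "write_panel_tsv",
    "estimate_af",
    "genotype_known_sites",
]


@dataclass(frozen=True)
class PoolSample:
    """One DNA pool: a named population sample of pooled individuals.

    Parameters
    ----------
    name : str
        Unique pool identifier within a panel.
    n_individuals : int
        Number of individuals in the pool (30-35 in typical designs);
        together with ``ploidy`` it sets the minor-allele detection limit
        ``1 / (ploidy * n_individuals)``.
    ploidy : int
        Ploidy of the organism (2 for pigs).
    group_labels : mapping
        Grouping-scheme -> label assignments (e.g. ``{"coat": "black",
        "size": "large", "type": "commercial"}``) used for group contrasts.
    longitude, latitude : float, optional
        Sampling coordinates in decimal degrees, used for the Mantel test.
    """

    name: str
    n_individuals: int
    ploidy: int = 2
    group_labels: Mapping[str, str] = field(default_factory=dict)
    longitude: float | None = None
    latitude: float | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError(f"pool {self.name!r}: n_individuals must be >= 1")
        if self.ploidy < 1:
            raise ValueError(f"pool {self.name!r}: ploidy must be >= 1")

    @property
    def n_chromosomes(self) -> int:
        """Number of chromosome copies pooled (ploidy * individuals)."""
        return self.ploidy * self.n_individuals


class PoolPanel:
    """Ordered collection of :class:`PoolSample` with an optional wild pool.

    The wild pool (e.g. a wild-boar outgroup) is singled out because the
    ancestral-allele assignment and the wild-vs-domestic contrasts treat
    it asymmetrically.
    """

    def __init__(self, pools: Sequence[PoolSample], wild_pool: str | None = None):
        pools = list(pools)
        if len(pools) < 2:
            raise ValueError("a panel needs at least 2 pools")
        names = [p.name for p in pools]
        if len(set(names)) != len(names):
            raise ValueError("duplicate pool names in panel")
        if wild_pool is not None and wild_pool not in names:
            raise ValueError(f"wild_pool {wild_pool!r} is not a panel member")
        self.pools: list[PoolSample] = pools
        self.wild_pool = wild_pool
        self._index = {n: i for i, n in enumerate(names)}

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pools]

    def __len__(self) -> int:
        return len(self.pools)

    def __iter__(self):
        return iter(self.pools)

    def __getitem__(self, name: str) -> PoolSample:
        return self.pools[self.index(name)]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown pool {name!r}") from None

    def domestic_names(self) -> list[str]:
        """All pool names except the wild pool (all names if none is set)."""
        return [n for n in self.names if n != self.wild_pool]

    def group(self, scheme: str, label: str) -> list[str]:
        """Pool names carrying ``label`` under grouping ``scheme``."""
        return [p.name for p in self.pools if p.group_labels.get(scheme) == label]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PoolPanel):
            return NotImplemented
        return self.pools == other.pools and self.wild_pool == other.wild_pool

    def __repr__(self) -> str:
        return f"PoolPanel({len(self)} pools, wild={self.wild_pool!r})"


@dataclass(frozen=True)
class VariantSite:
    """A single bi-allelic SNP with per-pool read counts.

    ``counts`` maps pool name -> (ref_reads, alt_reads).  ``quality`` is
    the caller's site quality score, consumed as an input.  ``in_catalogue``
    flags membership in an external variant catalogue (dbSNP-style).
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    quality: float
    in_catalogue: bool
    counts: Mapping[str, tuple[int, int]]
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for pool, (r, a) in self.counts.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative read count for pool {pool!r}")

    def depth(self, pool: str) -> int:
        r, a = self.counts[pool]
        return r + a


class VariantTable:
    """Sorted, de-duplicated table of bi-allelic SNPs over a pool panel.

    Stored column-wise: ``sites`` is a DataFrame with columns
    ``chrom, pos, ref, alt, qual, in_catalogue, flags`` (``flags`` holds
    frozensets), and ``ref_reads`` / ``alt_reads`` are ``(n_sites,
    n_pools)`` integer arrays in panel pool order.  ``wild_af`` (optional,
    NaN = undefined) carries wild-pool allele frequencies attached by
    :func:`genotype_known_sites`.
    """

    SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "qual", "in_catalogue", "flags")

    def __init__(
        self,
        panel: PoolPanel,
        sites: pd.DataFrame,
        ref_reads: np.ndarray,
        alt_reads: np.ndarray,
        wild_af: np.ndarray | None = None,
    ):
        sites = sites.reset_index(drop=True)
        ref_reads = np.asarray(ref_reads, dtype=np.int64)
        alt_reads = np.asarray(alt_reads, dtype=np.int64)
        n = len(sites)
        if ref_reads.shape != (n, len(panel)) or alt_reads.shape != (n, len(panel)):
            raise ValueError("count arrays must be (n_sites, n_pools)")
        if (ref_reads < 0).any() or (alt_reads < 0).any():
            raise ValueError("read counts must be non-negative")
        if (sites["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")
        if (sites["ref"] == sites["alt"]).any():
            raise ValueError("ref and alt alleles must differ")

        order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
        sites = sites.iloc[order].reset_index(drop=True)
        ref_reads = ref_reads[order]
        alt_reads = alt_reads[order]
        if wild_af is not None:
            wild_af = np.asarray(wild_af, dtype=float)[order]

        dup = sites.duplicated(subset=["chrom", "pos", "ref", "alt"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (chrom, pos, ref, alt) records"
            )

        self.panel = panel
        self.sites = sites
        self.ref_reads = ref_reads
        self.alt_reads = alt_reads
        self.wild_af = wild_af

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_sites(cls, panel: PoolPanel, sites: Iterable[VariantSite]) -> "VariantTable":
        rows, refs, alts = [], [], []
        for s in sites:
            rows.append(
                (s.chrom, s.pos, s.ref_allele, s.alt_allele, s.quality,
                 s.in_catalogue, frozenset(s.flags))
            )
            refs.append([s.counts[n][0] for n in panel.names])
            alts.append([s.counts[n][1] for n in panel.names])
        df = pd.DataFrame(rows, columns=cls.SITE_COLUMNS)
        shape = (len(rows), len(panel))
        return cls(
            panel, df,
            np.array(refs, dtype=np.int64).reshape(shape),
            np.array(alts, dtype=np.int64).reshape(shape),
        )

    # -- basic protocol ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site(self, i: int) -> VariantSite:
        row = self.sites.iloc[i]
        counts = {
            name: (int(self.ref_reads[i, j]), int(self.alt_reads[i, j]))
            for j, name in enumerate(self.panel.names)
        }
        return VariantSite(
            chrom=row["chrom"], pos=int(row["pos"]),
            ref_allele=row["ref"], alt_allele=row["alt"],
            quality=float(row["qual"]), in_catalogue=bool(row["in_catalogue"]),
            counts=counts, flags=frozenset(row["flags"]),
        )

    def __iter__(self):
        return (self.site(i) for i in range(len(self)))

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            self.panel,
            self.sites.loc[mask],
            self.ref_reads[mask],
            self.alt_reads[mask],
            None if self.wild_af is None else self.wild_af[mask],
        )

    # -- derived quantities --------------------------------------------------

    def depth(self) -> np.ndarray:
        """(n_sites, n_pools) total read depth per site and pool."""
        return self.ref_reads + self.alt_reads

    def af(self) -> np.ndarray:
        """Per-pool alternative-allele frequency; NaN where depth is zero."""
        depth = self.depth()
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(depth > 0, self.alt_reads / np.maximum(depth, 1), np.nan)
        return out

    def pooled_af(self) -> np.ndarray:
        """Panel-wide AF: total alt reads / total reads; NaN at zero depth."""
        alt = self.alt_reads.sum(axis=1).astype(float)
        tot = self.depth().sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        same_sites = (
            self.sites[["chrom", "pos", "ref", "alt", "in_catalogue"]].equals(
                other.sites[["chrom", "pos", "ref", "alt", "in_catalogue"]]
            )
            and np.allclose(self.sites["qual"], other.sites["qual"], atol=1e-4)
            and list(self.sites["flags"]) == list(other.sites["flags"])
        )
        return (
            same_sites
            and self.panel.names == other.panel.names
            and np.array_equal(self.ref_reads, other.ref_reads)
            and np.array_equal(self.alt_reads, other.alt_reads)
        )

    def __repr__(self) -> str:
        return f"VariantTable({self.n_sites} sites x {len(self.panel)} pools)"


# ---------------------------------------------------------------------------
# Allele-frequency estimation
# ---------------------------------------------------------------------------

def estimate_af(site: VariantSite, pool: str) -> float:
    """Read-count AF of the alternative allele in one pool.

    Returns ``alt / (ref + alt)``; NaN (a distinct "undefined" sentinel,
    never 0.0) when the pool has zero depth at the site.
    """
    ref, alt = site.counts[pool]  # KeyError on unknown pool
    depth = ref + alt
    if depth == 0:
        return float("nan")
    return alt / depth


def genotype_known_sites(
    table: VariantTable,
    wild_counts: Mapping[tuple[str, int, str, str], tuple[int, int]],
    rd_min: int = 3,
) -> VariantTable:
    """Attach wild-pool allele frequencies at already-ascertained sites.

    Mirrors genotyping a low-coverage outgroup pool only at the sites
    discovered in the main panel: sites with wild depth below ``rd_min``
    (default 3) get an undefined (NaN) wild AF, never zero.  Keys in
    ``wild_counts`` that match no table site are reported via a warning,
    not silently dropped; table sites absent from ``wild_counts`` are
    retained with undefined wild AF.
    """
    keys = list(zip(table.sites["chrom"], table.sites["pos"].astype(int),
                    table.sites["ref"], table.sites["alt"]))
    key_set = set(keys)
    unmatched = [k for k in wild_counts if k not in key_set]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} wild-count keys match no table site "
            f"(first: {unmatched[0]})", stacklevel=2,
        )
    wild_af = np.full(len(table), np.nan)
    for i, k in enumerate(keys):
        if k in wild_counts:
            r, a = wild_counts[k]
            if r + a >= rd_min:
                wild_af[i] = a / (r + a)
    return VariantTable(table.panel, table.sites, table.ref_reads,
                        table.alt_reads, wild_af)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_FLAGS_INFO = "VFLAGS"


def read_pool_vcf(
    path: str, panel: PoolPanel, multiallelic: str = "drop"
) -> VariantTable:
    """Read a multi-sample VCF with per-pool AD fields into a VariantTable.

    One VCF sample column per pool, carrying allelic depths in FORMAT/AD.
    ``multiallelic`` is ``"drop"`` (default; keep bi-allelic records only)
    or ``"split"`` (one bi-allelic row per alternative allele, ref reads
    taken as the reference AD).

    Raises ``ValueError`` if a panel pool has no sample column, or on a
    malformed AD field (with the offending locus in the message).
    """
    if multiallelic not in ("drop", "split"):
        raise ValueError("multiallelic must be 'drop' or 'split'")
    rows, refs, alts = [], [], []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        missing = [n for n in panel.names if n not in samples]
        if missing:
            raise ValueError(f"VCF is missing sample(s) for pool(s): {missing}")
        has_flags = _FLAGS_INFO in vf.header.info
        has_db = "DB" in vf.header.info
        for rec in vf:
            alleles = rec.alleles
            if alleles is None or len(alleles) < 2:
                continue
            n_alt = len(alleles) - 1
            if n_alt > 1 and multiallelic == "drop":
                continue
            ads = {}
            for name in panel.names:
                ad = rec.samples[name].get("AD")
                if ad is None or len(ad) != n_alt + 1 or any(x is None for x in ad):
                    raise ValueError(
                        f"malformed AD field for pool {name!r} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                ads[name] = ad
            flags = frozenset(rec.info.get(_FLAGS_INFO, ()) or ()) if has_flags \
                else frozenset()
            in_cat = bool(rec.info.get("DB", False)) if has_db else False
            qual = float(rec.qual) if rec.qual is not None else 0.0
            for ai in range(1, n_alt + 1):
                alt = alleles[ai]
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue  # SNPs only
                rows.append((rec.chrom, rec.pos, rec.ref, alt, qual, in_cat, flags))
                refs.append([ads[n][0] for n in panel.names])
                alts.append([ads[n][ai] for n in panel.names])
    df = pd.DataFrame(rows, columns=VariantTable.SITE_COLUMNS)
    shape = (len(rows), len(panel))
    return VariantTable(
        panel, df,
        np.array(refs, dtype=np.int64).reshape(shape),
        np.array(alts, dtype=np.int64).reshape(shape),
    )


def write_pool_vcf(
    table: VariantTable, path: str, chrom_lengths: Mapping[str, int] | None = None
) -> None:
    """Write a VariantTable as a VCF 4.2 file (lossless round trip).

    Per-pool counts go to FORMAT/AD, the caller quality to QUAL, catalogue
    membership to INFO/DB and site flags to INFO/VFLAGS.
    """
    header = pysam.VariantHeader()
    chroms = dict(chrom_lengths or {})
    for c in pd.unique(table.sites["chrom"]):
        if c not in chroms:
            # contig length must exceed every position; exact length unknown
            max_pos = int(table.sites.loc[table.sites["chrom"] == c, "pos"].max())
            chroms[c] = max_pos + 1
    for c, ln in chroms.items():
        header.contigs.add(str(c), length=int(ln))
    header.add_meta("INFO", items=[("ID", "DB"), ("Number", "0"), ("Type", "Flag"),
                                   ("Description", "Variant-catalogue membership")])
    header.add_meta("INFO", items=[("ID", _FLAGS_INFO), ("Number", "."),
                                   ("Type", "String"),
                                   ("Description", "Site-level QC flags")])
    header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"),
                                     ("Type", "Integer"),
                                     ("Description", "Ref,alt read depths")])
    for name in table.panel.names:
        header.add_sample(name)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for i in range(len(table)):
            row = table.sites.iloc[i]
            rec = vf.new_record(
                contig=str(row["chrom"]), start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]), qual=float(row["qual"]),
            )
            if row["in_catalogue"]:
                rec.info["DB"] = True
            if row["flags"]:
                rec.info[_FLAGS_INFO] = tuple(sorted(row["flags"]))
            for j, name in enumerate(table.panel.names):
                rec.samples[name]["AD"] = (
                    int(table.ref_reads[i, j]), int(table.alt_reads[i, j])
                )
            vf.write(rec)


# ---------------------------------------------------------------------------
# Panel and count-matrix TSV
# ---------------------------------------------------------------------------

def write_panel_tsv(panel: PoolPanel, path: str) -> None:
    """Panel metadata as TSV: name, n_individuals, ploidy, groups, coords."""
    schemes = sorted({s for p in panel for s in p.group_labels})
    rows = []
    for p in panel:
        row = {
            "name": p.name, "n_individuals": p.n_individuals, "ploidy": p.ploidy,
            "is_wild": int(p.name == panel.wild_pool),
            "longitude": p.longitude, "latitude": p.latitude,
        }
        for s in schemes:
            row[f"group_{s}"] = p.group_labels.get(s, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str) -> PoolPanel:
    df = pd.read_csv(path, sep="\t")
    schemes = [c[len("group_"):] for c in df.columns if c.startswith("group_")]
    pools, wild = [], None
    for _, r in df.iterrows():
        labels = {s: r[f"group_{s}"] for s in schemes
                  if isinstance(r[f"group_{s}"], str) and r[f"group_{s}"]}
        lon = None if pd.isna(r.get("longitude")) else float(r["longitude"])
        lat = None if pd.isna(r.get("latitude")) else float(r["latitude"])
        pools.append(PoolSample(str(r["name"]), int(r["n_individuals"]),
                                int(r["ploidy"]), labels, lon, lat))
        if int(r.get("is_wild", 0)):
            wild = str(r["name"])
    return PoolPanel(pools, wild_pool=wild)


def write_counts_tsv(table: VariantTable, path: str) -> None:
    """Allele-count matrix as TSV: site columns then ref/alt pairs per pool."""
    df = table.sites[["chrom", "pos", "ref", "alt", "qual", "in_catalogue"]].copy()
    for j, name in enumerate(table.panel.names):
        df[f"{name}_ref"] = table.ref_reads[:, j]
        df[f"{name}_alt"] = table.alt_reads[:, j]
    df.to_csv(path, sep="\t", index=False)
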