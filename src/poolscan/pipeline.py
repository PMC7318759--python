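"""End-to-end orchestration of the selection-signature pipeline.

Stages (each re-runnable on its own from its predecessors' on-disk
outputs): simulate -> filter -> windows -> scan-hp -> scan-fst ->
contrasts -> outliers -> annotate -> tree -> mantel -> enrich ->
deleterious.  Every stage writes plain-text outputs (VCF/TSV/BED/
Newick/JSON) into the run directory and registers them, with SHA-256
hashes and the parameters used, in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from . import downstream, qc, regions, simulate, structure, windows as ws
from .variants import (PoolPanel, VariantTable, read_panel_tsv, read_pool_vcf,
                       write_panel_tsv, write_pool_vcf)

log = logging.getLogger("poolscan")

__all__ = ["RunConfig", "run_pipeline", "STAGES"]


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run (YAML-loadable).

    Every analysis threshold surfaces as a named key with its standard
    default: depth bounds 10/68 (the latter from mean depth 42), 3 alt
    reads, rarity limit 0.0143, quality grid 0-50, 100-kb windows,
    20-SNP window floor, 99.95th percentile, ±200-kb flanks, 500-kb
    concordance, enrichment 4 genes / 2 windows / 0.05, ancestral-allele
    0.5, frequency contrast 0.8/0.2.
    """

    outdir: str = "poolscan_run"
    seed: int = 0
    # inputs (ignored when simulate=True: the simulate stage writes them)
    vcf: str | None = None
    panel: str | None = None
    genes: str | None = None           # GFF3 or BED
    gene_sets: str | None = None       # GMT
    impact: str | None = None          # TSV
    simulate: bool = True
    sim: dict = field(default_factory=dict)   # SimConfig overrides
    # filtering
    rd_min: int = 10
    min_alt_reads_total: int = 3
    rd_mean: float = 42.0
    rd_max: int | None = None
    maf_rare_limit: float | None = None  # derived from pool size when None
    q_grid_max: int = 50
    excluded_chroms: tuple[str, ...] = ()
    apply_quality_cutoff: bool = True
    # windows & scans
    window_size: int = 100_000
    window_step: int = 100_000
    min_snps_per_window: int = 20
    percentile: float = 99.95
    fst_mode: str = "mean"            # or "ratio" (ratio-of-sums)
    group_pooling: str = "sum"        # or "avg"
    contrasts: tuple[dict, ...] = ()  # {label, group_a: [...], group_b: [...]}
    contrast_schemes: tuple[str, ...] = ()  # auto contrasts per group scheme
    # regions / downstream
    flank: int = 200_000
    concordance_distance: int = 500_000
    merge_max_gap: int = 0
    enrich_min_genes: int = 4
    enrich_min_windows: int = 2
    enrich_alpha: float = 0.05
    universe_size: int | None = None
    af_hi: float = 0.8
    af_lo: float = 0.2
    # structure
    n_bootstrap: int = 1000
    n_mantel_perm: int = 9_999
    local_only_mantel: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("contrasts", "contrast_schemes", "excluded_chroms"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def out(self, *parts: str) -> Path:
        p = Path(self.outdir).joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def validate(self) -> None:
        if not self.simulate:
            for key in ("vcf", "panel"):
                path = getattr(self, key)
                if path is None or not Path(path).exists():
                    raise ValueError(f"config {key!r}: missing input file {path!r}")
        if self.fst_mode not in ("mean", "ratio"):
            raise ValueError("fst_mode must be 'mean' or 'ratio'")
        if self.group_pooling not in ("sum", "avg"):
            raise ValueError("group_pooling must be 'sum' or 'avg'")


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _register(cfg: RunConfig, stage: str, outputs: Sequence[Path],
              params: Mapping | None = None) -> None:
    mpath = cfg.out("manifest.json")
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
    manifest[stage] = {
        "outputs": {str(p.relative_to(cfg.outdir)): _sha256(p) for p in outputs},
        "parameters": dict(params or {}),
    }
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# shared loaders
# ---------------------------------------------------------------------------

def _input_paths(cfg: RunConfig) -> dict[str, Path | None]:
    if cfg.simulate:
        return {
            "vcf": cfg.out("inputs", "panel.vcf"),
            "panel": cfg.out("inputs", "panel.tsv"),
            "genes": cfg.out("inputs", "genes.gff3"),
            "gene_sets": cfg.out("inputs", "gene_sets.gmt"),
            "impact": cfg.out("inputs", "impact.tsv"),
        }
    return {k: Path(v) if v else None
            for k, v in {"vcf": cfg.vcf, "panel": cfg.panel, "genes": cfg.genes,
                         "gene_sets": cfg.gene_sets, "impact": cfg.impact}.items()}


def _load_filtered(cfg: RunConfig) -> tuple[VariantTable, PoolPanel]:
    panel = read_panel_tsv(str(_input_paths(cfg)["panel"]))
    table = read_pool_vcf(str(cfg.out("filtered.vcf")), panel)
    return table, panel


def _chrom_lengths(cfg: RunConfig) -> dict[str, int]:
    return {k: int(v) for k, v in
            json.loads(cfg.out("chrom_lengths.json").read_text()).items()}


def _genome_windows(cfg: RunConfig) -> ws.GenomeWindows:
    return ws.make_windows(_chrom_lengths(cfg), cfg.window_size, cfg.window_step)


def _write_track(track: ws.WindowTrack, path: Path) -> None:
    df = track.to_frame()
    df.insert(3, "statistic", track.statistic)
    df.to_csv(path, sep="\t", index=False)


def _read_track(cfg: RunConfig, path: Path) -> ws.WindowTrack:
    df = pd.read_csv(path, sep="\t")
    gw = _genome_windows(cfg)
    if len(df) != len(gw):
        raise ValueError(f"track {path} does not match the configured windows")
    return ws.WindowTrack(
        name=str(df["name"].iloc[0]), statistic=str(df["statistic"].iloc[0]),
        windows=gw, values=df["value"].to_numpy(float),
        n_snps=df["n_snps"].to_numpy(np.int64),
        retained=df["retained"].to_numpy(bool),
    )


def _outlier_windows_from_bed(path: Path) -> list[regions.Window]:
    if not path.exists():
        return []
    df = pd.read_csv(path, sep="\t")
    return [(str(r["chrom"]), int(r["start0"]), int(r["end0"]))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> None:
    sim_kwargs = dict(cfg.sim)
    sim_kwargs.setdefault("seed", cfg.seed)
    scfg = simulate.SimConfig(**sim_kwargs)
    res = simulate.simulate_panel(scfg)
    paths = _input_paths(cfg)
    write_pool_vcf(res.table, str(paths["vcf"]), scfg.chrom_lengths)
    write_panel_tsv(res.panel, str(paths["panel"]))
    _write_gff3(res.genes, paths["genes"])
    _write_gmt(res.gene_sets, paths["gene_sets"])
    res.impact.to_csv(paths["impact"], sep="\t", index=False)
    cfg.out("chrom_lengths.json").write_text(
        json.dumps(dict(scfg.chrom_lengths)))
    truth_path = cfg.out("inputs", "truth.json")
    truth_path.write_text(json.dumps({
        "sweeps": [dataclasses.asdict(s) for s in res.truth.sweeps],
        "group_loci": [dataclasses.asdict(g) for g in res.truth.group_loci],
    }, indent=2))
    log.info("simulate: %d sites, %d pools", len(res.table), len(res.panel))
    _register(cfg, "simulate", [*filter(None, paths.values()), truth_path,
                                cfg.out("chrom_lengths.json")],
              dataclasses.asdict(scfg))


def stage_filter(cfg: RunConfig) -> None:
    paths = _input_paths(cfg)
    panel = read_panel_tsv(str(paths["panel"]))
    table = read_pool_vcf(str(paths["vcf"]), panel)
    if not cfg.out("chrom_lengths.json").exists():
        with pysam.VariantFile(str(paths["vcf"])) as vf:
            lengths = {c: vf.header.contigs[c].length for c in vf.header.contigs}
        cfg.out("chrom_lengths.json").write_text(json.dumps(lengths))

    fcfg = qc.FilterConfig(
        rd_min=cfg.rd_min, min_alt_reads_total=cfg.min_alt_reads_total,
        rd_mean=cfg.rd_mean, rd_max=cfg.rd_max,
        maf_rare_limit=cfg.maf_rare_limit or qc.maf_rare_limit(
            max(p.n_individuals for p in panel), panel.pools[0].ploidy),
        q_grid=tuple(range(0, cfg.q_grid_max + 1)),
        excluded_chroms=frozenset(cfg.excluded_chroms),
    )
    filtered, counts = qc.step1_filter(table, fcfg)
    classes, _excl = qc.classify_variants(filtered, fcfg.maf_rare_limit)
    ks_path = cfg.out("ks_diagnostics.tsv")
    selected_q = None
    rare = classes["rarity"] == "rare"
    quals = filtered.sites["qual"].to_numpy(float)[rare]
    cats = filtered.sites["in_catalogue"].to_numpy(bool)[rare]
    if cats.any() and (~cats).any():
        ksres = qc.select_quality_cutoff(quals, cats, fcfg.q_grid)
        ksres.to_frame().to_csv(ks_path, sep="\t", index=False)
        selected_q = ksres.selected_q
        if cfg.apply_quality_cutoff:
            filtered = filtered.subset(
                filtered.sites["qual"].to_numpy(float) >= selected_q)
    else:
        pd.DataFrame({"Q": [], "D": []}).to_csv(ks_path, sep="\t", index=False)
        log.info("filter: rare class too sparse for the KS cutoff; skipped")

    write_pool_vcf(filtered, str(cfg.out("filtered.vcf")), _chrom_lengths(cfg))
    qc.filter_report(counts, len(filtered)).to_csv(
        cfg.out("filter_report.tsv"), sep="\t", index=False)
    try:
        tstv = qc.ts_tv_ratio(filtered)
    except ValueError:
        tstv = float("nan")
    cfg.out("qc_summary.json").write_text(json.dumps({
        "sites_in": len(table), "sites_out": len(filtered),
        "selected_q": selected_q, "ts_tv": tstv,
    }))
    log.info("filter: %d -> %d sites (Q cutoff %s, Ts/Tv %.3f)",
             len(table), len(filtered), selected_q, tstv)
    _register(cfg, "filter",
              [cfg.out("filtered.vcf"), cfg.out("filter_report.tsv"),
               ks_path, cfg.out("qc_summary.json")],
              {"rd_min": fcfg.rd_min, "rd_max": fcfg.rd_max,
               "maf_rare_limit": fcfg.maf_rare_limit,
               "min_alt_reads_total": fcfg.min_alt_reads_total})


def stage_windows(cfg: RunConfig) -> None:
    table, _ = _load_filtered(cfg)
    diag = ws.window_size_diagnostic(table, _chrom_lengths(cfg))
    df = pd.DataFrame({"size": list(diag), "n_sparse_windows": list(diag.values())})
    df.to_csv(cfg.out("window_diagnostic.tsv"), sep="\t", index=False)
    log.info("windows: %d candidate sizes", len(df))
    _register(cfg, "windows", [cfg.out("window_diagnostic.tsv")],
              {"min_snps": 10})


def stage_scan_hp(cfg: RunConfig) -> None:
    table, panel = _load_filtered(cfg)
    gw = _genome_windows(cfg)
    outputs = []
    for pool in panel.names:
        track = ws.hp_track(table, gw, pool, cfg.min_snps_per_window).log2()
        p = cfg.out("tracks", f"hp_{pool}.tsv")
        _write_track(track, p)
        outputs.append(p)
        log.info("scan-hp %s: %d/%d windows retained", pool,
                 track.n_retained, len(gw))
    _register(cfg, "scan-hp", outputs,
              {"window_size": cfg.window_size,
               "min_snps": cfg.min_snps_per_window})


def stage_scan_fst(cfg: RunConfig) -> None:
    table, panel = _load_filtered(cfg)
    gw = _genome_windows(cfg)
    outputs, summary = [], []
    for pool in panel.names:
        track, scalar = ws.single_breed_fst(
            table, gw, pool, min_snps=cfg.min_snps_per_window, mode=cfg.fst_mode)
        p = cfg.out("tracks", f"fst_{pool}.tsv")
        _write_track(track, p)
        outputs.append(p)
        summary.append({"pool": pool, "mean_fst": scalar,
                        "n_retained": track.n_retained})
        log.info("scan-fst %s: mean F_ST %.4f", pool, scalar)
    sp = cfg.out("breed_fst_summary.tsv")
    pd.DataFrame(summary).to_csv(sp, sep="\t", index=False)
    _register(cfg, "scan-fst", outputs + [sp], {"mode": cfg.fst_mode})


def _resolve_contrasts(cfg: RunConfig, panel: PoolPanel) -> list[ws.ContrastSpec]:
    specs = []
    for c in cfg.contrasts:
        spec = ws.ContrastSpec(tuple(c["group_a"]), tuple(c["group_b"]),
                               str(c["label"]))
        for p in spec.group_a + spec.group_b:
            if p not in panel.names:
                raise ValueError(
                    f"contrast {spec.label!r} references unknown pool {p!r}")
        specs.append(spec)
    for scheme in cfg.contrast_schemes:
        labels = sorted({p.group_labels[scheme] for p in panel
                         if scheme in p.group_labels})
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                specs.append(ws.ContrastSpec(
                    tuple(panel.group(scheme, la)), tuple(panel.group(scheme, lb)),
                    f"{scheme}:{la}_vs_{lb}"))
    if panel.wild_pool:
        domestic = tuple(panel.domestic_names())
        specs.append(ws.ContrastSpec((panel.wild_pool,), domestic,
                                     "wild_vs_domestic"))
    return specs


def stage_contrasts(cfg: RunConfig) -> None:
    table, panel = _load_filtered(cfg)
    gw = _genome_windows(cfg)
    outputs = []
    for spec in _resolve_contrasts(cfg, panel):
        track = ws.group_fst(table, gw, spec, cfg.min_snps_per_window,
                             mode=cfg.fst_mode, pooling=cfg.group_pooling)
        p = cfg.out("tracks", f"contrast_{spec.label.replace(':', '_')}.tsv")
        _write_track(track, p)
        outputs.append(p)
        log.info("contrast %s: %d windows retained", spec.label, track.n_retained)
    if outputs:
        _register(cfg, "contrasts", outputs, {"pooling": cfg.group_pooling})


def stage_outliers(cfg: RunConfig) -> None:
    outputs = []
    for p in sorted(cfg.out("tracks").parent.glob("tracks/*.tsv")):
        track = _read_track(cfg, p)
        if track.n_retained == 0:
            continue
        oset = ws.call_outliers(track, percentile=cfg.percentile)
        bed = cfg.out("outliers", p.stem + ".bed")
        oset.to_bed_frame().to_csv(bed, sep="\t", index=False)
        outputs.append(bed)
        log.info("outliers %s: %d windows (%s tail)", p.stem, len(oset), oset.tail)
    _register(cfg, "outliers", outputs, {"percentile": cfg.percentile})


def stage_annotate(cfg: RunConfig) -> None:
    paths = _input_paths(cfg)
    gene_path = paths["genes"]
    genes = []
    if gene_path and Path(gene_path).exists():
        reader = (regions.read_gff3_genes if str(gene_path).endswith(("gff3", "gff"))
                  else regions.read_bed_genes)
        genes = reader(str(gene_path))
    lengths = _chrom_lengths(cfg)

    per_track: dict[str, list[regions.Window]] = {}
    for bed in sorted(cfg.out("outliers").parent.glob("outliers/*.bed")):
        per_track[bed.stem] = _outlier_windows_from_bed(bed)

    hp_sets = {k.removeprefix("hp_"): v for k, v in per_track.items()
               if k.startswith("hp_")}
    fst_sets = {k.removeprefix("fst_"): v for k, v in per_track.items()
                if k.startswith("fst_")}

    ann_rows = []
    all_windows: dict[regions.Window, set[str]] = {}
    for label, wins in per_track.items():
        for w in wins:
            all_windows.setdefault(w, set()).add(label)
            aw = regions.annotate_window(w, genes, cfg.flank,
                                         lengths.get(w[0]))
            ann_rows.append({
                "track": label, "chrom": w[0], "start0": w[1], "end0": w[2],
                "genes_within": ",".join(g.gene_name for g in aw.genes_within),
                "genes_flanking": ",".join(g.gene_name for g in aw.genes_flanking),
            })
    pd.DataFrame(
        ann_rows, columns=["track", "chrom", "start0", "end0",
                           "genes_within", "genes_flanking"]
    ).to_csv(cfg.out("annotated_windows.tsv"), sep="\t", index=False)

    shared = (regions.shared_windows(hp_sets) if len(hp_sets) >= 2 else [])
    pd.DataFrame(
        [{"chrom": w[0], "start0": w[1], "end0": w[2],
          "n_breeds": len(b), "breeds": ",".join(sorted(b))}
         for w, b in shared],
        columns=["chrom", "start0", "end0", "n_breeds", "breeds"],
    ).to_csv(cfg.out("shared_windows.tsv"), sep="\t", index=False)

    merged = regions.merge_regions(list(all_windows), cfg.merge_max_gap,
                                   all_windows)
    regions.regions_to_frame(merged).to_csv(cfg.out("regions.bed"),
                                            sep="\t", index=False)

    conc_rows = []
    for breed in set(hp_sets) & set(fst_sets):
        for hw, fw in regions.concordant_signals(
                hp_sets[breed], fst_sets[breed], cfg.concordance_distance):
            conc_rows.append({"breed": breed,
                              "hp_window": f"{hw[0]}:{hw[1]}-{hw[2]}",
                              "fst_window": f"{fw[0]}:{fw[1]}-{fw[2]}"})
    pd.DataFrame(conc_rows, columns=["breed", "hp_window", "fst_window"]
                 ).to_csv(cfg.out("concordant.tsv"), sep="\t", index=False)
    log.info("annotate: %d outlier windows, %d merged regions, %d concordant",
             len(all_windows), len(merged), len(conc_rows))
    _register(cfg, "annotate",
              [cfg.out("annotated_windows.tsv"), cfg.out("shared_windows.tsv"),
               cfg.out("regions.bed"), cfg.out("concordant.tsv")],
              {"flank": cfg.flank, "max_gap": cfg.merge_max_gap,
               "concordance_distance": cfg.concordance_distance})


def stage_tree(cfg: RunConfig) -> None:
    table, panel = _load_filtered(cfg)
    dm = structure.pairwise_fst_matrix(table, panel)
    dm.to_frame().to_csv(cfg.out("fst_matrix.tsv"), sep="\t")
    dm.to_long_frame().to_csv(cfg.out("fst_matrix_long.tsv"), sep="\t",
                              index=False)
    if len(panel) >= 3:
        tree = (structure.bootstrap_support(table, panel, cfg.n_bootstrap,
                                            seed=cfg.seed)
                if cfg.n_bootstrap > 0 else
                structure.nj_tree(dm))
        cfg.out("tree.nwk").write_text(tree.to_newick() + "\n")
    log.info("tree: %d pools, %d bootstrap replicates", len(panel),
             cfg.n_bootstrap)
    _register(cfg, "tree",
              [cfg.out("fst_matrix.tsv"), cfg.out("fst_matrix_long.tsv")]
              + ([cfg.out("tree.nwk")] if len(panel) >= 3 else []),
              {"n_bootstrap": cfg.n_bootstrap})


def stage_mantel(cfg: RunConfig) -> None:
    _, panel = _load_filtered(cfg)
    dm = structure.DistanceMatrix.from_frame(
        pd.read_csv(cfg.out("fst_matrix.tsv"), sep="\t", index_col=0))
    names = panel.domestic_names() if cfg.local_only_mantel else panel.names
    names = [n for n in names
             if panel[n].longitude is not None and panel[n].latitude is not None]
    if len(names) < 3:
        log.info("mantel: fewer than 3 pools with coordinates; skipped")
        return
    geo = structure.geographic_distances(panel, names)
    res = structure.mantel_test(dm.submatrix(names), geo,
                                n_perm=cfg.n_mantel_perm, seed=cfg.seed)
    cfg.out("mantel.json").write_text(json.dumps(
        {"r": res.r, "p": res.p, "n_perm": res.n_perm, "pools": names}))
    log.info("mantel: r = %.3f, p = %.4f", res.r, res.p)
    _register(cfg, "mantel", [cfg.out("mantel.json")],
              {"n_perm": cfg.n_mantel_perm, "local_only": cfg.local_only_mantel})


def stage_enrich(cfg: RunConfig) -> None:
    paths = _input_paths(cfg)
    gs_path = paths["gene_sets"]
    if gs_path is None or not Path(gs_path).exists():
        log.info("enrich: no gene-set collection provided; skipped")
        return
    coll = downstream.read_gmt(str(gs_path), cfg.universe_size)
    ann = pd.read_csv(cfg.out("annotated_windows.tsv"), sep="\t")
    conc = pd.read_csv(cfg.out("concordant.tsv"), sep="\t")
    rows = []
    breeds = set(conc["breed"]) if len(conc) else set()
    for breed in sorted(breeds):
        wins = set()
        for col in ("hp_window", "fst_window"):
            wins |= set(conc.loc[conc["breed"] == breed, col])
        window_map: dict[str, set] = {}
        mask = ann["track"].isin([f"hp_{breed}", f"fst_{breed}"])
        for _, r in ann[mask].iterrows():
            key = f"{r['chrom']}:{r['start0']}-{r['end0']}"
            if key not in wins:
                continue
            for col in ("genes_within", "genes_flanking"):
                if isinstance(r[col], str) and r[col]:
                    for g in r[col].split(","):
                        window_map.setdefault(g, set()).add(key)
        if not window_map:
            continue
        try:
            enr = downstream.fisher_enrichment(window_map, coll)
        except ValueError:
            continue
        kept = downstream.filter_enrichment(
            enr, window_map, cfg.enrich_min_genes, cfg.enrich_min_windows,
            cfg.enrich_alpha)
        df = downstream.enrichment_to_frame(kept)
        df.insert(0, "breed", breed)
        rows.append(df)
    out = (pd.concat(rows, ignore_index=True) if rows else
           pd.DataFrame(columns=["breed", "term", "n_genes", "n_windows",
                                 "p_raw", "p_adj", "genes"]))
    out.to_csv(cfg.out("enrichment.tsv"), sep="\t", index=False)
    log.info("enrich: %d enriched term rows", len(out))
    _register(cfg, "enrich", [cfg.out("enrichment.tsv")],
              {"min_genes": cfg.enrich_min_genes,
               "min_windows": cfg.enrich_min_windows,
               "alpha": cfg.enrich_alpha})


def stage_deleterious(cfg: RunConfig) -> None:
    paths = _input_paths(cfg)
    impact_path = paths["impact"]
    if impact_path is None or not Path(impact_path).exists():
        log.info("deleterious: no impact table provided; skipped")
        return
    table, panel = _load_filtered(cfg)
    impact = pd.read_csv(impact_path, sep="\t")
    records, counts = downstream.classify_deleterious(impact)

    af = table.af()
    site_index = {
        (r["chrom"], int(r["pos"]), r["ref"], r["alt"]): i
        for i, (_, r) in enumerate(table.sites.iterrows())
    }
    wild = panel.wild_pool
    wild_j = panel.index(wild) if wild else None
    domestic_j = [panel.index(n) for n in panel.domestic_names()]

    region_df = pd.read_csv(cfg.out("regions.bed"), sep="\t")
    sweep_regions = [
        regions.SweepRegion(str(r["chrom"]), int(r["start0"]), int(r["end0"]), [])
        for _, r in region_df.iterrows()
    ]

    rows = []
    for rec in records:
        i = site_index.get((rec.chrom, rec.pos, rec.ref, rec.alt))
        wild_af = float("nan")
        group_af = float("nan")
        if i is not None:
            group_af = float(np.nanmean(af[i, domestic_j]))
            if wild_j is not None:
                if table.wild_af is not None:
                    wild_af = float(table.wild_af[i])
                else:
                    wild_af = float(af[i, wild_j])
        anc = downstream.ancestral_allele(wild_af)
        contrast = (downstream.frequency_contrast(group_af, wild_af,
                                                  cfg.af_hi, cfg.af_lo)
                    if not (np.isnan(group_af) or np.isnan(wild_af)) else False)
        in_sweep = bool(downstream.deleterious_in_sweeps([rec], sweep_regions)) \
            if rec.deleterious else False
        rows.append({
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
            "gene": rec.gene, "consequence": rec.consequence,
            "sift_score": rec.sift_score, "deleterious": rec.deleterious,
            "ancestral_allele": anc, "group_af": group_af, "wild_af": wild_af,
            "marked_contrast": contrast, "in_sweep_region": in_sweep,
        })
    df = pd.DataFrame(rows)
    df.to_csv(cfg.out("deleterious.tsv"), sep="\t", index=False)
    cfg.out("deleterious_summary.json").write_text(json.dumps(counts))
    hits = df[df["deleterious"] & df["marked_contrast"] & df["in_sweep_region"]]
    hits.to_csv(cfg.out("deleterious_in_sweeps.tsv"), sep="\t", index=False)
    log.info("deleterious: %d harmful, %d contrast-passing in sweeps",
             counts["deleterious_total"], len(hits))
    _register(cfg, "deleterious",
              [cfg.out("deleterious.tsv"), cfg.out("deleterious_summary.json"),
               cfg.out("deleterious_in_sweeps.tsv")],
              {"af_hi": cfg.af_hi, "af_lo": cfg.af_lo})


STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "windows": stage_windows,
    "scan-hp": stage_scan_hp,
    "scan-fst": stage_scan_fst,
    "contrasts": stage_contrasts,
    "outliers": stage_outliers,
    "annotate": stage_annotate,
    "tree": stage_tree,
    "mantel": stage_mantel,
    "enrich": stage_enrich,
    "deleterious": stage_deleterious,
}


def run_pipeline(cfg: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages in order; return the manifest."""
    cfg.validate()
    order = list(STAGES)
    if not cfg.simulate:
        order.remove("simulate")
    if stages is not None:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        order = [s for s in order if s in set(stages)]
    for name in order:
        try:
            STAGES[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    mpath = cfg.out("manifest.json")
    return json.loads(mpath.read_text()) if mpath.exists() else {}


# ---------------------------------------------------------------------------
# small writers for simulated ancillary inputs
# ---------------------------------------------------------------------------

def _write_gff3(genes: Sequence[regions.GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpoolscan\tgene\t{g.start0 + 1}\t{g.end0}\t.\t+\t.\t"
                f"ID=gene:{g.gene_id};Name={g.gene_name};biotype={g.biotype}\n"
            )


def _write_gmt(gene_sets: Mapping[str, Sequence[str]], path: Path) -> None:
    with open(path, "w") as fh:
        for term, members in gene_sets.items():
            fh.write("\t".join([term, "synthetic"] + list(members)) + "\n")
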