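"""End-to-end orchestration: simulate/load → QC → structure → scan →
annotate → enrich, as one reproducible, seeded run.

Every randomized stage draws from a named substream derived from the
single top-level seed, so adding or re-running one stage never perturbs
another's draws.  All output files are byte-stable for a fixed config and
seed; the manifest records a SHA-256 checksum per output.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotate import hypergeometric_enrichment, overlap_genes, read_gene_sets
from .io_formats import (
    GeneRecord,
    PopulationMap,
    ValidationError,
    read_gene_annotation,
    read_population_map,
    read_vcf,
    write_bed,
    write_population_map,
    write_vcf,
)
from .qc import QCThresholds, apply_qc
from .scan import (
    ScanThresholds,
    candidate_windows,
    merge_regions,
    scan_windows,
)
from .simulate import SimulationConfig, SweepSpec, simulate, write_truth
from .structure import admixture_nmf, nj_tree, p_distance_matrix, pca, relationship_matrix, select_K


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``vcf`` + ``popmap`` point at real inputs, or ``simulation``
    describes a synthetic dataset to generate first.  Defaults follow the
    study design this pipeline implements: missingness 0.1, MAF 0.05,
    HWE alpha 1e-6, 50 kb windows with 25 kb steps, top 5% F_ST,
    2.5% ratio tails, K from 2 to 10.
    """

    out_dir: str = "sweepscan_run"
    seed: int = 0
    # inputs
    vcf: str | None = None
    popmap: str | None = None
    simulation: SimulationConfig | None = None
    annotation: str | None = None
    annotation_format: str = "BED"
    gene_sets: str | None = None
    # QC
    max_missing_rate: float = 0.10
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    # scan
    window_size: int = 50_000
    step: int = 25_000
    min_snps: int = 3
    fst_estimator: str = "direct"
    fst_top_fraction: float = 0.05
    ratio_tail_fraction: float = 0.025
    # structure
    k_min: int = 2
    k_max: int = 10
    seeds_per_k: int = 1
    nmf_max_iter: int = 200
    nmf_tol: float = 1e-5
    nmf_mask_fraction: float = 0.05
    pca_components: int = 10
    #: ancestry inference runs on a seeded random subset of at most this
    #: many post-QC sites (cheap stand-in for LD pruning); GRM/PCA, the
    #: tree and the scan always use every site.
    structure_max_sites: int = 20_000
    run_structure: bool = True
    run_enrichment: bool = True


@dataclass
class RunManifest:
    config: dict
    version: str
    stages_completed: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)


def validate_config(config: RunConfig) -> list[str]:
    """Check config invariants; returns violation names (empty = ok)."""
    v: list[str] = []
    if config.simulation is None:
        if config.vcf is None or config.popmap is None:
            v.append("missing_input")
        else:
            if not Path(config.vcf).exists():
                v.append("vcf_not_found")
            if not Path(config.popmap).exists():
                v.append("popmap_not_found")
    if config.annotation is not None and not Path(config.annotation).exists():
        v.append("annotation_not_found")
    if config.gene_sets is not None and not Path(config.gene_sets).exists():
        v.append("gene_sets_not_found")
    for name in ("max_missing_rate", "min_maf", "hwe_alpha"):
        if not (0 < getattr(config, name) < 1):
            v.append(f"{name}_out_of_range")
    if config.window_size < config.step:
        v.append("window_lt_step")
    if config.step <= 0:
        v.append("nonpositive_step")
    if not (0 < config.fst_top_fraction < 0.5):
        v.append("fst_top_fraction_out_of_range")
    if not (0 < config.ratio_tail_fraction < 0.5):
        v.append("ratio_tail_fraction_out_of_range")
    if not (2 <= config.k_min <= config.k_max):
        v.append("bad_k_range")
    if config.seeds_per_k < 1:
        v.append("bad_seeds_per_k")
    if config.fst_estimator not in ("direct", "hudson", "wc"):
        v.append("unknown_fst_estimator")
    return v


def _substream(seed: int, name: str) -> int:
    """Deterministic named substream seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _synthetic_annotation(chrom_lengths: dict[str, int]) -> list[GeneRecord]:
    """Deterministic synthetic gene grid: 30-kb genes every 60 kb."""
    genes = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        k = 0
        start = 15_000
        while start + 30_000 <= length:
            genes.append(GeneRecord(chrom, start, start + 30_000, f"{chrom}_g{k:04d}", "+"))
            start += 60_000
            k += 1
    return genes


def _synthetic_gene_sets(genes: list[GeneRecord], seed: int, n_sets: int = 50,
                         set_size: int = 40) -> dict[str, set[str]]:
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in genes]
    return {
        f"SET{idx:03d}": set(rng.choice(ids, size=min(set_size, len(ids)), replace=False))
        for idx in range(n_sets)
    }


def run_all(config: RunConfig) -> RunManifest:
    """Execute the whole pipeline; any stage failure halts the run with
    the manifest recording the stages already completed."""
    violations = validate_config(config)
    if violations:
        raise ValidationError(f"invalid config: {violations}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    if config.simulation is not None:
        cfg_dict["simulation"] = asdict(config.simulation)
    manifest = RunManifest(config=cfg_dict, version=__version__)

    def _record(path: Path) -> None:
        manifest.outputs[str(path.relative_to(out))] = _sha256(path)

    def _stage_done(name: str, t0: float) -> None:
        manifest.stages_completed.append(name)
        manifest.timings[name] = round(time.perf_counter() - t0, 3)

    # ---- input: simulate or load -----------------------------------------
    t0 = time.perf_counter()
    if config.simulation is not None:
        sim_cfg = config.simulation
        if sim_cfg.seed == 0:
            sim_cfg = SimulationConfig(**{**asdict(sim_cfg), "seed": _substream(config.seed, "simulate")})
            sim_cfg.sweep_specs = [SweepSpec(**s) if isinstance(s, dict) else s
                                   for s in sim_cfg.sweep_specs]
        gm, popmap, truth = simulate(sim_cfg)
        write_vcf(gm, out / "simulated.vcf", sim_cfg.chrom_lengths)
        write_population_map(popmap, out / "popmap.tsv")
        write_truth(truth, out / "truth_sweeps.bed", out / "truth_frequencies.tsv")
        for name in ("simulated.vcf", "popmap.tsv", "truth_sweeps.bed", "truth_frequencies.tsv"):
            _record(out / name)
        chrom_lengths = dict(sim_cfg.chrom_lengths)
        _stage_done("simulate", t0)
    else:
        gm = read_vcf(config.vcf)
        popmap = read_population_map(config.popmap)
        chrom_lengths = {
            c: int(sub["pos"].max()) for c, sub in gm.sites.groupby("chrom", sort=True)
        }
        _stage_done("load", t0)
    popmap.validate_against(gm, scan_mode=True)

    # ---- QC ---------------------------------------------------------------
    t0 = time.perf_counter()
    thresholds = QCThresholds(config.max_missing_rate, config.min_maf, config.hwe_alpha)
    gm_qc, qc_report = apply_qc(gm, popmap, thresholds)
    write_vcf(gm_qc, out / "qc.vcf", chrom_lengths)
    (out / "qc_report.txt").write_text(qc_report.summary())
    _record(out / "qc.vcf")
    _record(out / "qc_report.txt")
    manifest.results["qc"] = {
        "sites_before": qc_report.sites_before,
        "sites_after": qc_report.sites_after,
        "removed_missing": qc_report.removed_missing,
        "removed_maf": qc_report.removed_maf,
        "removed_hwe": qc_report.removed_hwe,
    }
    _stage_done("qc", t0)

    # ---- population structure --------------------------------------------
    if config.run_structure:
        t0 = time.perf_counter()
        rel = relationship_matrix(gm_qc)
        k_pca = min(config.pca_components, gm_qc.n_samples - 1)
        pca_res = pca(rel, k_pca)
        _write_tsv(
            out / "pca_coordinates.tsv",
            ["sample"] + [f"PC{i+1}" for i in range(k_pca)],
            [
                [s] + [f"{x:.8g}" for x in pca_res.coordinates[i]]
                for i, s in enumerate(pca_res.samples)
            ],
        )
        _write_tsv(
            out / "pca_variance.tsv",
            ["component", "variance_fraction"],
            [[f"PC{i+1}", f"{v:.8g}"] for i, v in enumerate(pca_res.variance_fraction)],
        )
        dm = p_distance_matrix(gm_qc)
        (out / "nj_tree.nwk").write_text(nj_tree(dm) + "\n")

        # ancestry on a seeded site subset (see structure_max_sites)
        gm_struct = gm_qc
        if gm_qc.n_sites > config.structure_max_sites:
            rng = np.random.default_rng(_substream(config.seed, "structure_subsample"))
            idx = np.sort(
                rng.choice(gm_qc.n_sites, size=config.structure_max_sites, replace=False)
            )
            gm_struct = gm_qc.take_sites(idx)
        k_max = min(config.k_max, gm_struct.n_samples)
        best_k, ce_table = select_K(
            gm_struct,
            range(config.k_min, k_max + 1),
            seeds_per_K=config.seeds_per_k,
            seed=_substream(config.seed, "select_K"),
            mask_fraction=config.nmf_mask_fraction,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
        )
        _write_tsv(
            out / "cross_entropy.tsv",
            ["K", "masked_cross_entropy"],
            [[str(k), f"{ce_table[k]:.8g}"] for k in sorted(ce_table)],
        )
        adm = admixture_nmf(
            gm_struct,
            best_k,
            seed=_substream(config.seed, f"admixture_K{best_k}"),
            mask_fraction=config.nmf_mask_fraction,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
        )
        _write_tsv(
            out / f"admixture_Q_K{best_k}.tsv",
            ["sample"] + [f"cluster{c+1}" for c in range(best_k)],
            [
                [s] + [f"{x:.8g}" for x in adm.Q[i]]
                for i, s in enumerate(gm_struct.samples)
            ],
        )
        for name in (
            "pca_coordinates.tsv", "pca_variance.tsv", "nj_tree.nwk",
            "cross_entropy.tsv", f"admixture_Q_K{best_k}.tsv",
        ):
            _record(out / name)
        manifest.results["structure"] = {
            "best_K": best_k,
            "pc1_variance_fraction": float(pca_res.variance_fraction[0]),
            "pc2_variance_fraction": float(pca_res.variance_fraction[1])
            if k_pca > 1 else None,
        }
        _stage_done("structure", t0)

    # ---- selection scan ----------------------------------------------------
    t0 = time.perf_counter()
    scan_res = scan_windows(
        gm_qc,
        popmap,
        chrom_lengths=chrom_lengths,
        window_size=config.window_size,
        step=config.step,
        min_snps=config.min_snps,
        estimator=config.fst_estimator,
    )
    scan_res.table.to_csv(out / "window_stats.tsv", sep="\t", index=False, float_format="%.8g")
    sel_b, sel_a, sel_info = candidate_windows(
        scan_res, ScanThresholds(config.fst_top_fraction, config.ratio_tail_fraction)
    )
    regions = merge_regions(sel_b, "SELECTED_IN_B") + merge_regions(sel_a, "SELECTED_IN_A")
    write_bed(
        [(r.chrom, r.start, r.end, r.direction) for r in regions],
        out / "candidate_regions.bed",
    )
    for name in ("window_stats.tsv", "candidate_regions.bed"):
        _record(out / name)
    manifest.warnings["fst_clip_count"] = scan_res.fst_clip_count
    manifest.warnings["undefined_window_counts"] = {
        "fst_undefined": scan_res.counters["n_windows"]
        - scan_res.counters["n_windows_fst_defined"],
        "ratio_undefined": scan_res.counters["n_windows"]
        - scan_res.counters["n_windows_ratio_defined"],
    }
    manifest.results["scan"] = {
        **sel_info,
        "n_selected_in_B_windows": int(len(sel_b)),
        "n_selected_in_A_windows": int(len(sel_a)),
        "n_candidate_regions": len(regions),
    }
    _stage_done("scan", t0)

    # ---- annotation + enrichment -------------------------------------------
    t0 = time.perf_counter()
    if config.annotation is not None:
        genes = read_gene_annotation(config.annotation, config.annotation_format)
    else:
        genes = _synthetic_annotation(chrom_lengths)
        write_bed(
            [(g.chrom, g.start, g.end, g.gene_id) for g in genes],
            out / "synthetic_genes.bed",
        )
        _record(out / "synthetic_genes.bed")
    annotated, per_direction = overlap_genes(regions, genes)
    _write_tsv(
        out / "region_genes.tsv",
        ["chrom", "start", "end", "direction", "n_windows", "genes"],
        [
            [r.chrom, str(r.start), str(r.end), r.direction, str(r.n_windows),
             ",".join(r.gene_ids)]
            for r in annotated
        ],
    )
    _record(out / "region_genes.tsv")
    for direction in sorted(per_direction):
        path = out / f"genes_{direction}.txt"
        path.write_text("".join(g + "\n" for g in sorted(per_direction[direction])))
        _record(path)
    manifest.results["annotation"] = {
        d: len(v) for d, v in sorted(per_direction.items())
    }
    _stage_done("annotate", t0)

    if config.run_enrichment:
        t0 = time.perf_counter()
        if config.gene_sets is not None:
            gene_sets = read_gene_sets(config.gene_sets)
        else:
            gene_sets = _synthetic_gene_sets(genes, _substream(config.seed, "gene_sets"))
        universe = [g.gene_id for g in genes]
        for direction in sorted(per_direction):
            rows = hypergeometric_enrichment(per_direction[direction], gene_sets, universe)
            path = out / f"enrichment_{direction}.tsv"
            _write_tsv(
                path,
                ["set_id", "set_size", "overlap", "p_value", "fdr"],
                [
                    [r.set_id, str(r.set_size), str(r.overlap),
                     f"{r.p_value:.6g}", f"{r.fdr:.6g}"]
                    for r in rows
                ],
            )
            _record(path)
        _stage_done("enrich", t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=str)
    return manifest


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_run_config(path: str) -> RunConfig:
    """Load a YAML run config; the ``simulation`` block, if present, maps
    onto :class:`SimulationConfig` with ``sweeps`` as a list of
    ``[chrom, start, end, population, intensity]`` entries."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = None
    if "simulation" in raw:
        sim_raw = dict(raw.pop("simulation") or {})
        sweeps = [
            SweepSpec(s[0], int(s[1]), int(s[2]), str(s[3]),
                      float(s[4]) if len(s) > 4 else 1.0)
            for s in sim_raw.pop("sweeps", [])
        ]
        sim = SimulationConfig(sweep_specs=sweeps, **sim_raw)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(simulation=sim, **raw)
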