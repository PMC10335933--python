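"""End-to-end pipeline driver with provenance manifest.

Stages run in dependency order (synthdata -> pangene / pavscan /
divscan -> gwasloci -> gsbreed); each stage writes TSV outputs into the
run directory and the driver records a manifest with the seed, a config
hash and per-file SHA-256 checksums, plus a resolved copy of the config,
so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, divscan, gsbreed, gwasloci, io, pangene, pavscan
from .synthdata import SimConfig, SimDataset, simulate_dataset

STAGE_ORDER = ("synthdata", "pangene", "pavscan", "divscan", "gwasloci",
               "gsbreed")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Run settings: output dir, seed, stage toggles, per-stage knobs."""

    outdir: str = "panpav_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    sim: dict = field(default_factory=dict)        # SimConfig overrides
    growth_permutations: int = 50
    q_max: float = 0.01
    min_delta: float = 0.25
    promoter_len: int = 2000
    te_n_perm: int = 199
    window_size: int = 20_000
    window_step: int = 2_000
    scan_quantile: float = 0.01
    n_pc: int = 10
    p_max: float = gwasloci.DEFAULT_P_MAX
    locus_dist_max: int = 50_000
    locus_r2_min: float = 0.3
    candidate_window: int = 50_000
    ld_flank: int = 50_000
    ld_r2_cut: float = 0.5
    rof_max: float = 0.99
    gs_model: str = "gbm"
    gs_reps: int = 20
    breeding_top_k: int = 10
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in STAGE_ORDER:
            self.stages.setdefault(s, True)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _stage_synthdata(cfg: PipelineConfig, out: Path) -> SimDataset:
    data = simulate_dataset(cfg.sim_config())
    io.write_snp_vcf(out / "snps.vcf", data.snps, data.config.genome)
    io.write_sv_vcf(out / "pavs.vcf", data.pavs, data.config.genome)
    io.write_presence_matrix(out / "presence.tsv", data.presence)
    io.write_groups(out / "groups.tsv", data.groups)
    io.write_phenotypes(out / "phenotypes.tsv", data.phenotypes)
    io.write_bed(out / "tes.bed", data.tes, name_col="te_id")
    io.write_gff3(out / "genes.gff3", data.genes.rename(
        columns={"gene_id": "name"}))
    _write(data.truth.selected_pavs, out / "truth_selected_pavs.tsv")
    _write(data.truth.causal_effects, out / "truth_causal_effects.tsv")
    _write(data.truth.planted_tsds, out / "truth_tsds.tsv")
    data.truth.family_category.rename("category").to_csv(
        out / "truth_family_category.tsv", sep="\t", index_label="family")
    return data


def _stage_pangene(cfg: PipelineConfig, out: Path, data: SimDataset) -> None:
    comp = pangene.classify_families(data.presence)
    _write(comp.summary(), out / "pan_composition.tsv")
    comp.categories.to_csv(out / "pan_categories.tsv", sep="\t",
                           index_label="family")
    curve = pangene.growth_curves(data.presence,
                                  n_permutations=cfg.growth_permutations,
                                  seed=cfg.seed)
    _write(curve.to_frame(), out / "growth_curve.tsv")
    closure = pangene.fit_closure(curve)
    _write(closure.summary(), out / "closure.tsv")


def _stage_pavscan(cfg: PipelineConfig, out: Path, data: SimDataset) -> None:
    res = pavscan.SelectionScan(data.pavs, data.groups, q_max=cfg.q_max,
                                min_delta=cfg.min_delta).fit()
    _write(res.domestication, out / "scan_domestication.tsv")
    _write(res.improvement, out / "scan_improvement.tsv")
    _write(res.favpav, out / "favpav.tsv")
    _write(res.summary(), out / "selection_summary.tsv")

    assoc, profile = pavscan.map_pavs_to_genes(data.pavs, data.genes,
                                               promoter_len=cfg.promoter_len)
    _write(assoc, out / "pav_gene_associations.tsv")
    _write(profile, out / "pav_distance_profile.tsv")
    _write(pavscan.favorable_genes(res.favpav, assoc),
           out / "favorable_genes.tsv")

    enr = pavscan.te_overlap_enrichment(data.pavs, data.tes,
                                        data.config.genome,
                                        n_perm=cfg.te_n_perm, seed=cfg.seed)
    _write(enr.summary(), out / "te_enrichment.tsv")
    _write(pavscan.classify_te_derived(data.pavs, data.tes),
           out / "te_derived.tsv")


def _stage_divscan(cfg: PipelineConfig, out: Path, data: SimDataset) -> None:
    res = divscan.DiversityScan(
        data.snps, data.groups, window_size=cfg.window_size,
        step=cfg.window_step, genome=data.config.genome).fit()
    flagged = res.candidates(cfg.scan_quantile)
    _write(flagged.windows, out / "diversity_windows.tsv")
    _write(flagged.thresholds.summary(), out / "diversity_thresholds.tsv")


def _marker_frame(data: SimDataset):
    """Combined SNP+SV marker matrix and metadata for GWAS/GS stages."""
    rec = data.pavs.records
    dosage = np.hstack([data.snps.dosage, data.pavs.genotypes])
    ids = np.concatenate([data.snps.ids, rec["id"].to_numpy()])
    chrom = np.concatenate([data.snps.chrom, rec["chrom"].to_numpy()])
    pos = np.concatenate([data.snps.pos, rec["start"].to_numpy()])
    mtype = np.concatenate([np.full(data.snps.n_markers, "SNP"),
                            np.full(len(rec), "SV")])
    return dosage, ids, chrom, pos, mtype


def _stage_gwasloci(cfg: PipelineConfig, out: Path, data: SimDataset
                    ) -> gwasloci.LMMResults:
    dosage, ids, chrom, pos, mtype = _marker_frame(data)
    trait = data.phenotypes.traits[0]
    env = data.phenotypes.envs[0]
    y = data.phenotypes.trait_vector(trait, env, data.snps.accessions)
    model = gwasloci.MixedLMM(y, dosage, marker_ids=ids, chrom=chrom,
                              pos=pos, marker_type=mtype, n_pc=cfg.n_pc)
    res = model.fit()
    _write(res.table, out / "association.tsv")
    _write(res.summary(), out / "association_summary.tsv")

    meff, thresholds = gwasloci.effective_marker_number(model.dosage)
    _write(pd.DataFrame([{"m_eff": meff,
                          **{f"threshold_a{a}": t
                             for a, t in thresholds.items()}}]),
           out / "effective_markers.tsv")

    loci = gwasloci.cluster_loci(res.table, model.dosage, p_max=cfg.p_max,
                                 dist_max=cfg.locus_dist_max,
                                 r2_min=cfg.locus_r2_min)
    _write(gwasloci.loci_to_frame(loci), out / "loci.tsv")
    _write(gwasloci.candidate_genes(loci, data.genes,
                                    window=cfg.candidate_window),
           out / "candidate_genes.tsv")

    rec = data.pavs.records
    ld = gwasloci.sv_snp_ld_complement(
        data.pavs.genotypes, rec["chrom"].to_numpy(),
        rec["start"].to_numpy(int), rec["end"].to_numpy(int),
        data.snps.dosage, data.snps.chrom, data.snps.pos,
        sv_ids=rec["id"].to_numpy(), flank=cfg.ld_flank,
        r2_cut=cfg.ld_r2_cut)
    _write(ld.table, out / "sv_snp_ld.tsv")
    _write(ld.summary(), out / "sv_snp_ld_summary.tsv")
    return res


def _stage_gsbreed(cfg: PipelineConfig, out: Path, data: SimDataset,
                   assoc: gwasloci.LMMResults | None) -> None:
    dosage, ids, chrom, pos, mtype = _marker_frame(data)
    trait = data.phenotypes.traits[0]
    env = data.phenotypes.envs[0]
    y = data.phenotypes.trait_vector(trait, env, data.snps.accessions)

    is_sv = mtype == "SV"
    imp = gsbreed.feature_gain(dosage, y, marker_ids=ids, seed=cfg.seed)
    _write(imp.table, out / "marker_importance.tsv")
    cg = set(gsbreed.rof_select(imp, cfg.rof_max))
    gwas_snp, gwas_sv = set(), set()
    if assoc is not None:
        sig = assoc.significant(cfg.p_max)
        gwas_snp = set(sig.loc[sig["type"] == "SNP", "marker_id"])
        gwas_sv = set(sig.loc[sig["type"] == "SV", "marker_id"])
    panels = gsbreed.build_panels(cg - set(ids[is_sv]), cg & set(ids[is_sv]),
                                  gwas_snp, gwas_sv)
    _write(pd.DataFrame([{"panel": p.name, "n_markers": len(p)}
                         for p in panels.values()]),
           out / "panels.tsv")

    id_index = {m: i for i, m in enumerate(ids)}
    reports = []
    results = None
    for name, panel in panels.items():
        if not len(panel):
            continue
        cols = np.array([id_index[m] for m in panel.markers])
        gp = gsbreed.GenomicPrediction(
            dosage[:, cols], y, marker_ids=ids[cols], model=cfg.gs_model,
            rof_max=cfg.rof_max, reps=cfg.gs_reps, seed=cfg.seed)
        fitted = gp.fit()
        row = fitted.summary()
        row.insert(0, "panel", name)
        reports.append(row)
        if name == "SNPSV_cg_gwas":
            results = fitted
    if reports:
        _write(pd.concat(reports, ignore_index=True),
               out / "prediction_precision.tsv")
    if results is not None and len(results.importance.table):
        cultivated = (data.groups.loc[data.snps.accessions] == "cultivar"
                      ).to_numpy()
        top_k = min(cfg.breeding_top_k, len(results.importance.table))
        breeding = results.breeding_potential(
            top_k=top_k, cap=max(20, top_k), accession_mask=cultivated)
        _write(breeding.summary(), out / "breeding_report.tsv")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in order; return the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    io.dump_config(out / "resolved_config.yaml", config)

    data: SimDataset | None = None
    assoc = None
    completed = []
    if config.stages.get("synthdata", True):
        data = _stage_synthdata(config, out)
        completed.append("synthdata")
    if data is None:
        raise ValueError("pipeline currently requires the synthdata stage "
                         "(external-input runs load data via panpav.io)")
    if config.stages.get("pangene", True):
        _stage_pangene(config, out, data)
        completed.append("pangene")
    if config.stages.get("pavscan", True):
        _stage_pavscan(config, out, data)
        completed.append("pavscan")
    if config.stages.get("divscan", True):
        _stage_divscan(config, out, data)
        completed.append("divscan")
    if config.stages.get("gwasloci", True):
        assoc = _stage_gwasloci(config, out, data)
        completed.append("gwasloci")
    if config.stages.get("gsbreed", True):
        _stage_gsbreed(config, out, data, assoc)
        completed.append("gsbreed")

    cfg_text = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "panpav_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "stages_completed": completed,
        "files": {p.name: _sha256(p)
                  for p in sorted(out.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
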