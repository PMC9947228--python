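"""End-to-end orchestration of the subgroup-discovery analysis.

Stages, in order: genotype QC -> participant alignment -> genetic PCs ->
per-SNP/per-lipid GWAS -> SNP preselection -> non-negative preparation and
fuzzy NMF biclustering of both domains -> hypergeometric relation testing
-> distinctness screening -> per-relation LD pruning -> clinical Welch
comparisons -> gene-set overrepresentation (when a SNP-gene map and GMT
collections are supplied).  Default thresholds are the analysis settings
the package documents: GWAS preselection p < 5e-4 capped at 20,000 SNPs,
relation alpha 0.01, distinctness fraction 0.5, pruning r² 0.5, clumping
r² 0.1 within 250 kb, ORA FDR 0.05.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import enrichment, io, nmf, relations
from .cohort import CohortConfig, simulate_cohort, write_cohort
from .errors import ConfigurationError
from .gwas import compute_pcs, preselect_snps, run_gwas, study_wide_threshold
from .ld import LdParams, prune_snps
from .qc import QcThresholds, run_qc


@dataclass
class PipelineConfig:
    """All stage parameters plus paths and the global seed."""

    qc: QcThresholds = field(default_factory=QcThresholds)
    ld: LdParams = field(default_factory=LdParams)
    gwas_p_threshold: float = 5e-4
    gwas_snp_cap: int = 20_000
    genomewide_alpha: float = 5e-8
    n_pcs: int = 10
    rank_grid: tuple = tuple(range(2, 21))
    membership_fraction: float = 0.5
    dedup_jaccard: float = 0.9
    relation_alpha: float = 0.01
    distinctness_fraction: float = 0.5
    fdr_max: float = 0.05
    set_size_bounds: tuple = (10, 500)
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-6
    seed: int = 0
    cohort: CohortConfig = None
    input_dir: str = None
    output_dir: str = "biclink_out"
    snp_gene_map_path: str = None
    gmt_paths: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(raw)
        if "qc" in kw and isinstance(kw["qc"], dict):
            kw["qc"] = QcThresholds(**kw["qc"])
        if "ld" in kw and isinstance(kw["ld"], dict):
            kw["ld"] = LdParams(**kw["ld"])
        if "cohort" in kw and isinstance(kw["cohort"], dict):
            for tup_key in ("maf_range", "subgroup_size_range"):
                if tup_key in kw["cohort"]:
                    kw["cohort"][tup_key] = tuple(kw["cohort"][tup_key])
            kw["cohort"] = CohortConfig(**kw["cohort"])
        for tup_key in ("rank_grid", "set_size_bounds"):
            if tup_key in kw:
                kw[tup_key] = tuple(kw[tup_key])
        return cls(**kw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0
    versions: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (set, frozenset, tuple)):
                return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
            return str(o)

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "counts": self.counts,
                    "timings": self.timings,
                    "config": self.config,
                    "seed": self.seed,
                    "versions": self.versions,
                },
                fh,
                indent=2,
                default=default,
            )


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "biclink": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_pipeline(config: PipelineConfig, cohort=None, log=print):
    """Execute the full analysis; returns (RunReport, artifacts dict).

    ``cohort`` may carry pre-loaded ``(genotype, lipidome, covariates,
    truth_or_None)``; otherwise the cohort is simulated from
    ``config.cohort`` (or read from ``config.input_dir``).
    """
    cfg = config
    outdir = cfg.output_dir
    os.makedirs(outdir, exist_ok=True)
    report = RunReport(seed=cfg.seed, config=cfg.echo(), versions=_versions())
    artifacts: dict = {}
    t_start = time.perf_counter()

    def tick(stage, t0):
        report.timings[stage] = round(time.perf_counter() - t0, 3)

    # --- inputs --------------------------------------------------------
    t0 = time.perf_counter()
    if cohort is not None:
        genotype, lipidome, covariates = cohort[0], cohort[1], cohort[2]
        truth = cohort[3] if len(cohort) > 3 else None
    elif cfg.input_dir is not None:
        from .cohort import read_cohort

        genotype, lipidome, covariates, truth = read_cohort(cfg.input_dir)
    else:
        ccfg = cfg.cohort or CohortConfig(seed=cfg.seed)
        genotype, lipidome, covariates, truth = simulate_cohort(ccfg)
        artifacts.update(write_cohort((genotype, lipidome, covariates, truth), os.path.join(outdir, "cohort")))
    report.counts["input_samples"] = genotype.n_participants
    report.counts["input_snps"] = genotype.n_snps
    report.counts["input_lipids"] = lipidome.n_lipids
    tick("load", t0)

    # --- QC ------------------------------------------------------------
    t0 = time.perf_counter()
    genotype, qc_report = run_qc(genotype, cfg.qc)
    qc_path = os.path.join(outdir, "qc_report.tsv")
    io.write_table(qc_report.to_frame(), qc_path)
    artifacts["qc_report"] = qc_path
    report.counts.update({f"qc_{k}": v for k, v in qc_report.counts.items()})
    tick("qc", t0)
    log(f"[qc] retained {genotype.n_participants} samples, {genotype.n_snps} SNPs")

    # --- alignment -----------------------------------------------------
    shared = [
        p
        for p in genotype.participant_ids
        if p in set(lipidome.participant_ids) and p in set(covariates.index)
    ]
    dropped = genotype.n_participants - len(shared)
    mask = np.isin(genotype.participant_ids, shared)
    genotype = genotype.subset(participant_mask=mask)
    lipidome_conc = lipidome.concentrations.loc[shared]
    lipidome = type(lipidome)(lipidome_conc, lipidome.classes)
    covariates = covariates.loc[shared]
    report.counts["aligned_participants"] = len(shared)
    report.counts["dropped_participants"] = dropped
    log(f"[align] {len(shared)} participants shared across inputs ({dropped} dropped)")

    # --- PCs + GWAS ----------------------------------------------------
    t0 = time.perf_counter()
    k = min(cfg.n_pcs, genotype.n_participants - 1, genotype.n_snps)
    pcs = compute_pcs(genotype, k, ld_thin_r2=cfg.ld.prune_r2)
    covar_cols = [c for c in ("sex", "age", "bmi", "t2d", "lipid_medication") if c in covariates]
    design = covariates[covar_cols].copy()
    for i in range(pcs.shape[1]):
        design[f"PC{i + 1}"] = pcs[:, i]
    gwas_table = run_gwas(genotype, lipidome, design)
    gwas_path = os.path.join(outdir, "gwas.tsv")
    io.write_table(gwas_table.records, gwas_path)
    artifacts["gwas"] = gwas_path
    nominal = gwas_table.records[gwas_table.records["p"] < cfg.gwas_p_threshold]
    report.counts["gwas_records"] = len(gwas_table.records)
    report.counts["gwas_nominal_associations"] = len(nominal)
    report.counts["study_wide_threshold"] = study_wide_threshold(
        cfg.genomewide_alpha, lipidome.n_lipids
    )
    tick("gwas", t0)

    # --- preselection --------------------------------------------------
    selected = preselect_snps(gwas_table, cfg.gwas_p_threshold, cfg.gwas_snp_cap)
    report.counts["preselected_snps"] = len(selected)
    log(f"[gwas] {len(nominal)} nominal associations; {len(selected)} SNPs preselected")
    geno_sub = genotype.subset_snp_ids(selected)

    # --- biclustering --------------------------------------------------
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(cfg.seed)
    seed_g, seed_l = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    g_bcs = nmf.multilayer_biclustering(
        nmf.prepare_genotype_matrix(geno_sub),
        cfg.rank_grid,
        seed=seed_g,
        membership_fraction=cfg.membership_fraction,
        dedup_jaccard=cfg.dedup_jaccard,
        domain="genotype",
        participant_ids=geno_sub.participant_ids,
        feature_ids=geno_sub.snp_ids,
        max_iter=cfg.nmf_max_iter,
        tol=cfg.nmf_tol,
    )
    l_bcs = nmf.multilayer_biclustering(
        nmf.prepare_lipidome_matrix(lipidome),
        cfg.rank_grid,
        seed=seed_l,
        membership_fraction=cfg.membership_fraction,
        dedup_jaccard=cfg.dedup_jaccard,
        domain="lipidome",
        participant_ids=lipidome.participant_ids,
        feature_ids=lipidome.lipid_names,
        max_iter=cfg.nmf_max_iter,
        tol=cfg.nmf_tol,
    )
    for bset, tag in ((g_bcs, "genotype"), (l_bcs, "lipidome")):
        pframe, fframe = bset.to_frames()
        p_path = os.path.join(outdir, f"biclusters_{tag}_participants.tsv")
        f_path = os.path.join(outdir, f"biclusters_{tag}_features.tsv")
        io.write_table(pframe, p_path)
        io.write_table(fframe, f_path)
        artifacts[f"biclusters_{tag}_participants"] = p_path
        artifacts[f"biclusters_{tag}_features"] = f_path
    report.counts["genotype_biclusters"] = len(g_bcs)
    report.counts["lipidome_biclusters"] = len(l_bcs)
    tick("bicluster", t0)
    log(f"[bicluster] {len(g_bcs)} genotype, {len(l_bcs)} lipidome biclusters")

    # --- relations -----------------------------------------------------
    t0 = time.perf_counter()
    rel_set = relations.find_relations(g_bcs, l_bcs, N=len(shared), alpha=cfg.relation_alpha)
    rel_set = relations.score_distinctness(rel_set)
    multifinal, equifinal = relations.summarize_multifinality(rel_set)
    report.counts["relation_candidates"] = rel_set.counts["candidates"]
    report.counts["significant_relations"] = rel_set.counts["significant"]
    report.counts["distinct_relations"] = rel_set.counts["distinct"]
    report.counts["multifinal_genotype_biclusters"] = multifinal
    report.counts["equifinal_lipidome_biclusters"] = equifinal
    tick("relations", t0)
    log(
        f"[relations] {rel_set.counts['significant']} significant of "
        f"{rel_set.counts['candidates']} candidates; {rel_set.counts['distinct']} distinct"
    )

    # --- per-relation LD pruning --------------------------------------
    t0 = time.perf_counter()
    pruned_relations = []
    for r in rel_set.relations:
        if r.distinct and r.genotype_snps:
            kept = prune_snps(genotype, sorted(r.genotype_snps), cfg.ld)
            r = dataclasses.replace(r, pruned_snps=frozenset(kept))
        pruned_relations.append(r)
    rel_set = relations.RelationSet(
        pruned_relations, rel_set.cohort_size, rel_set.alpha, rel_set.counts
    )
    rel_path = os.path.join(outdir, "relations.tsv")
    io.write_table(rel_set.to_frame(), rel_path)
    artifacts["relations"] = rel_path
    tick("prune", t0)

    # --- clinical comparisons -----------------------------------------
    t0 = time.perf_counter()
    clin_cols = [
        c
        for c in covariates.columns
        if c not in ("sex", "t2d", "lipid_medication") and pd.api.types.is_numeric_dtype(covariates[c])
        and not c.startswith("PC")
    ]
    clin_rows = []
    for r in rel_set.relations:
        if not r.distinct:
            continue
        comp = relations.compare_clinical(r, covariates, variables=clin_cols)
        for _, row in comp.results.iterrows():
            clin_rows.append({"relation_id": r.id, **row.to_dict()})
    clin_frame = pd.DataFrame(clin_rows)
    clin_path = os.path.join(outdir, "clinical_comparisons.tsv")
    io.write_table(clin_frame, clin_path)
    artifacts["clinical"] = clin_path
    tick("clinical", t0)

    # --- enrichment ----------------------------------------------------
    t0 = time.perf_counter()
    snp_gene_map = None
    if cfg.snp_gene_map_path:
        snp_gene_map = io.read_snp_gene_map(cfg.snp_gene_map_path)
    collections = {name: io.read_gmt(path) for name, path in (cfg.gmt_paths or {}).items()}
    if snp_gene_map and collections:
        universe, _ = enrichment.map_snps_to_genes(selected, snp_gene_map)
        results = enrichment.enrich_relations(
            rel_set,
            snp_gene_map,
            collections,
            fdr_max=cfg.fdr_max,
            set_size_bounds=cfg.set_size_bounds,
            universe_genes=universe,
        )
        enr_path = os.path.join(outdir, "enrichment.tsv")
        io.write_table(enrichment.results_to_frame(results), enr_path)
        artifacts["enrichment"] = enr_path
        report.counts["enriched_sets"] = len(results)
        report.counts["relations_with_enrichment"] = len({r.relation_id for r in results})
    else:
        log("[enrich] skipped (no SNP-gene map or gene-set collections supplied)")
    tick("enrich", t0)

    report.timings["total"] = round(time.perf_counter() - t_start, 3)
    report_path = os.path.join(outdir, "run_report.json")
    report.to_json(report_path)
    artifacts["run_report"] = report_path
    return report, artifacts, rel_set
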