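"""Synthetic cohort generator with planted genotype-lipidome subgroups.

The generator emulates the statistical structure the downstream analysis
assumes: Hardy-Weinberg-conforming biallelic SNPs arranged in LD blocks
(haplotype-level allele copying), log-normal lipid concentrations with a
class-structured correlation, clinical covariates on adult-population
scales, and a configurable number of planted subgroups whose members carry
both boosted minor-allele dosages on a private SNP set and an additive
log-scale shift on a private lipid set.  Ground truth is returned so every
downstream stage can be validated against known memberships.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` substreams, so identical configurations
produce bit-identical cohorts and files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io
from .containers import LIPID_CLASSES, GenotypeMatrix, LipidomeMatrix
from .errors import ConfigurationError

CLINICAL_COLUMNS = {
    # mean, sd on adult Finnish-population scales
    "total_cholesterol": (5.0, 0.9),
    "ldl_cholesterol": (3.1, 0.8),
    "hdl_cholesterol": (1.3, 0.3),
    "triglycerides": (1.4, 0.9),
    "glucose": (5.3, 0.8),
    "insulin": (9.0, 8.0),
    "systolic_bp": (120.0, 14.0),
    "diastolic_bp": (75.0, 11.0),
    "crp": (1.7, 4.0),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror a mid-adulthood population cohort: ~1,426 participants
    aged 30-45 (age 38 +/- 5 years, BMI ~26 +/- 5 kg/m^2) profiled on a
    437-species lipid panel.  ``genotype_effect`` is the within-subgroup
    boost of the per-haplotype minor-allele probability on subgroup SNPs;
    ``lipid_effect`` is an additive shift in log-concentration units on
    subgroup lipids; ``noise_sd`` is the residual log-concentration SD.
    """

    n_participants: int = 1426
    n_snps: int = 5000
    n_lipids: int = 437
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 20
    ld_copy_prob: float = 0.9
    n_subgroups: int = 3
    subgroup_size_range: tuple = (100, 200)
    snps_per_subgroup: int = 50
    lipids_per_subgroup: int = 15
    genotype_effect: float = 0.3
    lipid_effect: float = 1.0
    noise_sd: float = 0.5
    class_factor_sd: float = 0.3
    age_lipid_slope: float = 0.0
    covariate_means: dict = field(
        default_factory=lambda: {"age": (38.0, 5.0), "bmi": (26.0, 5.0)}
    )
    couple_domains: bool = True
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_participants": self.n_participants,
            "n_snps": self.n_snps,
            "n_lipids": self.n_lipids,
            "ld_block_size": self.ld_block_size,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name in ("ld_copy_prob", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if self.n_subgroups < 0:
            raise ConfigurationError("n_subgroups must be non-negative")
        if self.n_subgroups > 0:
            slo, shi = self.subgroup_size_range
            if not (1 <= slo <= shi):
                raise ConfigurationError("invalid subgroup_size_range")
            if shi > self.n_participants:
                raise ConfigurationError("subgroup larger than cohort")
            if self.snps_per_subgroup * self.n_subgroups > self.n_snps:
                raise ConfigurationError("subgroup SNP sets exceed n_snps")
            if self.lipids_per_subgroup * self.n_subgroups > self.n_lipids:
                raise ConfigurationError("subgroup lipid sets exceed n_lipids")


@dataclass
class CohortTruth:
    """Planted ground truth: per-subgroup member / SNP / lipid identifier sets.

    When lipid subgroups are decoupled from genotype subgroups
    (``couple_domains=False``), ``lipid_members`` carries the independent
    membership sets that received the lipid effect; otherwise it equals
    ``subgroup_members``.
    """

    subgroup_members: list
    subgroup_snps: list
    subgroup_lipids: list
    lipid_members: list = None

    def __post_init__(self):
        if self.lipid_members is None:
            self.lipid_members = self.subgroup_members


def _simulate_haplotype(rng, n, mafs, block_size, copy_prob):
    """One haplotype per participant; within a block each SNP copies the
    previous SNP's allele with probability ``copy_prob``."""
    m = len(mafs)
    H = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        fresh = (rng.random(n) < mafs[j]).astype(np.int8)
        if j % block_size == 0:
            H[:, j] = fresh
        else:
            copy = rng.random(n) < copy_prob
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def _snp_map(rng, n_snps, block_size):
    """Assign SNPs to chromosomes 1..22 with blocks kept contiguous and
    realistic ~2-10 kb spacing."""
    n_blocks = int(np.ceil(n_snps / block_size))
    block_chrom = np.sort(rng.integers(1, 23, size=n_blocks))
    chrom = np.repeat(block_chrom, block_size)[:n_snps]
    spacing = rng.integers(2_000, 10_000, size=n_snps)
    pos = np.empty(n_snps, dtype=int)
    for c in np.unique(chrom):
        mask = chrom == c
        pos[mask] = 10_000 + np.cumsum(spacing[mask])
    alleles = rng.choice(list("ACGT"), size=(n_snps, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    return pd.DataFrame(
        {
            "id": [f"rs{j + 1:06d}" for j in range(n_snps)],
            "chromosome": chrom.astype(str),
            "position": pos,
            "allele_minor": alleles[:, 0],
            "allele_major": alleles[:, 1],
        }
    )


def _draw_memberships(rng, cfg):
    sizes = rng.integers(
        cfg.subgroup_size_range[0], cfg.subgroup_size_range[1] + 1, size=cfg.n_subgroups
    )
    members = [
        set(rng.choice(cfg.n_participants, size=int(s), replace=False).tolist()) for s in sizes
    ]
    return members


def simulate_cohort(config: CohortConfig):
    """Generate a cohort with planted genotype-lipidome subgroups.

    Returns
    -------
    (GenotypeMatrix, LipidomeMatrix, covariates: DataFrame, CohortTruth)
        Covariates include sex/age/BMI/T2D/lipid-medication plus clinical
        chemistry columns; the truth object records planted memberships as
        participant identifiers (strings), SNP ids and lipid names.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (s_geno, s_lipid, s_covar, s_groups, s_missing) = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]
    n, m, L = cfg.n_participants, cfg.n_snps, cfg.n_lipids
    pids = [f"P{i + 1:05d}" for i in range(n)]

    # --- genotype layer ------------------------------------------------
    mafs = s_geno.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    snps = _snp_map(s_geno, m, cfg.ld_block_size)
    H1 = _simulate_haplotype(s_geno, n, mafs, cfg.ld_block_size, cfg.ld_copy_prob)
    H2 = _simulate_haplotype(s_geno, n, mafs, cfg.ld_block_size, cfg.ld_copy_prob)

    # --- subgroups -----------------------------------------------------
    members = _draw_memberships(s_groups, cfg)
    lipid_members = (
        members if cfg.couple_domains else _draw_memberships(s_groups, cfg)
    )
    snp_pool = s_groups.permutation(m)
    lipid_pool = s_groups.permutation(L)
    sub_snps, sub_lipids = [], []
    for g in range(cfg.n_subgroups):
        sub_snps.append(
            sorted(snp_pool[g * cfg.snps_per_subgroup : (g + 1) * cfg.snps_per_subgroup].tolist())
        )
        sub_lipids.append(
            sorted(
                lipid_pool[g * cfg.lipids_per_subgroup : (g + 1) * cfg.lipids_per_subgroup].tolist()
            )
        )

    # boost minor-allele probability for members on their subgroup SNPs;
    # with genotype_effect == 0 members are redrawn from the null law, so
    # the planted structure vanishes by construction
    for g in range(cfg.n_subgroups):
        rows = np.fromiter(members[g], int)
        cols = np.asarray(sub_snps[g], int)
        p_boost = np.clip(mafs[cols] + cfg.genotype_effect, 0.0, 0.98)
        shape = (len(rows), len(cols))
        H1[np.ix_(rows, cols)] = (s_geno.random(shape) < p_boost).astype(np.int8)
        H2[np.ix_(rows, cols)] = (s_geno.random(shape) < p_boost).astype(np.int8)

    dosages = (H1 + H2).astype(float)
    if cfg.missing_rate > 0:
        mask = s_missing.random((n, m)) < cfg.missing_rate
        dosages[mask] = np.nan
    genotype = GenotypeMatrix(dosages, pids, snps)

    # --- covariates ----------------------------------------------------
    age_mu, age_sd = cfg.covariate_means.get("age", (38.0, 5.0))
    bmi_mu, bmi_sd = cfg.covariate_means.get("bmi", (26.0, 5.0))
    covar = pd.DataFrame(index=pd.Index(pids, name="participant_id"))
    covar["sex"] = (s_covar.random(n) < 0.53).astype(int)  # 1 = female
    covar["age"] = np.clip(s_covar.normal(age_mu, age_sd, n), 18, 80)
    covar["bmi"] = np.clip(s_covar.normal(bmi_mu, bmi_sd, n), 15, 60)
    covar["t2d"] = (s_covar.random(n) < 0.04).astype(int)
    covar["lipid_medication"] = (s_covar.random(n) < 0.05).astype(int)
    for name, (mu, sd) in CLINICAL_COLUMNS.items():
        covar[name] = np.clip(s_covar.normal(mu, sd, n), 0.01, None)

    # --- lipidome layer ------------------------------------------------
    lipid_names = [f"L{j + 1:04d}" for j in range(L)]
    class_idx = s_lipid.integers(0, len(LIPID_CLASSES), size=L)
    classes = pd.Series([LIPID_CLASSES[c] for c in class_idx], index=lipid_names)
    base_mu = s_lipid.normal(1.0, 0.5, size=L)
    class_factor = s_lipid.normal(0.0, 1.0, size=(n, len(LIPID_CLASSES)))
    log_conc = (
        base_mu[None, :]
        + cfg.class_factor_sd * class_factor[:, class_idx]
        + cfg.noise_sd * s_lipid.normal(size=(n, L))
    )
    if cfg.age_lipid_slope:
        log_conc += cfg.age_lipid_slope * (covar["age"].to_numpy() - age_mu)[:, None]
    for g in range(cfg.n_subgroups):
        rows = np.fromiter(lipid_members[g], int)
        log_conc[np.ix_(rows, np.asarray(sub_lipids[g], int))] += cfg.lipid_effect
    lipidome = LipidomeMatrix(
        pd.DataFrame(np.exp(log_conc), index=pd.Index(pids, name="participant_id"), columns=lipid_names),
        classes,
    )

    truth = CohortTruth(
        subgroup_members=[{pids[i] for i in ms} for ms in members],
        subgroup_snps=[{snps["id"].iloc[j] for j in js} for js in sub_snps],
        subgroup_lipids=[{lipid_names[j] for j in js} for js in sub_lipids],
        lipid_members=[{pids[i] for i in ms} for ms in lipid_members],
    )
    return genotype, lipidome, covar, truth


def write_cohort(cohort, directory: str) -> dict:
    """Write a simulated cohort to ``directory`` as plain-text files.

    Returns a mapping of artifact name to file path.  The files round-trip
    losslessly through :func:`read_cohort`.
    """
    genotype, lipidome, covar, truth = cohort
    os.makedirs(directory, exist_ok=True)
    paths = {
        "raw": os.path.join(directory, "genotype.raw"),
        "bim": os.path.join(directory, "genotype.bim"),
        "lipidome": os.path.join(directory, "lipidome.tsv"),
        "lipid_classes": os.path.join(directory, "lipid_classes.tsv"),
        "covariates": os.path.join(directory, "covariates.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    sex = covar["sex"].to_numpy() + 1 if "sex" in covar else None  # PLINK: 1=male, 2=female
    io.write_raw(genotype, paths["raw"], sex=sex)
    io.write_bim(genotype.snps, paths["bim"])
    io.write_lipidome(lipidome, paths["lipidome"], paths["lipid_classes"])
    io.write_table(covar, paths["covariates"], index_label="participant_id")

    rows = []
    for g, (ms, ssnps, slip, lms) in enumerate(
        zip(truth.subgroup_members, truth.subgroup_snps, truth.subgroup_lipids, truth.lipid_members)
    ):
        for p in sorted(ms):
            rows.append((g, "member", p))
        for s in sorted(ssnps):
            rows.append((g, "snp", s))
        for l in sorted(slip):
            rows.append((g, "lipid", l))
        for p in sorted(lms):
            rows.append((g, "lipid_member", p))
    pd.DataFrame(rows, columns=["subgroup", "kind", "identifier"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths


def read_cohort(directory: str):
    """Read back a cohort written by :func:`write_cohort`."""
    genotype = io.read_raw(
        os.path.join(directory, "genotype.raw"), os.path.join(directory, "genotype.bim")
    )
    lipidome = io.read_lipidome(
        os.path.join(directory, "lipidome.tsv"), os.path.join(directory, "lipid_classes.tsv")
    )
    covar = io.read_table(os.path.join(directory, "covariates.tsv"), index_col="participant_id")
    truth_tab = pd.read_csv(os.path.join(directory, "truth.tsv"), sep="\t", dtype={"identifier": str})
    groups = sorted(truth_tab["subgroup"].unique())
    members, snps, lipids, lipid_members = [], [], [], []
    for g in groups:
        sub = truth_tab[truth_tab["subgroup"] == g]
        members.append(set(sub.loc[sub["kind"] == "member", "identifier"]))
        snps.append(set(sub.loc[sub["kind"] == "snp", "identifier"]))
        lipids.append(set(sub.loc[sub["kind"] == "lipid", "identifier"]))
        lipid_members.append(set(sub.loc[sub["kind"] == "lipid_member", "identifier"]))
    truth = CohortTruth(members, snps, lipids, lipid_members)
    return genotype, lipidome, covar, truth


def config_to_dict(cfg: CohortConfig) -> dict:
    return asdict(cfg)
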