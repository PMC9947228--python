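"""Genotype quality control: call rate, HWE, MAF and relatedness filters.

Filters are applied in a fixed order — sample call rate, relatedness
(method-of-moments pi-hat), SNP call rate, Hardy-Weinberg exact test, minor
allele frequency — so that per-SNP statistics are always computed on the
retained sample set.  Missing genotypes are ignored (no imputation at the
QC stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix
from .errors import DomainError, EmptyResultError, UndefinedStatisticError


@dataclass
class QcThresholds:
    """Exclusion thresholds.

    A SNP is removed when HWE exact p <= ``hwe_p_max``, call rate <
    ``snp_call_rate_min`` or MAF < ``maf_min``; a sample is removed when
    call rate < ``sample_call_rate_min``; one member of each pair with
    pi-hat > ``pi_hat_max`` is removed.
    """

    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    hwe_p_max: float = 1.0e-6
    maf_min: float = 0.01
    pi_hat_max: float = 0.2

    def __post_init__(self):
        for name in ("sample_call_rate_min", "snp_call_rate_min", "hwe_p_max", "maf_min", "pi_hat_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must be in [0,1], got {v}")


@dataclass
class QcReport:
    """Removal bookkeeping: identifier -> reason code, plus per-filter counts."""

    removed_samples: dict = field(default_factory=dict)
    removed_snps: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", k, v) for k, v in self.removed_samples.items()]
        rows += [("snp", k, v) for k, v in self.removed_snps.items()]
        return pd.DataFrame(rows, columns=["entity_type", "identifier", "reason"])


def compute_maf(dosages) -> float:
    """Minor-allele frequency of one SNP's dosage vector (missing ignored)."""
    v = np.asarray(dosages, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise UndefinedStatisticError("all genotypes missing; MAF undefined")
    f = v.sum() / (2.0 * v.size)
    return float(min(f, 1.0 - f))


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose probability does not exceed that of the
    observed count (probability ordering, the PLINK-family convention).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise DomainError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise DomainError("need at least one genotype")
    na = 2 * n_AA + n_Aa  # count of allele A
    # heterozygote counts share the parity of the allele count
    hs = np.arange(na % 2, min(na, 2 * n - na) + 1, 2)
    n_AA_h = (na - hs) // 2
    n_aa_h = n - n_AA_h - hs
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA_h + 1)
        - gammaln(hs + 1)
        - gammaln(n_aa_h + 1)
        + hs * np.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hs == n_Aa][0]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _ibs_expectations(freqs):
    """Per-SNP P(IBS=i | IBD=j) for the method-of-moments estimator."""
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    e = {
        (0, 0): 2 * p**2 * q**2,
        (1, 0): 4 * p**3 * q + 4 * p * q**3,
        (2, 0): p**4 + q**4 + 4 * p**2 * q**2,
        (1, 1): 2 * p**2 * q + 2 * p * q**2,
        (2, 1): p**3 + q**3 + p**2 * q + p * q**2,
    }
    return e


def estimate_pi_hat(g_i, g_j, allele_freqs) -> float:
    """Method-of-moments IBD-sharing estimate for one sample pair.

    ``allele_freqs`` are the frequencies of the dosage-counted allele, one
    per SNP, strictly inside (0,1).  SNPs missing in either sample are
    dropped pairwise.  P(IBD=0,1,2) are solved from observed vs expected
    identity-by-state counts, clamped to [0,1] and renormalized;
    pi-hat = P(IBD=1)/2 + P(IBD=2).
    """
    gi = np.asarray(g_i, dtype=float)
    gj = np.asarray(g_j, dtype=float)
    if gi.shape != gj.shape:
        raise DomainError("dosage vectors differ in length")
    p = np.asarray(allele_freqs, dtype=float)
    keep = ~np.isnan(gi) & ~np.isnan(gj) & (p > 0) & (p < 1)
    gi, gj, p = gi[keep], gj[keep], p[keep]
    if gi.size == 0:
        raise UndefinedStatisticError("no informative SNPs for pi-hat")
    ibs = 2 - np.abs(gi - gj)
    N0 = float((ibs == 0).sum())
    N1 = float((ibs == 1).sum())
    N2 = float((ibs == 2).sum())
    e = _ibs_expectations(p)
    E00, E10, E20 = e[(0, 0)].sum(), e[(1, 0)].sum(), e[(2, 0)].sum()
    E11, E21 = e[(1, 1)].sum(), e[(2, 1)].sum()
    M = float(gi.size)
    z0 = N0 / E00 if E00 > 0 else 0.0
    z1 = (N1 - z0 * E10) / E11 if E11 > 0 else 0.0
    z2 = (N2 - z0 * E20 - z1 * E21) / M
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    total = z.sum()
    if total <= 0:
        return 0.0
    z = z / total
    return float(z[1] / 2.0 + z[2])


def pairwise_pi_hat(dosages, allele_freqs) -> np.ndarray:
    """Pi-hat for every sample pair (vectorized over the IBS count step).

    Missing calls are dropped pairwise via indicator products; returns a
    symmetric n x n matrix with zeros on the diagonal.
    """
    G = np.asarray(dosages, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    informative = (p > 0) & (p < 1)
    G = G[:, informative]
    p = p[informative]
    n = G.shape[0]
    A = [np.where(np.isnan(G), 0.0, (G == v).astype(float)) for v in (0.0, 1.0, 2.0)]
    V = (~np.isnan(G)).astype(float)
    N0 = A[0] @ A[2].T + A[2] @ A[0].T
    N1 = A[0] @ A[1].T + A[1] @ A[0].T + A[1] @ A[2].T + A[2] @ A[1].T
    N2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T
    e = _ibs_expectations(p)
    # per-pair expected counts restricted to jointly observed SNPs
    def pair_sum(w):
        return (V * w[None, :]) @ V.T

    E00, E10, E20 = pair_sum(e[(0, 0)]), pair_sum(e[(1, 0)]), pair_sum(e[(2, 0)])
    E11, E21 = pair_sum(e[(1, 1)]), pair_sum(e[(2, 1)])
    M = V @ V.T
    with np.errstate(divide="ignore", invalid="ignore"):
        z0 = np.where(E00 > 0, N0 / E00, 0.0)
        z1 = np.where(E11 > 0, (N1 - z0 * E10) / E11, 0.0)
        z2 = np.where(M > 0, (N2 - z0 * E20 - z1 * E21) / M, 0.0)
    z0, z1, z2 = (np.clip(z, 0.0, 1.0) for z in (z0, z1, z2))
    total = z0 + z1 + z2
    total = np.where(total > 0, total, 1.0)
    pi = (z1 / 2.0 + z2) / total * (z0 + z1 + z2 > 0)
    np.fill_diagonal(pi, 0.0)
    return pi


def run_qc(genotype: GenotypeMatrix, thresholds: QcThresholds = None):
    """Apply the full QC cascade; returns (filtered matrix, QcReport)."""
    thr = thresholds or QcThresholds()
    report = QcReport()
    G = genotype.dosages
    pids = genotype.participant_ids

    # 1. sample call rate
    sample_cr = 1.0 - np.isnan(G).mean(axis=1)
    keep_sample = sample_cr >= thr.sample_call_rate_min
    for pid, ok in zip(pids, keep_sample):
        if not ok:
            report.removed_samples[pid] = "call_rate"
    gm = genotype.subset(participant_mask=keep_sample)
    sample_cr = sample_cr[keep_sample]

    # 2. relatedness on the post-call-rate matrix
    if gm.n_participants > 1:
        with np.errstate(invalid="ignore"):
            freqs = np.nanmean(gm.dosages, axis=0) / 2.0
        pi = pairwise_pi_hat(gm.dosages, freqs)
        flagged = np.argwhere(np.triu(pi > thr.pi_hat_max, k=1))
        alive = set(range(gm.n_participants))
        for i, j in flagged:
            if i in alive and j in alive:
                # drop the lower-call-rate member; ties keep the earlier id
                if sample_cr[i] < sample_cr[j]:
                    drop = i
                elif sample_cr[j] < sample_cr[i]:
                    drop = j
                else:
                    drop = max(i, j, key=lambda k: gm.participant_ids[k])
                alive.discard(drop)
                report.removed_samples[gm.participant_ids[drop]] = "relatedness"
        keep = np.zeros(gm.n_participants, bool)
        keep[list(alive)] = True
        gm = gm.subset(participant_mask=keep)

    if gm.n_participants == 0:
        raise EmptyResultError("all samples removed by QC", report)

    # 3-5. SNP filters on retained samples
    G = gm.dosages
    n = gm.n_participants
    snp_cr = 1.0 - np.isnan(G).mean(axis=0)
    keep_snp = np.ones(gm.n_snps, bool)
    snp_ids = gm.snp_ids
    for j in np.nonzero(snp_cr < thr.snp_call_rate_min)[0]:
        keep_snp[j] = False
        report.removed_snps[snp_ids[j]] = "call_rate"
    for j in np.nonzero(keep_snp)[0]:
        col = G[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            keep_snp[j] = False
            report.removed_snps[snp_ids[j]] = "call_rate"
            continue
        n_aa = int((col == 0).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        if hwe_exact_test(n_AA, n_Aa, n_aa) <= thr.hwe_p_max:
            keep_snp[j] = False
            report.removed_snps[snp_ids[j]] = "hwe"
            continue
        if compute_maf(col) < thr.maf_min:
            keep_snp[j] = False
            report.removed_snps[snp_ids[j]] = "maf"
    gm = gm.subset(snp_mask=keep_snp)

    reasons_s = pd.Series(list(report.removed_samples.values()), dtype=object)
    reasons_v = pd.Series(list(report.removed_snps.values()), dtype=object)
    report.counts = {
        "input_samples": genotype.n_participants,
        "input_snps": genotype.n_snps,
        "removed_samples_call_rate": int((reasons_s == "call_rate").sum()),
        "removed_samples_relatedness": int((reasons_s == "relatedness").sum()),
        "removed_snps_call_rate": int((reasons_v == "call_rate").sum()),
        "removed_snps_hwe": int((reasons_v == "hwe").sum()),
        "removed_snps_maf": int((reasons_v == "maf").sum()),
        "retained_samples": gm.n_participants,
        "retained_snps": gm.n_snps,
    }
    return gm, report
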