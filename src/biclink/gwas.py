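"""Covariate-adjusted association scan between SNP dosages and lipid species.

Each (SNP, lipid) pair is fit by ordinary least squares,
``lipid ~ intercept + dosage + covariates``, on complete cases; the dosage
term's effect, standard error and two-sided t-distribution p-value are
reported.  For fully observed dosage columns the scan is vectorized via the
Frisch-Waugh-Lovell decomposition (residualize dosages and lipids against
the covariate design once, then sweep all pairs with matrix products),
which is numerically identical to the per-pair fit.  Genetic principal
components are computed by SVD of the standardized, mean-imputed dosage
matrix, optionally on an LD-thinned SNP subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import GenotypeMatrix, LipidomeMatrix
from .errors import AlignmentError, DomainError, UndefinedStatisticError
from .ld import LdParams, prune_snps

P_FLOOR = 1e-300  # keep reported p-values inside (0, 1]


@dataclass
class GwasRecord:
    snp: str
    lipid: str
    beta: float
    se: float
    p: float
    n: int


@dataclass
class GwasTable:
    """Association records as a DataFrame (snp, lipid, beta, se, p, n)."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.records.duplicated(subset=["snp", "lipid"]).any():
            raise DomainError("duplicate (snp, lipid) records")

    def min_p_per_snp(self) -> pd.Series:
        return self.records.groupby("snp", sort=True)["p"].min()


def compute_pcs(genotype: GenotypeMatrix, k: int, ld_thin_r2: float | None = 0.5) -> np.ndarray:
    """First ``k`` genetic principal-component scores (participants x k).

    The dosage matrix is mean-imputed, column-standardized and decomposed
    by SVD; scores are ordered by decreasing explained variance.  By
    default the input SNPs are first LD-thinned by windowed pruning at
    r² = ``ld_thin_r2`` to damp local-LD artifacts (pass None to skip).
    """
    gm = genotype
    if ld_thin_r2 is not None and gm.n_snps > 1:
        kept = prune_snps(gm, gm.snp_ids, LdParams(prune_r2=ld_thin_r2))
        gm = gm.subset_snp_ids(kept)
    G = gm.dosages.copy()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(G, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(G))
    G[nan_rows, nan_cols] = col_mean[nan_cols]
    sd = G.std(axis=0)
    ok = sd > 0
    Z = (G[:, ok] - G[:, ok].mean(axis=0)) / sd[ok]
    n = Z.shape[0]
    if k > min(Z.shape):
        raise DomainError(f"k={k} exceeds matrix rank bound {min(Z.shape)}")
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    if k > rank:
        raise DomainError(f"k={k} exceeds numerical rank {rank}")
    return U[:, :k] * S[:k]


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    return np.column_stack([np.ones(len(C)), C])


def fit_snp_lipid(dosage, lipid_values, covariates: pd.DataFrame | None = None) -> GwasRecord:
    """OLS fit of one (SNP, lipid) pair on complete cases."""
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(lipid_values, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    if cov is not None:
        keep &= ~np.isnan(cov).any(axis=1)
    x, y = x[keep], y[keep]
    if np.unique(x).size < 2:
        raise UndefinedStatisticError("monomorphic SNP in analyzed samples")
    X = np.column_stack([np.ones(x.size), x] + ([] if cov is None else [cov[keep]]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DomainError("rank-deficient design (collinear covariates)")
    fit = sm.OLS(y, X).fit()
    p = float(max(fit.pvalues[1], P_FLOOR))
    return GwasRecord("", "", float(fit.params[1]), float(fit.bse[1]), p, int(x.size))


def run_gwas(
    genotype: GenotypeMatrix, lipidome: LipidomeMatrix, covariates: pd.DataFrame | None = None
) -> GwasTable:
    """Full scan over every (SNP, lipid) pair.

    Monomorphic SNPs are skipped.  Participants are aligned by identifier
    (inner join); rows with any missing covariate or lipid value are
    dropped globally, while missing dosages trigger a per-pair
    complete-case fallback fit for the affected SNPs.
    """
    shared = [p for p in genotype.participant_ids if p in set(lipidome.participant_ids)]
    if covariates is not None:
        shared = [p for p in shared if p in set(covariates.index)]
    if not shared:
        raise AlignmentError("no overlapping participants between inputs")
    g_pos = {p: i for i, p in enumerate(genotype.participant_ids)}
    G = genotype.dosages[[g_pos[p] for p in shared]]
    Y = lipidome.concentrations.loc[shared].to_numpy(float)
    C = None if covariates is None else covariates.loc[shared].astype(float)
    if C is not None and C.isna().any().any():
        ok = ~C.isna().any(axis=1).to_numpy()
        G, Y, C = G[ok], Y[ok], C[ok]
    D = _design(C, G.shape[0])
    n, m = G.shape
    L = Y.shape[1]
    p_model = D.shape[1] + 1
    df = n - p_model
    if df < 1:
        raise DomainError("not enough samples for the model")

    snp_ids = genotype.snp_ids
    lipids = lipidome.lipid_names
    complete = ~np.isnan(G).any(axis=0)
    frames = []

    if complete.any():
        Gc = G[:, complete]
        # Frisch-Waugh-Lovell: residualize both sides against the covariates
        Q, _ = np.linalg.qr(D)
        Xr = Gc - Q @ (Q.T @ Gc)
        Yr = Y - Q @ (Q.T @ Y)
        sxx = (Xr**2).sum(axis=0)
        poly = sxx > 1e-12  # monomorphic => zero residual variance
        Xr = Xr[:, poly]
        sxx = sxx[poly]
        sxy = Xr.T @ Yr
        syy = (Yr**2).sum(axis=0)
        beta = sxy / sxx[:, None]
        rss = np.maximum(syy[None, :] - beta * sxy, 0.0)
        sigma2 = rss / df
        se = np.sqrt(np.maximum(sigma2 / sxx[:, None], 1e-300))
        tval = beta / se
        pval = np.maximum(2.0 * stats.t.sf(np.abs(tval), df), P_FLOOR)
        ids = [sid for sid, c in zip(snp_ids, complete) if c]
        ids = [sid for sid, keep in zip(ids, poly) if keep]
        frames.append(
            pd.DataFrame(
                {
                    "snp": np.repeat(ids, L),
                    "lipid": np.tile(lipids, len(ids)),
                    "beta": beta.ravel(),
                    "se": se.ravel(),
                    "p": pval.ravel(),
                    "n": n,
                }
            )
        )

    rows = []
    for j in np.nonzero(~complete)[0]:
        for l, lip in enumerate(lipids):
            try:
                rec = fit_snp_lipid(G[:, j], Y[:, l], C)
            except (UndefinedStatisticError, DomainError):
                continue
            rows.append((snp_ids[j], lip, rec.beta, rec.se, rec.p, rec.n))
    if rows:
        frames.append(pd.DataFrame(rows, columns=["snp", "lipid", "beta", "se", "p", "n"]))

    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["snp", "lipid", "beta", "se", "p", "n"])
    )
    records = records.sort_values(["snp", "lipid"], kind="mergesort").reset_index(drop=True)
    return GwasTable(records, provenance={"n_participants": n, "n_snps": m, "n_lipids": L})


def preselect_snps(table: GwasTable, p_threshold: float = 5e-4, cap: int = 20_000) -> list:
    """SNPs with any association below ``p_threshold``, capped at ``cap``.

    When more than ``cap`` SNPs qualify, the ``cap`` SNPs with the smallest
    per-SNP minimum p are kept (ties broken by identifier order).  Returns
    identifiers sorted by identifier.
    """
    if table.records.empty:
        return []
    min_p = table.min_p_per_snp()
    passing = min_p[min_p < p_threshold]
    if len(passing) > cap:
        ranked = sorted(passing.index, key=lambda s: (passing[s], s))[:cap]
        passing = passing[ranked]
    return sorted(passing.index)


def study_wide_threshold(genomewide_alpha: float = 5e-8, n_phenotypes: int = 437) -> float:
    """Bonferroni study-wide threshold, reported to two significant figures."""
    if not 0 < genomewide_alpha < 1 or n_phenotypes < 1:
        raise DomainError("alpha in (0,1) and n_phenotypes >= 1 required")
    return float(f"{genomewide_alpha / n_phenotypes:.1e}")
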