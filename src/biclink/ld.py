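"""Linkage-disequilibrium utilities: pairwise r², windowed pruning, clumping.

Pruning removes correlated SNPs by r² alone inside a sliding SNP-count
window, keeping the larger-MAF member of each offending pair.  Clumping
walks GWAS hits in ascending p-value order and absorbs correlated SNPs
within a physical window around each index SNP, so the most significant
SNP per LD region survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import DomainError, LookupError_, UndefinedStatisticError
from .qc import compute_maf


@dataclass
class LdParams:
    """Pruning/clumping parameters.

    ``prune_window``/``prune_step`` are SNP counts; ``clump_window_kb`` is a
    physical distance.  Defaults: prune at r² > 0.5 in 50-SNP windows
    stepping by 5; clump at r² >= 0.1 within 250 kb.
    """

    prune_r2: float = 0.5
    prune_window: int = 50
    prune_step: int = 5
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0

    def __post_init__(self):
        for name in ("prune_r2", "clump_r2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise DomainError(f"{name} must be in (0,1], got {v}")
        if self.prune_window < 1 or self.prune_step < 1:
            raise DomainError("windows and steps must be >= 1")
        if self.clump_window_kb <= 0:
            raise DomainError("clump_window_kb must be positive")


def ld_r2(g1, g2) -> float:
    """Squared Pearson correlation of two dosage vectors over complete pairs."""
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise DomainError("dosage vectors differ in length")
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("zero variance; r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2(G) -> np.ndarray:
    """Pairwise-complete dosage r² for the columns of G.

    Matches :func:`ld_r2` pairwise; zero-variance or undefined pairs get 0.
    """
    X = np.asarray(G, dtype=float)
    if np.isnan(X).any():
        C = np.ma.corrcoef(np.ma.masked_invalid(X), rowvar=False)
        r2 = np.asarray(C.filled(0.0)) ** 2
    else:
        sd = X.std(axis=0)
        ok = sd > 0
        r2 = np.zeros((X.shape[1], X.shape[1]))
        if ok.sum() >= 1:
            C = np.corrcoef(X[:, ok], rowvar=False)
            C = np.atleast_2d(C)
            r2[np.ix_(ok, ok)] = C**2
    np.fill_diagonal(r2, 1.0)
    return r2


def _sorted_subset(genotype: GenotypeMatrix, snp_subset):
    """Indices of the subset sorted by (chromosome, position)."""
    id_to_idx = {sid: j for j, sid in enumerate(genotype.snp_ids)}
    missing = [s for s in snp_subset if s not in id_to_idx]
    if missing:
        raise LookupError_(f"unknown SNP ids: {missing[:3]}")
    idx = [id_to_idx[s] for s in snp_subset]
    snps = genotype.snps.iloc[idx]

    def chrom_key(c):
        try:
            return (0, int(c))
        except (TypeError, ValueError):
            return (1, str(c))

    order = sorted(
        range(len(idx)),
        key=lambda t: (chrom_key(snps.iloc[t]["chromosome"]), int(snps.iloc[t]["position"])),
    )
    return [idx[t] for t in order]


def prune_snps(genotype: GenotypeMatrix, snp_subset, params: LdParams = None) -> set:
    """Windowed greedy LD pruning of ``snp_subset``; returns retained ids.

    Within each window of ``prune_window`` SNPs, while any retained pair
    exceeds ``prune_r2`` the member with the smaller MAF is dropped (ties:
    the later-position member); the window then advances by ``prune_step``.
    """
    params = params or LdParams()
    idx = _sorted_subset(genotype, snp_subset)
    if not idx:
        return set()
    G = genotype.dosages[:, idx]
    chroms = genotype.snps["chromosome"].to_numpy()[idx]
    mafs = np.array([compute_maf(G[:, t]) for t in range(len(idx))])
    alive = np.ones(len(idx), bool)
    m = len(idx)
    start = 0
    while start < m:
        stop = min(start + params.prune_window, m)
        window = [t for t in range(start, stop) if alive[t]]
        if len(window) > 1:
            r2 = _pairwise_r2(G[:, window])
            same_chrom = chroms[window][:, None] == chroms[window][None, :]
            r2 = np.where(same_chrom, r2, 0.0)  # never prune across chromosomes
            np.fill_diagonal(r2, 0.0)
            local_alive = np.ones(len(window), bool)
            while True:
                masked = np.where(np.outer(local_alive, local_alive), r2, 0.0)
                a, b = np.unravel_index(np.argmax(masked), masked.shape)
                if masked[a, b] <= params.prune_r2:
                    break
                ga, gb = window[a], window[b]
                if mafs[ga] < mafs[gb]:
                    drop = a
                elif mafs[gb] < mafs[ga]:
                    drop = b
                else:
                    drop = max(a, b)  # tie: later position
                local_alive[drop] = False
                alive[window[drop]] = False
        if stop >= m:
            break
        start += params.prune_step
    snp_ids = genotype.snps["id"].to_numpy()
    return {snp_ids[idx[t]] for t in range(m) if alive[t]}


def clump_snps(gwas_table, genotype: GenotypeMatrix, params: LdParams = None) -> pd.DataFrame:
    """Greedy p-value-driven clumping of GWAS SNPs.

    Uses the per-SNP minimum p-value across phenotypes.  Returns a
    DataFrame with columns ``snp, chromosome, position, index_snp`` where
    ``index_snp == snp`` marks clump indices.
    """
    params = params or LdParams()
    records = gwas_table.records if hasattr(gwas_table, "records") else gwas_table
    min_p = records.groupby("snp", sort=True)["p"].min()
    id_to_idx = {sid: j for j, sid in enumerate(genotype.snp_ids)}
    missing = [s for s in min_p.index if s not in id_to_idx]
    if missing:
        raise LookupError_(f"GWAS SNPs absent from genotype matrix: {missing[:3]}")
    order = sorted(min_p.index, key=lambda s: (min_p[s], s))
    snps = genotype.snps
    pos = {s: int(snps.iloc[id_to_idx[s]]["position"]) for s in order}
    chrom = {s: str(snps.iloc[id_to_idx[s]]["chromosome"]) for s in order}
    window_bp = params.clump_window_kb * 1000.0
    assigned: dict = {}
    for s in order:
        if s in assigned:
            continue
        assigned[s] = s  # new index SNP
        gs = genotype.dosages[:, id_to_idx[s]]
        for t in order:
            if t in assigned or chrom[t] != chrom[s] or abs(pos[t] - pos[s]) > window_bp:
                continue
            try:
                if ld_r2(gs, genotype.dosages[:, id_to_idx[t]]) >= params.clump_r2:
                    assigned[t] = s
            except UndefinedStatisticError:
                continue
    out = pd.DataFrame(
        {
            "snp": list(assigned.keys()),
            "chromosome": [chrom[s] for s in assigned],
            "position": [pos[s] for s in assigned],
            "index_snp": list(assigned.values()),
        }
    )
    return out.sort_values(["index_snp", "snp"]).reset_index(drop=True)
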