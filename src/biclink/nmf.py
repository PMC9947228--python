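"""Fuzzy biclustering by non-negative matrix factorization.

A participants-by-features matrix X >= 0 is factorized as X ~ W H with
W (participants x rank) and H (rank x features) non-negative, by Frobenius
multiplicative updates from a non-negative double-SVD initialization.  Each
factor k induces one bicluster: the participants whose loading W[i,k] is at
least a fraction of their row maximum, paired with the features selected
analogously from H.  Because the threshold is relative rather than a hard
assignment, one participant or feature can belong to several biclusters
("fuzzy" membership).  Running the factorization over a grid of ranks and
deduplicating near-identical biclusters yields the multi-rank bicluster
inventory used by the relation analysis.

The multiplicative updates never increase the Frobenius objective, so the
recorded error history is non-increasing; a small epsilon floor inside the
update ratios guards against division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, LipidomeMatrix
from .errors import ConfigurationError, DomainError, UndefinedStatisticError

EPS = 1e-12

DOMAIN_PREFIX = {"genotype": "G", "lipidome": "P"}


@dataclass
class FactorPair:
    """One NMF solution: X ~ W H at a given rank."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    final_error: float
    seed: int
    n_iter: int
    error_history: np.ndarray = None


@dataclass
class Bicluster:
    """A (participant set, feature set) pair extracted from one NMF factor.

    ``id`` encodes domain, rank and factor index, e.g. ``G12.1`` for the
    first factor of the rank-12 genotype factorization.  ``mean_loading``
    is the average row-normalized membership weight of the bicluster's
    participants and features and is used to break ties at deduplication.
    """

    id: str
    domain: str
    participants: frozenset
    features: frozenset
    mean_loading: float


@dataclass
class BiclusterSet:
    domain: str
    biclusters: list
    rank_grid: tuple = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [b.id for b in self.biclusters]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate bicluster ids")

    def __len__(self):
        return len(self.biclusters)

    def by_id(self) -> dict:
        return {b.id: b for b in self.biclusters}

    def to_frames(self):
        """(bicluster-participant, bicluster-feature) long-format tables."""
        prows = [(b.id, p) for b in self.biclusters for p in sorted(b.participants)]
        frows = [(b.id, f) for b in self.biclusters for f in sorted(b.features)]
        return (
            pd.DataFrame(prows, columns=["bicluster_id", "participant_id"]),
            pd.DataFrame(frows, columns=["bicluster_id", "feature_id"]),
        )


def bicluster_set_from_frames(domain: str, participants: pd.DataFrame, features: pd.DataFrame) -> BiclusterSet:
    """Rebuild a BiclusterSet from the long-format TSV frames written by
    :meth:`BiclusterSet.to_frames` (mean loadings are not serialized and
    default to 1.0)."""
    p_by_id = participants.groupby("bicluster_id")["participant_id"].apply(frozenset)
    f_by_id = features.groupby("bicluster_id")["feature_id"].apply(frozenset)
    ids = sorted(set(p_by_id.index) | set(f_by_id.index))
    bcs = [
        Bicluster(
            id=i,
            domain=domain,
            participants=p_by_id.get(i, frozenset()),
            features=f_by_id.get(i, frozenset()),
            mean_loading=1.0,
        )
        for i in ids
    ]
    return BiclusterSet(domain, bcs)


def _nndsvd_init(X, rank, rng):
    """Non-negative double SVD initialization; random-uniform fallback for
    components the SVD leaves empty."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n, m = X.shape
    W = np.zeros((n, rank))
    H = np.zeros((rank, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for k in range(1, min(rank, len(S))):
        u, v = U[:, k], Vt[k, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        np_norm, nn_norm = np.linalg.norm(up) * np.linalg.norm(vp), np.linalg.norm(un) * np.linalg.norm(vn)
        if np_norm >= nn_norm and np_norm > 0:
            W[:, k] = np.sqrt(S[k] * np_norm) * up / max(np.linalg.norm(up), EPS)
            H[k, :] = np.sqrt(S[k] * np_norm) * vp / max(np.linalg.norm(vp), EPS)
        elif nn_norm > 0:
            W[:, k] = np.sqrt(S[k] * nn_norm) * un / max(np.linalg.norm(un), EPS)
            H[k, :] = np.sqrt(S[k] * nn_norm) * vn / max(np.linalg.norm(vn), EPS)
    scale = X.mean() or 1.0
    for k in range(rank):
        if W[:, k].max() <= 0 or H[k, :].max() <= 0:
            W[:, k] = rng.uniform(0, np.sqrt(scale), n)
            H[k, :] = rng.uniform(0, np.sqrt(scale), m)
    # fill remaining zeros with the matrix mean ("nndsvda"): exact zeros are
    # absorbing states for multiplicative updates and trap poor local minima
    W[W <= 0] = scale
    H[H <= 0] = scale
    return W, H


def nmf_factorize(X, rank: int, seed: int = 0, max_iter: int = 500, tol: float = 1e-6) -> FactorPair:
    """Multiplicative-update NMF minimizing the Frobenius error.

    Stops when the relative error decrease falls below ``tol`` or after
    ``max_iter`` iterations.  The error history (including the initial
    error) is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise DomainError("NMF input must be complete (no missing values)")
    if (X < 0).any():
        raise DomainError("NMF input must be non-negative")
    if not 1 <= rank <= min(X.shape):
        raise DomainError(f"rank {rank} infeasible for shape {X.shape}")
    rng = np.random.default_rng(seed)
    W, H = _nndsvd_init(X, rank, rng)
    err = np.linalg.norm(X - W @ H)
    history = [err]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + EPS)
        new_err = np.linalg.norm(X - W @ H)
        history.append(new_err)
        if err > 0 and (err - new_err) / max(err, EPS) < tol:
            err = new_err
            break
        err = new_err
    return FactorPair(W, H, rank, float(err), seed, n_iter, np.asarray(history))


def extract_biclusters(
    fp: FactorPair,
    membership_fraction: float = 0.5,
    *,
    domain: str = "genotype",
    participant_ids=None,
    feature_ids=None,
    id_prefix: str | None = None,
) -> list:
    """Soft-threshold the factor loadings into biclusters.

    Participant i joins factor k iff ``W[i,k] >= membership_fraction *
    max_i' W[i',k]`` and ``W[i,k] > 0`` — i.e. the threshold is relative
    to the factor's strongest participant loading; features analogously
    from the rows of H.  The threshold is soft, so one participant or
    feature can clear it in several factors at once (fuzzy membership).
    Factors with an empty participant or feature set are dropped.
    """
    if not 0 < membership_fraction <= 1:
        raise DomainError("membership_fraction must be in (0,1]")
    W, H = fp.W, fp.H
    n, m = W.shape[0], H.shape[1]
    pids = list(participant_ids) if participant_ids is not None else list(range(n))
    fids = list(feature_ids) if feature_ids is not None else list(range(m))
    prefix = id_prefix if id_prefix is not None else DOMAIN_PREFIX.get(domain, "B")
    w_max = W.max(axis=0, keepdims=True)  # strongest loading per factor
    h_max = H.max(axis=1, keepdims=True)
    w_member = (W >= membership_fraction * w_max) & (W > 0)
    h_member = (H >= membership_fraction * h_max) & (H > 0)
    out = []
    for k in range(fp.rank):
        rows = np.nonzero(w_member[:, k])[0]
        cols = np.nonzero(h_member[k, :])[0]
        if rows.size == 0 or cols.size == 0:
            continue
        w_norm = W[rows, k] / max(w_max[0, k], EPS)
        h_norm = H[k, cols] / max(h_max[k, 0], EPS)
        out.append(
            Bicluster(
                id=f"{prefix}{fp.rank}.{k + 1}",
                domain=domain,
                participants=frozenset(pids[i] for i in rows),
                features=frozenset(fids[j] for j in cols),
                mean_loading=float((w_norm.mean() + h_norm.mean()) / 2.0),
            )
        )
    return out


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def dedup_biclusters(biclusters, dedup_jaccard: float = 0.9) -> list:
    """Drop near-duplicates: when both the participant-set and feature-set
    Jaccard similarities reach ``dedup_jaccard``, keep the bicluster with
    the larger mean loading (ties: the earlier id)."""
    ranked = sorted(biclusters, key=lambda b: (-b.mean_loading, b.id))
    kept = []
    for b in ranked:
        if any(
            _jaccard(b.participants, k.participants) >= dedup_jaccard
            and _jaccard(b.features, k.features) >= dedup_jaccard
            for k in kept
        ):
            continue
        kept.append(b)
    kept.sort(key=lambda b: b.id)
    return kept


def multilayer_biclustering(
    X,
    rank_grid=None,
    seed: int = 0,
    membership_fraction: float = 0.5,
    dedup_jaccard: float = 0.9,
    *,
    domain: str = "genotype",
    participant_ids=None,
    feature_ids=None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> BiclusterSet:
    """Factorize at every rank in ``rank_grid`` (default 2..20, clipped to
    the matrix dimensions), extract biclusters and deduplicate across ranks."""
    X = np.asarray(X, dtype=float)
    grid = tuple(rank_grid) if rank_grid is not None else tuple(range(2, 21))
    grid = tuple(r for r in grid if 1 <= r <= min(X.shape))
    if not grid:
        raise ConfigurationError("empty or infeasible rank grid")
    children = np.random.SeedSequence(seed).spawn(len(grid))
    all_bcs = []
    for r, child in zip(grid, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        fp = nmf_factorize(X, r, seed=sub_seed, max_iter=max_iter, tol=tol)
        all_bcs.extend(
            extract_biclusters(
                fp,
                membership_fraction,
                domain=domain,
                participant_ids=participant_ids,
                feature_ids=feature_ids,
            )
        )
    kept = dedup_biclusters(all_bcs, dedup_jaccard)
    return BiclusterSet(
        domain,
        kept,
        rank_grid=grid,
        params={"membership_fraction": membership_fraction, "dedup_jaccard": dedup_jaccard},
    )


def prepare_genotype_matrix(genotype: GenotypeMatrix) -> np.ndarray:
    """Mean-impute missing dosages; keep the 0-2 scale (already non-negative)."""
    G = genotype.dosages.copy()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(G, axis=0)
    if np.isnan(col_mean).any():
        raise UndefinedStatisticError("SNP column with all genotypes missing")
    r, c = np.nonzero(np.isnan(G))
    G[r, c] = col_mean[c]
    return G


def prepare_lipidome_matrix(lipidome: LipidomeMatrix) -> np.ndarray:
    """Per-lipid min-max scaling to [0,1]; constant columns map to 0."""
    Y = lipidome.concentrations.to_numpy(float).copy()
    lo = Y.min(axis=0)
    span = Y.max(axis=0) - lo
    span[span == 0] = 1.0
    return (Y - lo) / span


def prepare_matrix(matrix) -> np.ndarray:
    """Dispatch to the domain-appropriate non-negative preparation."""
    if isinstance(matrix, GenotypeMatrix):
        return prepare_genotype_matrix(matrix)
    if isinstance(matrix, LipidomeMatrix):
        return prepare_lipidome_matrix(matrix)
    raise DomainError(f"unsupported matrix type: {type(matrix)!r}")
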