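"""Many-to-many relation detection between genotype and lipidome biclusters.

Every genotype x lipidome bicluster pair is tested for an excess of shared
participants with the hypergeometric upper tail: drawing n participants
(the lipidome bicluster) from a cohort of N containing K marked ones (the
genotype bicluster), the p-value is P(X >= k) for the observed overlap k.
Significant relations (raw p below alpha, uncorrected by default) are then
screened for distinctness — a relation is distinct when more than half of
its genotype bicluster's SNPs and participants appear in no other
significant relation's genotype bicluster — and compared against clinical
variables with Welch's two-sample t-test (bicluster members vs the rest of
the cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, UndefinedStatisticError
from .nmf import BiclusterSet

P_MIN = 5e-324  # smallest positive double; keeps p inside (0, 1]


@dataclass
class Relation:
    """A significant genotype-lipidome bicluster pairing."""

    id: str
    genotype_bicluster_id: str
    lipidome_bicluster_id: str
    shared_participants: frozenset
    k: int
    p_hypergeom: float
    genotype_participants: frozenset = frozenset()
    genotype_snps: frozenset = frozenset()
    lipidome_lipids: frozenset = frozenset()
    pruned_snps: frozenset = None
    unique_snp_fraction: float = None
    unique_participant_fraction: float = None
    distinct: bool = False


@dataclass
class RelationSet:
    relations: list
    cohort_size: int
    alpha: float
    counts: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.relations)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.relations:
            rows.append(
                {
                    "relation_id": r.id,
                    "genotype_bicluster": r.genotype_bicluster_id,
                    "lipidome_bicluster": r.lipidome_bicluster_id,
                    "shared_participants": r.k,
                    "n_snps": len(r.genotype_snps),
                    "n_independent_snps": len(r.pruned_snps) if r.pruned_snps is not None else pd.NA,
                    "n_lipids": len(r.lipidome_lipids),
                    "p_hypergeom": r.p_hypergeom,
                    "unique_snp_fraction": r.unique_snp_fraction,
                    "unique_participant_fraction": r.unique_participant_fraction,
                    "distinct": r.distinct,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ClinicalComparison:
    """Per-variable Welch t-test of bicluster members vs the rest."""

    relation_id: str
    results: pd.DataFrame  # variable, t, p, mean_members, mean_rest, n_members, n_rest


def hypergeom_overlap_p(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts marked members among n draws without replacement from a
    population of N containing K marked members.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise DomainError(f"overlap k={k} outside [0, min(K,n)]")
    if k == 0:
        return 1.0
    # survival function evaluated in log space to survive extreme tails
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return float(min(max(np.exp(logp), P_MIN), 1.0))


def find_relations(
    g_set: BiclusterSet, l_set: BiclusterSet, N: int, alpha: float = 0.01
) -> RelationSet:
    """Test every genotype x lipidome bicluster pair; keep pairs with raw
    hypergeometric p below ``alpha``.

    Relation ids R1, R2, ... are assigned by ascending p-value with a
    stable tie-break on the (genotype, lipidome) bicluster ids.
    """
    if not 0 < alpha <= 1:
        raise DomainError("alpha must be in (0,1]")
    candidates = len(g_set) * len(l_set)
    hits = []
    for gb in g_set.biclusters:
        K = len(gb.participants)
        for lb in l_set.biclusters:
            n_draw = len(lb.participants)
            shared = gb.participants & lb.participants
            p = hypergeom_overlap_p(N, K, n_draw, len(shared))
            if p < alpha:
                hits.append((p, gb.id, lb.id, gb, lb, shared))
    hits.sort(key=lambda t: (t[0], t[1], t[2]))
    relations = [
        Relation(
            id=f"R{i + 1}",
            genotype_bicluster_id=gb.id,
            lipidome_bicluster_id=lb.id,
            shared_participants=frozenset(shared),
            k=len(shared),
            p_hypergeom=p,
            genotype_participants=gb.participants,
            genotype_snps=gb.features,
            lipidome_lipids=lb.features,
        )
        for i, (p, _, _, gb, lb, shared) in enumerate(hits)
    ]
    return RelationSet(
        relations,
        cohort_size=N,
        alpha=alpha,
        counts={"candidates": candidates, "significant": len(relations)},
    )


def score_distinctness(
    relation_set: RelationSet, snp_membership: dict = None, participant_membership: dict = None
) -> RelationSet:
    """Flag relations whose genotype bicluster is mostly private.

    For each significant relation, ``unique_snp_fraction`` is the fraction
    of its genotype bicluster's SNPs found in no OTHER significant
    relation's genotype bicluster; ``unique_participant_fraction`` is the
    analogue over the genotype bicluster's participants.  A relation is
    distinct when both fractions exceed 0.5.  Membership defaults to the
    sets carried on each relation; explicit ``bicluster id -> set``
    mappings may override them.
    """
    rels = relation_set.relations

    def sets_for(r):
        snps = (
            frozenset(snp_membership[r.genotype_bicluster_id])
            if snp_membership is not None
            else r.genotype_snps
        )
        parts = (
            frozenset(participant_membership[r.genotype_bicluster_id])
            if participant_membership is not None
            else r.genotype_participants
        )
        return snps, parts

    scored = []
    for i, r in enumerate(rels):
        snps, parts = sets_for(r)
        other_snps: set = set()
        other_parts: set = set()
        for j, o in enumerate(rels):
            if j == i:
                continue
            osnps, oparts = sets_for(o)
            other_snps |= osnps
            other_parts |= oparts
        usf = len(snps - other_snps) / len(snps) if snps else 0.0
        upf = len(parts - other_parts) / len(parts) if parts else 0.0
        scored.append(
            replace(
                r,
                unique_snp_fraction=usf,
                unique_participant_fraction=upf,
                distinct=(usf > 0.5 and upf > 0.5),
            )
        )
    counts = dict(relation_set.counts)
    counts["distinct"] = sum(r.distinct for r in scored)
    return RelationSet(scored, relation_set.cohort_size, relation_set.alpha, counts)


def summarize_multifinality(relation_set: RelationSet):
    """(multifinal genotype-bicluster count, equifinal lipidome-bicluster count).

    A genotype bicluster is multifinal when it appears in two or more
    significant relations (same genetic subgroup, several lipid profiles);
    a lipidome bicluster is equifinal symmetrically.
    """
    g_counts = pd.Series([r.genotype_bicluster_id for r in relation_set.relations]).value_counts()
    l_counts = pd.Series([r.lipidome_bicluster_id for r in relation_set.relations]).value_counts()
    return int((g_counts >= 2).sum()), int((l_counts >= 2).sum())


def compare_clinical(
    relation: Relation, clinical: pd.DataFrame, variables=None
) -> ClinicalComparison:
    """Welch two-sample t-test per clinical variable: genotype-bicluster
    members vs all other participants (two-sided).

    Variables with zero variance in either group yield NaN statistics for
    that variable; the others are still reported.
    """
    members = set(relation.genotype_participants)
    in_mask = clinical.index.isin(members)
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise UndefinedStatisticError("need >= 2 members and >= 2 non-members")
    cols = list(variables) if variables is not None else [
        c for c in clinical.columns if pd.api.types.is_numeric_dtype(clinical[c])
    ]
    rows = []
    for c in cols:
        x = clinical.loc[in_mask, c].dropna().to_numpy(float)
        y = clinical.loc[~in_mask, c].dropna().to_numpy(float)
        if len(x) < 2 or len(y) < 2 or x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {
                "variable": c,
                "t": float(t) if np.isfinite(t) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "mean_members": float(x.mean()) if len(x) else np.nan,
                "mean_rest": float(y.mean()) if len(y) else np.nan,
                "n_members": int(len(x)),
                "n_rest": int(len(y)),
            }
        )
    return ClinicalComparison(relation.id, pd.DataFrame(rows))
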