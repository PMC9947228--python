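"""Gene-set overrepresentation analysis of bicluster SNP sets.

Bicluster SNPs (after LD pruning) are mapped to gene symbols through a
user-supplied SNP-to-gene table (VEP-style) or a positional fallback, and
each gene set of a GMT collection is tested with the hypergeometric upper
tail (equivalent to a one-sided Fisher exact test on the 2x2 table).
P-values are Benjamini-Hochberg adjusted within each relation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DomainError


@dataclass
class OraResult:
    relation_id: str
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    q: float
    overlapping_genes: frozenset


def map_snps_to_genes(snps, mapping: dict):
    """Union of genes mapped by ``snps``; returns (gene set, unmapped count)."""
    if not mapping:
        raise ConfigurationError("empty SNP-gene map")
    genes: set = set()
    unmapped = 0
    for s in snps:
        hit = mapping.get(s)
        if hit:
            genes |= set(hit)
        else:
            unmapped += 1
    return genes, unmapped


def ora_test(query_genes, gene_set, universe_genes):
    """Hypergeometric overrepresentation test.

    Returns ``(overlap, p)`` where p is the probability of drawing at
    least ``overlap`` genes of ``gene_set`` when sampling ``|query|``
    genes from the universe.
    """
    universe = set(universe_genes)
    query = set(query_genes)
    if not query <= universe:
        raise DomainError("query genes must be a subset of the universe")
    gset = set(gene_set) & universe
    overlap = len(query & gset)
    if overlap == 0:
        return 0, 1.0
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(gset), len(query)))
    return overlap, float(min(max(p, 5e-324), 1.0))


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_relations(
    relation_set,
    snp_gene_map: dict,
    collections: dict,
    fdr_max: float = 0.05,
    set_size_bounds: tuple = (10, 500),
    universe_genes=None,
) -> list:
    """ORA for every distinct relation against every collection.

    ``collections`` maps a collection label to a ``{set name: genes}``
    mapping (as returned by :func:`biclink.io.read_gmt`).  The gene
    universe defaults to all genes appearing in ``snp_gene_map``.  BH
    adjustment is applied within each relation x collection; results with
    q < ``fdr_max`` are returned.  A relation's pruned SNP set is used
    when present, its full genotype-bicluster SNP set otherwise.
    """
    lo, hi = set_size_bounds
    if universe_genes is None:
        universe_genes = set().union(*(set(v) for v in snp_gene_map.values()))
    universe = set(universe_genes)
    out = []
    for r in relation_set.relations:
        if not r.distinct:
            continue
        snps = r.pruned_snps if r.pruned_snps is not None else r.genotype_snps
        query, _ = map_snps_to_genes(snps, snp_gene_map)
        query &= universe
        if not query:
            continue
        for _, sets in sorted(collections.items()):
            tested = []
            for name in sorted(sets):
                gset = set(sets[name]) & universe
                if not lo <= len(gset) <= hi:
                    continue
                overlap, p = ora_test(query, gset, universe)
                tested.append((name, gset, overlap, p))
            if not tested:
                continue
            qvals = bh_adjust([t[3] for t in tested])
            for (name, gset, overlap, p), q in zip(tested, qvals):
                if q < fdr_max:
                    out.append(
                        OraResult(
                            relation_id=r.id,
                            set_name=name,
                            overlap=overlap,
                            set_size=len(gset),
                            query_size=len(query),
                            universe_size=len(universe),
                            p=p,
                            q=float(q),
                            overlapping_genes=frozenset(query & gset),
                        )
                    )
    return out


def make_positional_gene_map(snps: pd.DataFrame, genes_per_chrom: int = 50, flank: int = 10_000) -> dict:
    """Positional fallback SNP-to-gene map for synthetic cohorts.

    Tiles each chromosome with ``genes_per_chrom`` equal intervals (gene
    symbols ``GENE_<chrom>_<i>``) and assigns every SNP to the interval(s)
    covering its position within ``flank`` bp.
    """
    mapping: dict = {}
    for chrom, sub in snps.groupby("chromosome"):
        lo = int(sub["position"].min())
        hi = int(sub["position"].max()) + 1
        edges = np.linspace(lo, hi, genes_per_chrom + 1)
        for sid, pos in zip(sub["id"], sub["position"]):
            hits = set()
            for i in range(genes_per_chrom):
                if edges[i] - flank <= pos < edges[i + 1] + flank:
                    hits.add(f"GENE_{chrom}_{i + 1}")
            if hits:
                mapping[sid] = hits
    return mapping


def results_to_frame(results) -> pd.DataFrame:
    rows = [
        {
            "relation_id": r.relation_id,
            "set_name": r.set_name,
            "overlap": r.overlap,
            "set_size": r.set_size,
            "query_size": r.query_size,
            "universe_size": r.universe_size,
            "p": r.p,
            "q": r.q,
            "overlapping_genes": ";".join(sorted(r.overlapping_genes)),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
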