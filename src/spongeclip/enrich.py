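"""Overrepresentation statistics and the PAR-CLIP × sponge intersection.

Three headline computations: (1) hypergeometric overrepresentation of seed
families among sponge-derepressed genes, with PAR-CLIP support required in
at least two replicas; (2) the intersection target list — genes that are
both derepressed (log2FC above the relaxed cutoff) and carry a
replica-supported PAR-CLIP seed hit for a family of interest; and (3)
MSigDB-style gene-set overlap tables (K, k, k/K, hypergeometric p, BH q).

BH adjustment is applied within one family of tests at a time: across seed
families in the seed analysis and across gene sets in the pathway analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneSetCollection


class EnrichError(ValueError):
    pass


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact hypergeometric upper tail P(X >= k) for X ~ HG(N, K, n)."""
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N or min(N, K, n, k) < 0:
        raise EnrichError(
            f"invalid hypergeometric bounds: N={N}, K={K}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, input order preserved."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise EnrichError("p values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass(frozen=True)
class TargetCall:
    """A gene passing the intersection rule: derepressed + PAR-CLIP seed hit."""

    gene_id: str
    log2fc: float
    families: tuple[str, ...]
    replicas_per_family: tuple[int, ...]
    site_types: tuple[str, ...]


def seed_enrichment(
    up_genes: set[str],
    hit_table: pd.DataFrame,
    universe: set[str],
) -> pd.DataFrame:
    """Per-family overrepresentation of PAR-CLIP seed hits in up-regulated genes.

    Universe = genes passing the expression filter; K = universe genes with
    a >=2-replica hit for the family; n = up-regulated genes in the
    universe; k = their overlap; p = exact hypergeometric upper tail;
    q = BH across families.
    """
    if not universe:
        raise EnrichError("empty universe")
    n_set = up_genes & universe
    rows = []
    hits = hit_table[hit_table["hit"]]
    for family in sorted(hit_table["family_id"].unique()):
        fam_genes = set(hits.loc[hits["family_id"] == family, "gene_id"]) & universe
        k = len(fam_genes & n_set)
        p = hypergeom_upper(len(universe), len(fam_genes), len(n_set), k)
        rows.append(
            {
                "family_id": family,
                "N": len(universe),
                "K": len(fam_genes),
                "n": len(n_set),
                "k": k,
                "ratio": k / len(fam_genes) if fam_genes else 0.0,
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["family_id", "N", "K", "n", "k", "ratio", "p"]
    )
    if len(out):
        out["q"] = bh_adjust(out["p"])
    else:
        out["q"] = []
    return out


def intersect_targets(
    de_results: pd.DataFrame,
    hit_table: pd.DataFrame,
    families_of_interest: Sequence[str],
    relaxed_log2fc: float = 0.3,
) -> list[TargetCall]:
    """Genes derepressed above the relaxed cutoff with a replica-supported hit.

    A gene is called when its log2FC exceeds ``relaxed_log2fc`` AND at least
    one family of interest has PAR-CLIP support in >=2 replicas (the ``hit``
    flag of the gene hit table).  Output is sorted by descending log2FC,
    ties broken by gene id.
    """
    fam_set = set(families_of_interest)
    hits = hit_table[hit_table["hit"] & hit_table["family_id"].isin(fam_set)]
    by_gene: dict[str, list] = {}
    for rec in hits.itertuples():
        by_gene.setdefault(rec.gene_id, []).append(rec)
    calls = []
    for gene, recs in by_gene.items():
        if gene not in de_results.index:
            continue
        lfc = float(de_results.loc[gene, "log2fc"])
        if lfc <= relaxed_log2fc:
            continue
        recs = sorted(recs, key=lambda r: r.family_id)
        site_types = sorted({st for r in recs for st in r.site_types.split(",")})
        calls.append(
            TargetCall(
                gene_id=gene,
                log2fc=lfc,
                families=tuple(r.family_id for r in recs),
                replicas_per_family=tuple(int(r.n_replicas) for r in recs),
                site_types=tuple(site_types),
            )
        )
    calls.sort(key=lambda c: (-c.log2fc, c.gene_id))
    return calls


def set_overlap_stats(
    query: set[str],
    gene_sets: GeneSetCollection,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Gene-set overlap table: K, k, k/K, hypergeometric p, BH q per set.

    The default universe is the union of all set members and the query
    (the annotation universe is rarely published, so it is explicit and
    configurable).  Sets disjoint from the universe are flagged (K = 0)
    and excluded from the BH family.
    """
    if universe is None:
        universe = set().union(*(gene_sets.members(s) for s in gene_sets)) | set(query)
    q = set(query) & universe
    rows = []
    for name in gene_sets:
        members = gene_sets.members(name) & universe
        K = len(members)
        k = len(q & members)
        row = {
            "set_name": name,
            "description": gene_sets.description(name),
            "N": len(universe),
            "K": K,
            "n": len(q),
            "k": k,
            "ratio": k / K if K else np.nan,
            "p": hypergeom_upper(len(universe), K, len(q), k) if K else np.nan,
            "excluded": K == 0,
        }
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    tested = ~out["excluded"]
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"])
    out = out.sort_values(["p", "set_name"], na_position="last").reset_index(drop=True)
    return out


def write_target_calls(calls: Sequence[TargetCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tfamilies\treplicas_per_family\tsite_types\n")
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.log2fc:.6f}\t{','.join(c.families)}\t"
                f"{','.join(str(r) for r in c.replicas_per_family)}\t"
                f"{','.join(c.site_types)}\n"
            )
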