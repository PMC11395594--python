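"""From screened CpGs to a marker panel via the interaction network.

The funnel: map the attribution-selected CpGs to genes through the array
annotation; induce the subnetwork of those genes in a confidence-weighted
interaction graph; detect dense molecular complexes with a reimplementation
of the MCODE procedure (k-core-based vertex weighting, greedy complex
growth, haircut post-processing, score = density x size); test each
top-scoring complex for over-representation of curated gene sets with the
upper-tail hypergeometric test and Benjamini-Hochberg correction; choose the
complex with the strongest enrichment evidence; and back-map its genes to
the selected CpGs — the marker panel.

MCODE parameters default to the canonical plugin settings: degree cutoff 2,
node-score cutoff 0.2, haircut on, fluff off.  Density is loop-free,
2E / (n(n-1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import CpGAnnotation, GeneNetwork, GeneSetCollection, MarkerPanel
from .attribution import SiteSelection


@dataclass
class Complex:
    """A dense subnetwork: score = density x node count."""

    genes: list[str]
    density: float
    score: float
    seed_vertex: str


@dataclass
class CpGGeneMap:
    genes: list[str]                      # deduplicated, order-stable
    table: pd.DataFrame                   # columns: cpg_id, gene
    unmapped: list[str] = field(default_factory=list)


@dataclass
class EnrichmentTable:
    table: pd.DataFrame  # set_name, universe_size, set_size, query_size, overlap, p_value, bh_adjusted_p


# ---------------------------------------------------------------------------
# gene mapping and induction


def map_cpgs_to_genes(selection: SiteSelection | list[str],
                      annotation: CpGAnnotation) -> CpGGeneMap:
    """Map selected CpGs to gene symbols (many CpGs may share a gene).

    Multi-gene annotations (';'-separated) contribute one row per gene.
    CpGs absent from the annotation are reported in ``unmapped``, not fatal.
    """
    cpgs = selection.selected if isinstance(selection, SiteSelection) else list(selection)
    ann = annotation.table.set_index("cpg_id")["gene"]
    rows, unmapped, genes, seen = [], [], [], set()
    for c in cpgs:
        if c not in ann.index:
            unmapped.append(c)
            continue
        for g in str(ann.loc[c]).split(";"):
            if not g:
                continue
            rows.append((c, g))
            if g not in seen:
                seen.add(g)
                genes.append(g)
    table = pd.DataFrame(rows, columns=["cpg_id", "gene"])
    return CpGGeneMap(genes=genes, table=table, unmapped=unmapped)


def induce_network(genes: list[str], network: GeneNetwork,
                   min_confidence: float = 0.0) -> GeneNetwork:
    """Subgraph on the given genes; low-confidence edges dropped, isolated
    genes (those present in the network) retained."""
    present = [g for g in genes if g in network.graph]
    sub = nx.Graph()
    sub.add_nodes_from(present)
    for u, v, d in network.graph.subgraph(present).edges(data=True):
        if d.get("confidence", 1.0) >= min_confidence:
            sub.add_edge(u, v, **d)
    return GeneNetwork(sub)


# ---------------------------------------------------------------------------
# MCODE


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weight(g: nx.Graph, v, degree_cutoff: int) -> float:
    """Core-clustering weight: k x density of the highest k-core of the
    closed neighborhood of v (v and its direct neighbors).  Including v
    keeps weights homogeneous inside a dense region, which is what lets one
    complex absorb a whole module instead of splintering it."""
    if g.degree(v) < degree_cutoff:
        return 0.0
    nbhd = g.subgraph([v, *g.neighbors(v)])
    core_num = nx.core_number(nbhd)
    k = max(core_num.values())
    core = nbhd.subgraph([u for u, c in core_num.items() if c >= k])
    return k * _density(core) if core.number_of_nodes() >= 2 else 0.0


def mcode_cluster(network: GeneNetwork, degree_cutoff: int = 2,
                  node_score_cutoff: float = 0.2, haircut: bool = True,
                  fluff: bool = False) -> list[Complex]:
    """Dense-complex detection; returns complexes ranked by score descending.

    Ranking ties break by larger size, then by lexicographically smallest
    member.  Complexes are vertex-disjoint.  ``fluff`` is accepted for
    interface completeness and is off by default.
    """
    g = network.graph
    if any(u == v for u, v in g.edges):
        raise ValueError("graph must be simple (no self-loops)")
    if fluff:
        raise NotImplementedError("fluff post-processing is not implemented")

    weight = {v: _vertex_weight(g, v, degree_cutoff) for v in g.nodes}
    assigned: set = set()
    complexes: list[Complex] = []
    # deterministic seed order: weight desc, then node name
    for seed in sorted(g.nodes, key=lambda v: (-weight[v], str(v))):
        if seed in assigned or weight[seed] <= 0.0:
            continue
        threshold = (1.0 - node_score_cutoff) * weight[seed]
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(g.neighbors(u), key=str):
                    if w in assigned or w in members:
                        continue
                    if weight[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        if haircut:
            members = _haircut(g, members)
        if len(members) < 2:
            assigned.add(seed)
            continue
        assigned |= members
        sub = g.subgraph(members)
        d = _density(sub)
        complexes.append(Complex(
            genes=sorted(members, key=str),
            density=d,
            score=d * len(members),
            seed_vertex=seed,
        ))
    complexes.sort(key=lambda c: (-c.score, -len(c.genes), c.genes[0]))
    return complexes


def _haircut(g: nx.Graph, members: set) -> set:
    members = set(members)
    while members:
        sub = g.subgraph(members)
        singly = {v for v in members if sub.degree(v) <= 1}
        if not singly:
            break
        members -= singly
    return members


# ---------------------------------------------------------------------------
# over-representation


def hypergeom_enrich(query_genes: list[str], collection: GeneSetCollection,
                     universe: set[str] | None = None) -> EnrichmentTable:
    """Upper-tail hypergeometric over-representation with BH adjustment.

    p = P(overlap >= k) for a query of size n drawn from a universe of size
    N containing K set members.  Query genes outside the universe are
    dropped (with the drop count recoverable from query_size); gene sets are
    intersected with the universe.
    """
    universe = universe if universe is not None else collection.universe
    if not universe:
        raise ValueError("enrichment requires a non-empty universe")
    query = {g for g in query_genes if g in universe}
    rows = []
    for name, members in collection.sets.items():
        inset = members & universe
        big_n, big_k, n, k = len(universe), len(inset), len(query), len(query & inset)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append((name, big_n, big_k, n, k, min(max(p, 0.0), 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "universe_size", "set_size",
                                     "query_size", "overlap", "p_value"])
    df["bh_adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    return EnrichmentTable(df)


def choose_key_complex(complexes: list[Complex], collection: GeneSetCollection,
                       universe: set[str] | None = None, top_m: int = 4,
                       alpha: float = 0.05) -> dict:
    """Among the ``top_m`` highest-scoring complexes, pick the one with the
    smallest minimum BH-adjusted enrichment p; ties go to the larger
    complex, then to the better MCODE rank.  All candidates' evidence is
    recorded so the choice is auditable; if no candidate reaches ``alpha``
    the best is still returned with ``below_threshold=True``."""
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    if not complexes:
        raise ValueError("no complexes to choose from")
    candidates = complexes[:top_m]
    evidence = []
    for rank, cx in enumerate(candidates):
        enr = hypergeom_enrich(cx.genes, collection, universe)
        min_p = float(enr.table["bh_adjusted_p"].min()) if len(enr.table) else 1.0
        evidence.append({"rank": rank, "complex": cx, "enrichment": enr,
                         "min_adjusted_p": min_p})
    best = min(evidence, key=lambda e: (e["min_adjusted_p"],
                                        -len(e["complex"].genes), e["rank"]))
    return {
        "chosen": best["complex"],
        "chosen_rank": best["rank"],
        "min_adjusted_p": best["min_adjusted_p"],
        "below_threshold": best["min_adjusted_p"] > alpha,
        "candidates": evidence,
    }


def genes_to_marker_cpgs(complex_: Complex, cpg_gene_table: pd.DataFrame) -> MarkerPanel:
    """Back-map a complex's genes to the selected CpGs they host."""
    genes = set(complex_.genes)
    hit = cpg_gene_table[cpg_gene_table["gene"].isin(genes)]
    if hit.empty:
        raise ValueError(
            "no selected CpG maps to the chosen complex; review screening k, "
            "MCODE parameters, or the annotation")
    cpg_to_gene = dict(zip(hit["cpg_id"], hit["gene"]))
    return MarkerPanel(
        cpg_ids=list(dict.fromkeys(hit["cpg_id"])),
        genes=sorted(set(hit["gene"])),
        cpg_to_gene=cpg_to_gene,
        provenance={"complex_genes": complex_.genes,
                    "complex_score": complex_.score,
                    "complex_density": complex_.density},
    )
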