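"""Gene-neighbourhood conservation against interaction networks.

Two neighbourhood notions are combined: genes are genome neighbours if
at most ``max_gap`` genes separate them in genomic order (circular
order honoured), and network neighbours if at most ``max_intermediate``
nodes separate them in a molecular interaction network.  A *common
connected component* (CCC) is a maximal gene set inducing a connected
subgraph in both neighbourhood graphs at once; depending on the network
it is called a transcripton (transcriptional regulation), interacton
(protein-protein interaction) or metabolon (metabolic network), and a
synton when only genome order is used.

Conservation of ancestral components in a reduced descendant genome is
scored by whether surviving orthologs remain a connected neighbourhood,
and its significance is assessed by a resampling test that assembles
random size-matched gene sets (*r-transcriptons*) within a bounded
genomic span, without replacement, and counts how many are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .genome_model import AnnotatedGenome, OrthologyMap

__all__ = [
    "NeighbourhoodGraph",
    "CommonComponent",
    "TUFate",
    "ResamplingResult",
    "genome_neighbourhood_graph",
    "network_neighbourhood_graph",
    "common_connected_components",
    "component_conservation",
    "classify_tu_fates",
    "classify_tu_fate",
    "r_transcripton_test",
]


@dataclass
class NeighbourhoodGraph:
    """Simple undirected gene graph with its construction provenance."""

    graph: nx.Graph
    provenance: dict

    @property
    def nodes(self):
        return set(self.graph.nodes)


@dataclass(frozen=True)
class CommonComponent:
    gene_set: frozenset
    kind: str  # {synton, transcripton, interacton, metabolon}


@dataclass(frozen=True)
class TUFate:
    tu_id: str
    fate: str  # {monocistronic, identical, similar, split, merged_reorganized, unclassifiable}


@dataclass(frozen=True)
class ResamplingResult:
    observed_statistic: int
    null_statistics: tuple
    p_value: float            # #{null >= observed} / n_sims
    p_value_plus1: float      # (#{null >= observed} + 1) / (n_sims + 1)
    n_sims: int
    seed: int
    size_pool: tuple


def genome_neighbourhood_graph(genome: AnnotatedGenome,
                               max_gap: int = 5) -> NeighbourhoodGraph:
    """Edge between two genes iff <= ``max_gap`` genes lie between them."""
    ids = genome.gene_ids()
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for step in range(1, max_gap + 2):
            j = i + step
            if j < n:
                g.add_edge(ids[i], ids[j])
            elif genome.circular and n > step and (j % n) != i:
                g.add_edge(ids[i], ids[j % n])
    return NeighbourhoodGraph(g, {"genome": {"max_gap": max_gap}})


def network_neighbourhood_graph(edge_list, max_intermediate: int = 1) -> NeighbourhoodGraph:
    """Edge between u,v iff their network distance is <= max_intermediate + 1."""
    base = nx.Graph()
    for e in edge_list:
        u, v = e[0], e[1]
        if u != v:
            base.add_edge(u, v)
    g = nx.Graph()
    g.add_nodes_from(base.nodes)
    cutoff = max_intermediate + 1
    for u in base.nodes:
        lengths = nx.single_source_shortest_path_length(base, u, cutoff=cutoff)
        for v, dist in lengths.items():
            if v != u and dist <= cutoff:
                g.add_edge(u, v)
    return NeighbourhoodGraph(g, {"network": {"max_intermediate": max_intermediate}})


def _as_graph(g):
    return g.graph if isinstance(g, NeighbourhoodGraph) else g


def common_connected_components(genome_graph, network_graph, orthology=None,
                                kind: str = "transcripton") -> "list[CommonComponent]":
    """Maximal node sets connected in both graphs simultaneously.

    Node sets are intersected first (after mapping ``network_graph``
    nodes through ``orthology`` when the graphs come from different
    organisms; unmapped nodes are dropped).  Computed by partition
    refinement: blocks are repeatedly split into connected components
    within each graph until a fixed point; components of size >= 2 are
    returned.
    """
    g1 = _as_graph(genome_graph)
    g2 = _as_graph(network_graph)
    if orthology is not None:
        mapping = orthology.to_ancestor()
        g2 = nx.relabel_nodes(
            g2.subgraph([n for n in g2.nodes if n in mapping]).copy(), mapping
        )
    common = set(g1.nodes) & set(g2.nodes)
    blocks = [common]
    stable = False
    while not stable:
        stable = True
        next_blocks = []
        for block in blocks:
            if len(block) <= 1:
                next_blocks.append(block)
                continue
            parts = list(nx.connected_components(g1.subgraph(block)))
            if len(parts) > 1:
                stable = False
            refined = []
            for part in parts:
                sub = list(nx.connected_components(g2.subgraph(part)))
                if len(sub) > 1:
                    stable = False
                refined.extend(sub)
            next_blocks.extend(refined)
        blocks = next_blocks
    return [
        CommonComponent(frozenset(b), kind) for b in blocks if len(b) >= 2
    ]


def _ranks_connected(ranks, n_genes: int, max_gap: int, circular: bool) -> bool:
    """Connectivity of a gene set in the genome-neighbourhood graph.

    The graph is a (circular) interval graph on gene ranks: the induced
    subgraph is connected iff at most one cyclic gap between consecutive
    chosen ranks exceeds ``max_gap + 1`` (all gaps, for a linear genome).
    """
    ranks = np.sort(np.asarray(ranks))
    if len(ranks) <= 1:
        return True
    gaps = np.diff(ranks)
    if not circular:
        return bool(np.all(gaps <= max_gap + 1))
    wrap = n_genes - ranks[-1] + ranks[0]
    all_gaps = np.concatenate((gaps, [wrap]))
    return int(np.sum(all_gaps > max_gap + 1)) <= 1


def component_conservation(components, genome_descendant: AnnotatedGenome,
                           orthology: OrthologyMap, max_gap: int = 5):
    """Score each ancestral component's fate in the descendant genome.

    A component is *testable* iff >= 2 members have descendant
    orthologs, and *conserved* iff those orthologs induce a connected
    subgraph of the descendant genome-neighbourhood graph.
    Returns a list of dicts (component, n_orthologs, testable, conserved).
    """
    a2d = orthology.to_descendant()
    rank = {gid: i for i, gid in enumerate(genome_descendant.gene_ids())}
    n = len(rank)
    out = []
    for comp in components:
        genes = comp.gene_set if isinstance(comp, CommonComponent) else frozenset(comp)
        orth = [a2d[g] for g in genes if g in a2d and a2d[g] in rank]
        testable = len(orth) >= 2
        conserved = False
        if testable:
            conserved = _ranks_connected(
                [rank[g] for g in orth], n, max_gap, genome_descendant.circular
            )
        out.append(
            {
                "component": genes,
                "n_orthologs": len(orth),
                "testable": testable,
                "conserved_as_component": conserved,
            }
        )
    return out


# ---------------------------------------------------------------------------
# TU fates
# ---------------------------------------------------------------------------

def classify_tu_fates(tus_descendant, tus_ancestor, orthology: OrthologyMap):
    """Evolutionary fate of each descendant TU against ancestral TUs.

    monocistronic: single-gene TU.  identical: the ancestral orthologs
    equal exactly one ancestral TU's gene set.  similar: a proper subset
    of exactly one ancestral TU whose other surviving orthologs do not
    reach further descendant TUs.  split: drawn from one ancestral TU
    whose orthologs span several descendant TUs.  merged_reorganized:
    drawn from >= 2 ancestral TUs.  unclassifiable: no member has an
    ancestral ortholog.
    """
    d2a = orthology.to_ancestor()
    a2d = orthology.to_descendant()
    anc_tu_of = {}
    for tu in tus_ancestor:
        for gid in tu.gene_ids:
            anc_tu_of[gid] = tu.id
    anc_tu_genes = {tu.id: set(tu.gene_ids) for tu in tus_ancestor}
    desc_tu_of = {}
    for tu in tus_descendant:
        for gid in tu.gene_ids:
            desc_tu_of[gid] = tu.id

    fates = []
    for tu in tus_descendant:
        if len(tu.gene_ids) == 1:
            fates.append(TUFate(tu.id, "monocistronic"))
            continue
        anc_genes = [d2a[g] for g in tu.gene_ids if g in d2a]
        if not anc_genes:
            fates.append(TUFate(tu.id, "unclassifiable"))
            continue
        source_tus = {anc_tu_of.get(g, f"__singleton__{g}") for g in anc_genes}
        if len(source_tus) >= 2:
            fates.append(TUFate(tu.id, "merged_reorganized"))
            continue
        src = next(iter(source_tus))
        src_genes = anc_tu_genes.get(src, set(anc_genes))
        if set(anc_genes) == src_genes:
            fates.append(TUFate(tu.id, "identical"))
            continue
        # which descendant TUs do the source TU's surviving orthologs reach?
        reached = {
            desc_tu_of.get(a2d[g]) for g in src_genes
            if g in a2d and desc_tu_of.get(a2d[g]) is not None
        }
        fates.append(TUFate(tu.id, "split" if len(reached) > 1 else "similar"))
    return fates


def classify_tu_fate(tu_descendant, tus_ancestor, orthology,
                     tus_descendant_all=None) -> TUFate:
    """Fate of a single descendant TU (context = all descendant TUs)."""
    context = tus_descendant_all if tus_descendant_all is not None else [tu_descendant]
    fates = {f.tu_id: f for f in classify_tu_fates(context, tus_ancestor, orthology)}
    return fates[tu_descendant.id]


# ---------------------------------------------------------------------------
# r-transcripton resampling test
# ---------------------------------------------------------------------------

def _simulate_statistic(rng, n_genes, rank_of_anc, size_pool, cap,
                        min_shared, span, max_gap, n_desc, circular):
    """One simulation: assemble r-transcriptons and count conserved ones."""
    unused = np.ones(n_genes, dtype=bool)
    retained = 0
    conserved = 0
    kernel = np.ones(span)
    while retained < cap:
        placed = False
        for _ in range(50):  # redraw X on placement failure
            x = int(size_pool[rng.integers(len(size_pool))])
            if x > span or x > unused.sum():
                continue
            # windows of `span` consecutive ranks with >= x unused genes
            u = unused.astype(float)
            if circular:
                ext = np.concatenate((u, u[: span - 1]))
                counts = np.convolve(ext, kernel, mode="valid")[:n_genes]
            else:
                counts = np.convolve(u, kernel, mode="valid")
            feasible = np.nonzero(counts >= x)[0]
            if len(feasible) == 0:
                continue
            w0 = int(feasible[rng.integers(len(feasible))])
            idx = np.arange(w0, w0 + span) % n_genes if circular else np.arange(
                w0, min(w0 + span, n_genes))
            avail = idx[unused[idx]]
            chosen = rng.choice(avail, size=x, replace=False)
            unused[chosen] = False
            placed = True
            break
        if not placed:
            break  # gene exhaustion
        ranks = rank_of_anc[chosen]
        ranks = ranks[ranks >= 0]
        if len(ranks) < min_shared:
            continue
        retained += 1
        if _ranks_connected(ranks, n_desc, max_gap, circular):
            conserved += 1
    return conserved


def r_transcripton_test(ancestor_genome: AnnotatedGenome,
                        ancestor_transcripton_sizes,
                        orthology: OrthologyMap,
                        descendant_genome: AnnotatedGenome,
                        observed_statistic: int,
                        n_sims: int = 1000,
                        cap: int = 38,
                        min_shared: int = 2,
                        span: int = 5,
                        max_gap: int = 5,
                        seed: int = 0) -> ResamplingResult:
    """Resampling significance test for conserved gene neighbourhoods.

    Each simulation assembles up to ``cap`` random gene sets
    (r-transcriptons): the size is drawn from the observed transcripton
    size pool, members are drawn without replacement within a window of
    ``span`` consecutive gene ranks of the ancestor, and a set is
    retained iff >= ``min_shared`` members have descendant orthologs.
    The simulation statistic is the number of retained r-transcriptons
    whose surviving orthologs stay a connected genome neighbourhood in
    the descendant.  ``p = #{null >= observed}/n_sims`` (the +1-corrected
    value is also reported).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    size_pool = tuple(int(s) for s in ancestor_transcripton_sizes)
    if not size_pool:
        raise ValueError("empty transcripton size pool")
    anc_ids = ancestor_genome.gene_ids()
    n_genes = len(anc_ids)
    a2d = orthology.to_descendant()
    desc_rank = {gid: i for i, gid in enumerate(descendant_genome.gene_ids())}
    rank_of_anc = np.array(
        [desc_rank.get(a2d.get(gid), -1) for gid in anc_ids], dtype=np.int64
    )
    rng = np.random.default_rng(seed)
    null = [
        _simulate_statistic(
            rng, n_genes, rank_of_anc, size_pool, cap, min_shared, span,
            max_gap, len(desc_rank),
            descendant_genome.circular and ancestor_genome.circular,
        )
        for _ in range(n_sims)
    ]
    null = np.array(null)
    n_ge = int(np.sum(null >= observed_statistic))
    return ResamplingResult(
        observed_statistic=int(observed_statistic),
        null_statistics=tuple(int(v) for v in null),
        p_value=n_ge / n_sims,
        p_value_plus1=(n_ge + 1) / (n_sims + 1),
        n_sims=n_sims,
        seed=seed,
        size_pool=size_pool,
    )
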