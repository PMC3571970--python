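"""Synthetic ancestor/descendant genome pairs with known ground truth.

The generator emulates the statistical structure a reduced endosymbiont
genome analysis assumes: an AT-rich chromosome laid out as transcription
units, typed interaction networks whose planted gene neighbourhoods
(transcriptons) are recoverable as common connected components, a
descendant produced by gene loss and rearrangement with the planted
neighbourhoods kept contiguous, AT-rich destabilization sinks planted a
fixed distance upstream of chosen start codons, literal consensus-motif
instances written into intergenic gaps, and functional-category labels
whose members carry planted promoter-instability effects.

Sequences are i.i.d. per region at the requested coding and non-coding
GC contents — no codon structure — which is sufficient for every
consumer here (the physical-property calculators and the base-
composition null models).  All operations are deterministic given the
spec seed; sub-operations draw from fixed spawns of that seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_model import AnnotatedGenome, GeneRecord, OrthologyMap, TURecord

__all__ = [
    "SyntheticSpec",
    "buchnera_like",
    "ecoli_like",
    "generate_ancestor",
    "derive_descendant",
    "plant_upstream_sinks",
    "plant_motifs_and_categories",
    "simulate_promoter_values",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_CATEGORY_POOL = (
    "metabolism", "transporter", "regulator", "cell_process",
    "translation", "membrane", "stress", "unknown",
)


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes_ancestor: int = 550
    gc_coding: float = 0.26
    gc_noncoding: float = 0.20
    mean_gene_len: int = 93
    mean_gap_len: int = 16
    tu_size_distribution: tuple = (1, 1, 1, 1, 2, 2, 3, 4)
    n_transcriptons_planted: int = 30
    retention_rate: float = 0.6
    rearrangement_mode: str = "shuffle_outside_planted"
    sink_offset_bp: int = 125
    sink_width_bp: int = 50
    sink_at_fraction: float = 0.95
    planted_motifs: tuple = ()
    category_effect: tuple = (("transporter", "regulator"), 1.5)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.retention_rate <= 1:
            raise ValueError("retention_rate must be in (0, 1]")
        for f in (self.gc_coding, self.gc_noncoding, self.sink_at_fraction):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.rearrangement_mode not in (
            "none", "shuffle_outside_planted", "full_shuffle"
        ):
            raise ValueError(f"unknown rearrangement_mode {self.rearrangement_mode!r}")
        if self.n_genes_ancestor < 2:
            raise ValueError("need at least 2 genes")
        if self.mean_gene_len < 10 or self.mean_gap_len < 2:
            raise ValueError("infeasible gene/gap lengths")


def buchnera_like(seed: int = 0, **overrides) -> SyntheticSpec:
    """AT-rich, gene-dense preset (desk-scale chromosome of ~60 kb)."""
    return replace(SyntheticSpec(seed=seed), **overrides)


def ecoli_like(seed: int = 0, **overrides) -> SyntheticSpec:
    """GC-balanced preset emulating a free-living ancestor."""
    return replace(
        SyntheticSpec(gc_coding=0.52, gc_noncoding=0.46, seed=seed), **overrides
    )


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed) % (2**31), stream]))


def _draw_seq(rng, length, gc) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _lengths(rng, n, mean) -> np.ndarray:
    vals = np.maximum(np.round(rng.normal(mean, 0.15 * mean, size=n)),
                      max(2, int(0.3 * mean))).astype(int)
    return vals


def generate_ancestor(spec: SyntheticSpec):
    """Build the ancestor genome, typed networks and planted transcriptons.

    Returns ``(genome, networks, true_transcriptons)`` where ``networks``
    maps type ('transcription', 'ppi', 'metabolic') to an edge list and
    ``true_transcriptons`` is the list of planted gene-id lists (ordered
    along the genome, each spanning consecutive genes).
    """
    rng = _rng(spec, 1)
    n = spec.n_genes_ancestor

    # assemble TU plan: cycle sizes from the distribution until n genes
    tu_sizes = []
    total = 0
    pool = np.asarray(spec.tu_size_distribution)
    while total < n:
        s = int(pool[rng.integers(len(pool))])
        s = min(s, n - total)
        tu_sizes.append(s)
        total += s

    gene_lens = _lengths(rng, n, spec.mean_gene_len)
    gap_lens = _lengths(rng, n, spec.mean_gap_len)

    genes, tus = [], []
    seq_parts = []
    pos = 0
    gi = 0
    for ti, size in enumerate(tu_sizes):
        strand = "+" if rng.random() < 0.5 else "-"
        member_ids = []
        for k in range(size):
            glen = int(gene_lens[gi])
            gid = f"g{gi:04d}"
            genes.append(GeneRecord(gid, pos, pos + glen, strand, "coding"))
            seq_parts.append(_draw_seq(rng, glen, spec.gc_coding))
            pos += glen
            gap = int(gap_lens[gi])
            seq_parts.append(_draw_seq(rng, gap, spec.gc_noncoding))
            pos += gap
            member_ids.append(gid)
            gi += 1
        if strand == "-":
            member_ids = member_ids[::-1]  # 5'->3' order on the minus strand
        tus.append(TURecord(f"tu{ti:03d}", tuple(member_ids), strand))

    sequence = np.concatenate(seq_parts).tobytes().decode()
    categories = {}
    for g in genes:
        k = min(rng.poisson(1.2), len(_CATEGORY_POOL))
        if k:
            labels = rng.choice(len(_CATEGORY_POOL), size=k, replace=False)
            categories[g.id] = {_CATEGORY_POOL[i] for i in labels}
    genome = AnnotatedGenome(
        sequence=sequence, genes=genes, tus=tus, categories=categories,
        circular=True, id="ancestor",
    )

    ids = [g.id for g in genes]
    transcriptons = _plant_gene_runs(rng, ids, spec.n_transcriptons_planted)
    planted_flat = {g for t in transcriptons for g in t}
    networks = {
        "transcription": _network_edges(rng, ids, transcriptons, planted_flat),
    }
    for kind, n_planted in (("ppi", max(3, spec.n_transcriptons_planted // 3)),
                            ("metabolic", max(3, spec.n_transcriptons_planted // 3))):
        runs = _plant_gene_runs(rng, ids, n_planted)
        networks[kind] = _network_edges(rng, ids, runs, {g for t in runs for g in t})
    return genome, networks, transcriptons


def _plant_gene_runs(rng, ids, n_runs, min_size=2, max_size=5):
    """Non-overlapping, non-adjacent runs of consecutive genes."""
    n = len(ids)
    taken = np.zeros(n, dtype=bool)
    runs = []
    attempts = 0
    while len(runs) < n_runs and attempts < 50 * n_runs:
        attempts += 1
        size = int(rng.integers(min_size, max_size + 1))
        start = int(rng.integers(0, n - size))
        lo, hi = max(0, start - 6), min(n, start + size + 6)
        if taken[lo:hi].any():
            continue  # keep runs separated by > max_gap so CCCs stay distinct
        taken[start: start + size] = True
        runs.append([ids[i] for i in range(start, start + size)])
    if len(runs) < n_runs:
        warnings.warn(f"placed only {len(runs)}/{n_runs} planted gene runs")
    return runs


def _network_edges(rng, ids, runs, planted_flat, noise_fraction=0.2):
    edges = []
    for run in runs:
        edges.extend((a, b) for a, b in zip(run, run[1:]))  # path: connected
    rank = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    n_noise = int(round(noise_fraction * n))
    added = 0
    guard = 0
    while added < n_noise and guard < 50 * n_noise:
        guard += 1
        u, v = ids[rng.integers(n)], ids[rng.integers(n)]
        if u == v:
            continue
        d = abs(rank[u] - rank[v])
        if min(d, n - d) < 12:
            continue  # genome-distant: noise cannot extend a planted CCC
        if u in planted_flat and v in planted_flat:
            continue
        edges.append((u, v))
        added += 1
    return edges


def derive_descendant(ancestor: AnnotatedGenome, spec: SyntheticSpec,
                      planted=()):
    """Gene loss plus rearrangement; returns (genome, orthology).

    Planted-run members are always retained; other genes survive
    i.i.d. with ``retention_rate``.  Rearrangement modes: ``none`` keeps
    ancestral order; ``shuffle_outside_planted`` keeps each planted run
    contiguous (in order) and permutes everything else as blocks;
    ``full_shuffle`` permutes all surviving genes.
    """
    rng = _rng(spec, 2)
    ids = ancestor.gene_ids()
    planted_flat = {g for run in planted for g in run}
    keep = {
        gid for gid in ids
        if gid in planted_flat or rng.random() < spec.retention_rate
    }
    run_of = {}
    for ri, run in enumerate(planted):
        for g in run:
            run_of[g] = ri

    # build blocks in ancestral order
    blocks = []
    seen_runs = set()
    for gid in ids:
        if gid not in keep:
            continue
        ri = run_of.get(gid)
        if ri is None:
            blocks.append([gid])
        elif ri not in seen_runs:
            seen_runs.add(ri)
            blocks.append(list(planted[ri]))

    mode = spec.rearrangement_mode
    if mode == "none":
        order = [g for b in blocks for g in b]
    elif mode == "shuffle_outside_planted":
        perm = rng.permutation(len(blocks))
        order = [g for i in perm for g in blocks[i]]
    else:  # full_shuffle
        flat = [g for b in blocks for g in b]
        order = [flat[i] for i in rng.permutation(len(flat))]

    gap_lens = _lengths(rng, len(order), spec.mean_gap_len)
    genes, seq_parts = [], []
    pos = 0
    anc_tu = ancestor.tu_of()
    for i, gid in enumerate(order):
        g = ancestor.gene(gid)
        gseq = np.frombuffer(
            ancestor.fetch(g.start, g.end).encode(), dtype=np.uint8
        )
        did = f"d_{gid}"
        genes.append(GeneRecord(did, pos, pos + len(gseq), g.strand, g.kind))
        seq_parts.append(gseq)
        pos += len(gseq)
        gap = int(gap_lens[i])
        seq_parts.append(_draw_seq(rng, gap, spec.gc_noncoding))
        pos += gap

    # descendant TUs: maximal runs of adjacent genes sharing ancestral TU + strand
    tus = []
    current = []
    cur_tu = object()
    for i, gid in enumerate(order):
        t = anc_tu.get(gid)
        strand = ancestor.gene(gid).strand
        key = (t, strand) if t is not None else None
        if key is not None and key == cur_tu:
            current.append(f"d_{gid}")
        else:
            if current:
                tus.append(current)
            current = [f"d_{gid}"]
            cur_tu = key if key is not None else (None, i)
    if current:
        tus.append(current)
    strand_of = {f"d_{gid}": ancestor.gene(gid).strand for gid in order}
    tu_records = [
        TURecord(f"dtu{i:03d}", tuple(members), strand_of[members[0]])
        for i, members in enumerate(tus)
    ]

    categories = {
        f"d_{gid}": set(ancestor.categories.get(gid, set()))
        for gid in order if gid in ancestor.categories
    }
    genome = AnnotatedGenome(
        sequence=np.concatenate(seq_parts).tobytes().decode(),
        genes=genes, tus=tu_records, categories=categories,
        circular=True, id="descendant",
    )
    orthology = OrthologyMap.from_pairs((gid, f"d_{gid}") for gid in order)
    return genome, orthology


def plant_upstream_sinks(genome: AnnotatedGenome, spec: SyntheticSpec,
                         target_gene_ids, stream: int = 3) -> AnnotatedGenome:
    """Write an AT-rich window centred ``sink_offset_bp`` upstream of targets.

    The window of ``sink_width_bp`` is strand-aware; bases are drawn at
    AT fraction ``sink_at_fraction``.  Annotation is unchanged.  When
    target windows overlap, the later write wins (with a warning).
    """
    rng = _rng(spec, stream)
    n = len(genome)
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    written = np.zeros(n, dtype=bool)
    half = spec.sink_width_bp // 2
    for gid in target_gene_ids:
        g = genome.gene(gid)
        if g.strand == "+":
            center = g.start - spec.sink_offset_bp
        else:
            center = g.end - 1 + spec.sink_offset_bp
        lo = center - half
        idx = np.arange(lo, lo + spec.sink_width_bp)
        if genome.circular:
            idx = idx % n
        else:
            idx = idx[(idx >= 0) & (idx < n)]
        if written[idx].any():
            warnings.warn(f"sink window of gene {gid!r} overlaps an earlier sink")
        at = spec.sink_at_fraction
        p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
        arr[idx] = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                              size=len(idx), p=p)
        written[idx] = True
    out = AnnotatedGenome(
        sequence=arr.tobytes().decode(), genes=list(genome.genes),
        tus=list(genome.tus), categories=dict(genome.categories),
        circular=genome.circular, id=genome.id, allow_n=genome.allow_n,
    )
    return out


def plant_motifs_and_categories(genome: AnnotatedGenome, spec: SyntheticSpec,
                                n_effect_genes: int = 50):
    """Plant literal motif instances and category-instability associations.

    Each requested motif pattern is instantiated (one concrete base per
    IUPAC symbol) ``count`` times into intergenic gaps; genes labelled
    with the effect categories receive upstream destabilization sinks.
    Returns ``(genome, category_map, truth)`` where ``truth`` records
    planted motif positions, effect-gene ids and the nominal effect size.
    """
    rng = _rng(spec, 4)
    n = len(genome)

    # categories and their upstream sinks first, so the sink writes cannot
    # clobber motif instances planted afterwards
    categories = {gid: set(labels) for gid, labels in genome.categories.items()}
    labels, delta = spec.category_effect
    coding = [g.id for g in genome.coding_genes()]
    n_eff = min(n_effect_genes, len(coding))
    effect_ids = [coding[i] for i in rng.choice(len(coding), n_eff, replace=False)]
    for i, gid in enumerate(effect_ids):
        categories.setdefault(gid, set()).add(labels[i % len(labels)])
    genome = plant_upstream_sinks(genome, spec, effect_ids, stream=5)

    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()

    genic = np.zeros(n, dtype=bool)
    for g in genome.genes:
        genic[g.start: g.end] = True
    free = ~genic

    motif_truth = []
    skipped = []
    for pattern, count in spec.planted_motifs:
        k = len(pattern)
        for _ in range(count):
            # candidate starts whose window is fully intergenic and unused
            ok = np.nonzero(free)[0]
            starts = [s for s in ok if s + k <= n and free[s: s + k].all()]
            if not starts:
                skipped.append(pattern)
                break
            s = int(starts[rng.integers(len(starts))])
            inst = "".join(
                _IUPAC[sym][rng.integers(len(_IUPAC[sym]))] for sym in pattern
            )
            arr[s: s + k] = np.frombuffer(inst.encode(), dtype=np.uint8)
            free[s: s + k] = False
            motif_truth.append({"pattern": pattern, "position": s, "instance": inst})

    planted = AnnotatedGenome(
        sequence=arr.tobytes().decode(), genes=list(genome.genes),
        tus=list(genome.tus), categories=categories,
        circular=genome.circular, id=genome.id, allow_n=genome.allow_n,
    )
    truth = {
        "motifs": motif_truth,
        "skipped_motifs": skipped,
        "effect_genes": effect_ids,
        "effect_labels": tuple(labels),
        "effect_delta": delta,
    }
    return planted, categories, truth


def simulate_promoter_values(n_in: int, n_out: int, delta: float,
                             sd: float = 2.0, baseline: float = 10.0,
                             seed: int = 0):
    """Gaussian surrogate of per-gene promoter-window stability values.

    Effect genes are shifted ``delta`` kcal/mol toward instability
    (lower values); the dispersion default of 2.0 kcal/mol matches the
    spread the sequence-level generator produces.  Used by the
    statistical-layer calibration and power simulations, which need many
    replicates without re-running the physics.
    """
    rng = np.random.default_rng(seed)
    in_vals = rng.normal(baseline - delta, sd, size=n_in)
    out_vals = rng.normal(baseline, sd, size=n_out)
    return in_vals, out_vals
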