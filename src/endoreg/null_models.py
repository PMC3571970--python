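"""Base-permutation null models for physical-property comparisons.

Two references are provided:

* the **global** null — a uniform permutation of all bases, preserving
  only the genome-scale GC content;
* the **local** null — an independent uniform permutation within each
  maximal coding and non-coding segment, preserving per-segment base
  composition (and hence the coding vs non-coding GC split).

Permutations act on the forward-strand string; the complement follows.
A single seeded generator drives each call, so outputs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_model import AnnotatedGenome

__all__ = ["NullModelSpec", "shuffle_global", "shuffle_local", "coding_mask"]


@dataclass(frozen=True)
class NullModelSpec:
    kind: str = "global"          # {"global", "local"}
    seed: int = 0
    replicate_count: int = 1

    def __post_init__(self):
        if self.kind not in ("global", "local"):
            raise ValueError(f"unknown null-model kind {self.kind!r}")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def _clone_with_sequence(genome: AnnotatedGenome, sequence: str) -> AnnotatedGenome:
    return AnnotatedGenome(
        sequence=sequence,
        genes=list(genome.genes),
        tus=list(genome.tus),
        categories=dict(genome.categories),
        circular=genome.circular,
        id=genome.id,
        allow_n=genome.allow_n,
    )


def shuffle_global(genome: AnnotatedGenome, seed: int) -> AnnotatedGenome:
    """Uniform permutation of all bases; annotations unchanged."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return _clone_with_sequence(genome, arr.tobytes().decode())


def coding_mask(genome: AnnotatedGenome) -> np.ndarray:
    """Boolean per-base mask: True where covered by >=1 gene interval."""
    mask = np.zeros(len(genome), dtype=bool)
    overlapping = False
    prev_end = None
    for g in genome.genes:
        if prev_end is not None and g.start < prev_end:
            overlapping = True
        prev_end = max(prev_end or 0, g.end)
        mask[g.start: g.end] = True
    if overlapping:
        warnings.warn(
            "overlapping genes: local null segments defined on the interval union"
        )
    return mask


def shuffle_local(genome: AnnotatedGenome, seed: int) -> AnnotatedGenome:
    """Per-segment uniform permutation within maximal coding/non-coding runs.

    Segments are the maximal runs of the coding/non-coding per-base mask
    derived from the union of gene intervals; on a circular genome a run
    crossing the origin is one segment.
    """
    rng = np.random.default_rng(seed)
    n = len(genome)
    mask = coding_mask(genome)
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()

    # segment boundaries: positions where the mask switches value
    switches = np.nonzero(mask != np.roll(mask, 1))[0]
    if len(switches) == 0:
        rng.shuffle(arr)
        return _clone_with_sequence(genome, arr.tobytes().decode())
    segments = []
    if genome.circular:
        for i, s in enumerate(switches):
            e = switches[(i + 1) % len(switches)]
            segments.append((int(s), int(e)))  # [s, e) mod n
    else:
        bounds = [0] + [int(s) for s in switches] + [n]
        segments = [(a, b) for a, b in zip(bounds, bounds[1:]) if a < b]
    for s, e in segments:
        if genome.circular and e <= s:
            idx = np.concatenate((np.arange(s, n), np.arange(0, e)))
        else:
            idx = np.arange(s, e)
        vals = arr[idx]
        rng.shuffle(vals)
        arr[idx] = vals
    return _clone_with_sequence(genome, arr.tobytes().decode())
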