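"""Degenerate consensus scanning for NAP binding sites and two-box promoters.

IUPAC patterns are matched exactly (every pattern position must be
satisfied); the two-box promoter model instead scores each box by the
fraction of matching positions and accepts placements where both boxes
reach a similarity tolerance and the spacer length falls in a closed
range, both boxes on the same strand and in 5'->3' order.

Expected hit counts under an i.i.d. base model, and a Poisson
under/over-representation test, support the comparison of observed
site counts with random expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import stats

from .genome_model import revcomp

__all__ = [
    "IUPAC",
    "MotifPattern",
    "MotifHit",
    "TwoBoxPromoterModel",
    "TwoBoxHit",
    "load_motifs",
    "iupac_scan",
    "two_box_scan",
    "expected_hit_count",
    "representation_test",
    "hits_to_bed",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern."""
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    name: str
    iupac: str

    def __post_init__(self):
        if not self.iupac:
            raise ValueError("empty pattern")
        bad = set(self.iupac) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)} in {self.name!r}")

    def __len__(self):
        return len(self.iupac)


@dataclass(frozen=True)
class MotifHit:
    position: int   # 0-based start on the forward strand
    strand: str
    matched: str    # site read on the hit's strand


@dataclass(frozen=True)
class TwoBoxPromoterModel:
    box1: str
    box2: str
    spacer_min: int
    spacer_max: int
    min_similarity: float

    def __post_init__(self):
        if not self.box1 or not self.box2:
            raise ValueError("boxes must be non-empty")
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValueError("min_similarity must lie in [0, 1]")


@dataclass(frozen=True)
class TwoBoxHit:
    strand: str
    box1_position: int   # forward-strand start of box1's occupied interval
    spacer_len: int
    box2_position: int
    similarity1: float
    similarity2: float


def load_motifs():
    """Shipped NAP consensus motifs and the sigma-32 two-box model."""
    with resources.files("endoreg.data").joinpath("motifs.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    motifs = [MotifPattern(name, pat) for name, pat in raw["motifs"].items()]
    s32 = raw["sigma32"]
    model = TwoBoxPromoterModel(
        s32["box1"], s32["box2"], s32["spacer_min"], s32["spacer_max"],
        s32["min_similarity"],
    )
    return motifs, model


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int64)
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    for base, code in _CODE.items():
        out[raw == ord(base)] = code
    return out


def _allowed_matrix(pattern: str) -> np.ndarray:
    """(k, 5) booleans: which base code (A,C,G,T, invalid) matches position j."""
    k = len(pattern)
    allowed = np.zeros((k, 5), dtype=bool)
    for j, sym in enumerate(pattern):
        for base in IUPAC[sym]:
            allowed[j, _CODE[base]] = True
    return allowed


def _match_positions(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Start positions where the pattern matches exactly (vectorized)."""
    k = len(pattern)
    n = len(codes)
    if k > n:
        return np.empty(0, dtype=np.int64)
    allowed = _allowed_matrix(pattern)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        ok &= allowed[j][codes[j: j + n - k + 1] % 5]
        # invalid bases are code -1 -> column 4 -> never allowed
    return np.nonzero(ok)[0]


def iupac_scan(seq: str, pattern, strands=("+", "-"),
               circular: bool = False) -> "list[MotifHit]":
    """All (overlapping) placements of a degenerate pattern.

    Minus-strand hits are reported at their forward-strand start
    coordinate, with ``matched`` read on the minus strand.  On circular
    sequences the scan crosses the origin; start positions are reported
    modulo the sequence length.
    """
    pat = pattern.iupac if isinstance(pattern, MotifPattern) else str(pattern)
    MotifPattern("query", pat)  # validate symbols
    n = len(seq)
    k = len(pat)
    if k > n:
        return []
    ext = seq + seq[: k - 1] if circular and k > 1 else seq
    codes = _encode(ext)
    hits = []
    for strand in strands:
        scan_pat = pat if strand == "+" else revcomp_pattern(pat)
        for s in _match_positions(codes, scan_pat):
            s = int(s)
            if circular and s >= n:
                continue
            site = ext[s: s + k]
            hits.append(MotifHit(s, strand, site if strand == "+" else revcomp(site)))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _similarity_track(codes: np.ndarray, box: str) -> np.ndarray:
    """Per-start fraction of box positions matched (IUPAC-aware)."""
    k = len(box)
    n = len(codes)
    if k > n:
        return np.empty(0)
    allowed = _allowed_matrix(box)
    m = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        m += allowed[j][codes[j: j + n - k + 1] % 5]
    return m / k


def two_box_scan(seq: str, model: TwoBoxPromoterModel, strands=("+", "-"),
                 circular: bool = False) -> "list[TwoBoxHit]":
    """Two-box promoter placements with constrained spacer.

    Both boxes must sit on the same strand, box1 5' of box2, separated
    by ``spacer_min..spacer_max`` bp, each with IUPAC-aware similarity
    >= ``min_similarity`` (inclusive).
    """
    n = len(seq)
    k1, k2 = len(model.box1), len(model.box2)
    total_max = k1 + model.spacer_max + k2
    ext = seq + seq[: total_max - 1] if circular and total_max > 1 else seq
    hits = []
    for strand in strands:
        s = ext if strand == "+" else revcomp(ext)
        codes = _encode(s)
        sim1 = _similarity_track(codes, model.box1)
        sim2 = _similarity_track(codes, model.box2)
        cand1 = np.nonzero(sim1 >= model.min_similarity)[0]
        ok2 = sim2 >= model.min_similarity
        for p1 in cand1:
            p1 = int(p1)
            if circular and p1 >= n:
                continue
            for spacer in range(model.spacer_min, model.spacer_max + 1):
                p2 = p1 + k1 + spacer
                if p2 >= len(ok2) or not ok2[p2]:
                    continue
                if strand == "+":
                    fwd1, fwd2 = p1 % n if circular else p1, p2 % n if circular else p2
                else:
                    # positions on the reverse string map back to forward starts
                    fwd1 = len(s) - p1 - k1
                    fwd2 = len(s) - p2 - k2
                    if circular:
                        fwd1 %= n
                        fwd2 %= n
                hits.append(
                    TwoBoxHit(strand, fwd1, spacer, fwd2,
                              float(sim1[p1]), float(sim2[p2]))
                )
    hits.sort(key=lambda h: (h.box1_position, h.strand, h.spacer_len))
    return hits


def expected_hit_count(pattern, composition, seq_len: int,
                       strands=("+", "-"), circular: bool = False) -> float:
    """Expected exact-match count under an i.i.d. base model.

    ``composition`` is a probability vector or mapping over A,C,G,T.
    Per strand the expectation is (number of placements) x prod_j
    P(base matches position j); placements are ``seq_len - k + 1`` on a
    linear sequence and ``seq_len`` on a circular one.
    """
    pat = pattern.iupac if isinstance(pattern, MotifPattern) else str(pattern)
    if isinstance(composition, dict):
        comp = np.array([composition[b] for b in "ACGT"], dtype=float)
    else:
        comp = np.asarray(composition, dtype=float)
    if abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must sum to 1")
    k = len(pat)
    placements = seq_len if circular else max(seq_len - k + 1, 0)
    total = 0.0
    for strand in strands:
        p = pat if strand == "+" else revcomp_pattern(pat)
        prob = 1.0
        for sym in p:
            prob *= sum(comp[_CODE[b]] for b in IUPAC[sym])
        total += placements * prob
    return total


def representation_test(observed_count: int, expected_count: float):
    """Two-sided Poisson exact p-value and normal-approximation z-score.

    Returns ``(z, p)``.  The two-sided p doubles the smaller tail
    (P(X <= obs) vs P(X >= obs)) and is capped at 1.
    """
    if expected_count < 0:
        raise ValueError("expected count must be >= 0")
    if expected_count == 0:
        if observed_count > 0:
            warnings.warn("expected count 0 with observed > 0; p = 0")
            return np.inf, 0.0
        return 0.0, 1.0
    z = (observed_count - expected_count) / np.sqrt(expected_count)
    lower = stats.poisson.cdf(observed_count, expected_count)
    upper = stats.poisson.sf(observed_count - 1, expected_count)
    p = min(1.0, 2.0 * min(lower, upper))
    return float(z), float(p)


def hits_to_bed(hits, path, name: str = "motif", chrom: str = "genome"):
    """Write motif or two-box hits as BED6 (score = round(100 * min similarity))."""
    with open(path, "w") as fh:
        for h in hits:
            if isinstance(h, MotifHit):
                start, end = h.position, h.position + len(h.matched)
                score, strand = 100, h.strand
            else:
                start = min(h.box1_position, h.box2_position)
                end = max(h.box1_position + 1, h.box2_position + 1)
                score = round(100 * min(h.similarity1, h.similarity2))
                strand = h.strand
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
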