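"""Intergenic-region classification and promoter-window stability statistics.

Intergenic regions are classified by the strands of their flanking
genes — *divergent* (two 5' UTRs, ``<- . ->``), *convergent* (two 3'
UTRs, ``-> . <-``) or *tandem* (one 3' and one 5' UTR, same strand) —
and tandem regions are further split by whether both flanking genes
belong to the same transcription unit (*intra-TU*) or not (*inter-TU*).
Per-region and per-gene (fixed upstream window) statistics are computed
from any per-base structural profile, typically the SIDD track, and a
bimodality assessment (Hartigan dip statistic with a bootstrap p-value,
plus a 1- vs 2-component Gaussian-mixture BIC comparison) operationalises
the visual stable/unstable split of tandem regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome_model import AnnotatedGenome

__all__ = [
    "IntergenicRegion",
    "PromoterWindowStat",
    "classify_intergenic",
    "annotate_tu_relation",
    "region_profile_stats",
    "promoter_window_values",
    "dip_statistic",
    "dip_test",
    "bimodality_assessment",
    "regions_to_bed",
]


@dataclass(frozen=True)
class IntergenicRegion:
    start: int                # 0-based half-open; may wrap on circular genomes
    end: int                  # end <= start encodes an origin-spanning region
    left_gene: str
    right_gene: str
    orientation_class: str    # {divergent, convergent, tandem}
    tu_relation: str = "not_applicable"  # {intra_tu, inter_tu, not_applicable}

    def length(self, genome_length: int) -> int:
        if self.end > self.start:
            return self.end - self.start
        return genome_length - self.start + self.end

    def positions(self, genome_length: int) -> np.ndarray:
        if self.end > self.start:
            return np.arange(self.start, self.end)
        return np.concatenate(
            (np.arange(self.start, genome_length), np.arange(0, self.end))
        )


@dataclass(frozen=True)
class PromoterWindowStat:
    gene_id: str
    window_bp: int
    value: float
    truncated: bool = False


def _orientation(left_strand: str, right_strand: str) -> str:
    if left_strand == right_strand:
        return "tandem"
    if left_strand == "-" and right_strand == "+":
        return "divergent"
    return "convergent"


def classify_intergenic(genome: AnnotatedGenome) -> "list[IntergenicRegion]":
    """One region per adjacent gene pair with a positive gap.

    Zero-length gaps are skipped; overlapping gene pairs produce no
    region (with a warning).  On a circular genome the origin-spanning
    gap between the last and first gene is included.
    """
    genes = genome.genes
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to define intergenic regions")
    n = len(genome)
    out = []
    pairs = list(zip(genes, genes[1:]))
    if genome.circular:
        pairs.append((genes[-1], genes[0]))
    for left, right in pairs:
        if right.start >= left.end:
            gap = right.start - left.end
            start, end = left.end, right.start
        else:
            # candidate wrap (last->first) or overlap
            if genome.circular and right is genes[0] and left is genes[-1]:
                gap = n - left.end + right.start
                start, end = left.end % n, right.start
                if gap <= 0 or gap >= n:
                    continue
            else:
                warnings.warn(
                    f"overlapping genes {left.id!r}/{right.id!r}: no intergenic region"
                )
                continue
        if gap == 0:
            continue
        out.append(
            IntergenicRegion(start, end, left.id, right.id,
                             _orientation(left.strand, right.strand))
        )
    return out


def annotate_tu_relation(regions, tus) -> "list[IntergenicRegion]":
    """Set ``tu_relation`` on tandem regions from TU membership.

    A tandem region is *intra_tu* iff both flanking genes belong to the
    same TU; genes not covered by the TU table count as *inter_tu*.
    Divergent and convergent regions keep ``not_applicable``.
    """
    tu_of = {}
    for tu in tus:
        for gid in tu.gene_ids:
            tu_of[gid] = tu.id
    out = []
    for r in regions:
        if r.orientation_class != "tandem":
            out.append(replace(r, tu_relation="not_applicable"))
            continue
        tl, tr = tu_of.get(r.left_gene), tu_of.get(r.right_gene)
        rel = "intra_tu" if (tl is not None and tl == tr) else "inter_tu"
        out.append(replace(r, tu_relation=rel))
    return out


def region_profile_stats(regions, per_base, genome_length: int,
                         statistic: str = "mean") -> pd.DataFrame:
    """Per-region profile statistic, with orientation class attached.

    ``statistic`` is ``mean`` or ``min`` over the region's per-base
    values (NaN-masked positions excluded).
    """
    if statistic not in ("mean", "min"):
        raise ValueError("statistic must be 'mean' or 'min'")
    per_base = np.asarray(per_base, dtype=float)
    rows = []
    fn = np.nanmean if statistic == "mean" else np.nanmin
    for i, r in enumerate(regions):
        vals = per_base[r.positions(genome_length)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = float(fn(vals)) if len(vals) else np.nan
        rows.append(
            (f"ig{i:05d}", r.left_gene, r.right_gene, r.orientation_class,
             r.tu_relation, r.length(genome_length), v)
        )
    return pd.DataFrame(
        rows,
        columns=["region_id", "left_gene", "right_gene", "orientation_class",
                 "tu_relation", "length", "value"],
    )


def promoter_window_values(genome: AnnotatedGenome, per_base,
                           window_bp: int = 150,
                           clip_to_gap: bool = False) -> "list[PromoterWindowStat]":
    """Mean profile value in the fixed window upstream of each CDS start.

    The window is strand-aware and by default fixed-length regardless of
    the intergenic gap (it may overlap the upstream gene);
    ``clip_to_gap=True`` instead truncates it at the nearest upstream
    gene boundary.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    per_base = np.asarray(per_base, dtype=float)
    n = len(genome)
    sorted_bounds = sorted((g.start, g.end) for g in genome.genes)
    out = []
    for g in genome.coding_genes():
        length = window_bp
        if clip_to_gap:
            gap = _upstream_gap(g, sorted_bounds, n, genome.circular)
            length = max(1, min(window_bp, gap))
        if g.strand == "+":
            pos = np.arange(g.start - length, g.start)
        else:
            pos = np.arange(g.end, g.end + length)
        truncated = False
        if genome.circular:
            pos = pos % n
        else:
            keep = (pos >= 0) & (pos < n)
            truncated = not keep.all()
            pos = pos[keep]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            v = float(np.nanmean(per_base[pos])) if len(pos) else np.nan
        out.append(PromoterWindowStat(g.id, length, v, truncated))
    return out


def _upstream_gap(gene, sorted_bounds, n, circular) -> int:
    """Distance from the gene's 5' end to the nearest upstream gene."""
    starts = [s for s, _ in sorted_bounds]
    ends = [e for _, e in sorted_bounds]
    if gene.strand == "+":
        cands = [gene.start - e for e in ends if e <= gene.start]
        if cands:
            return min(cands)
        if circular and ends:
            return gene.start + n - max(ends)
    else:
        cands = [s - gene.end for s in starts if s >= gene.end]
        if cands:
            return min(cands)
        if circular and starts:
            return n - gene.end + min(starts)
    return n


# ---------------------------------------------------------------------------
# Bimodality: Hartigan dip + Gaussian-mixture BIC
# ---------------------------------------------------------------------------

def _lower_hull(x, y):
    hull = [0]
    for i in range(1, len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (y[b] - y[a]) * (x[i] - x[a]) >= (y[i] - y[a]) * (x[b] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull]), np.array(hull)


def _upper_hull(x, y):
    fit, hull = _lower_hull(x, -np.asarray(y, dtype=float))
    return -fit, hull


def dip_statistic(values) -> float:
    """Hartigan's dip: sup-norm distance from the ECDF to unimodality.

    Computed by iteratively shrinking to the modal interval between the
    greatest convex minorant (of the ECDF left limits) and the least
    concave majorant (of its right limits); 0 for degenerate samples.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        return 0.0
    xs, counts = np.unique(x, return_counts=True)
    if len(xs) == 1:
        return 0.0
    w = counts / n
    Fr_all = np.cumsum(w)          # right limits
    Fl_all = Fr_all - w            # left limits
    lo, hi = 0, len(xs) - 1
    D = 0.0
    while True:
        xx = xs[lo: hi + 1]
        Fr = Fr_all[lo: hi + 1]
        Fl = Fl_all[lo: hi + 1]
        if len(xx) < 2:
            break
        gcm_fit, gcm_t = _lower_hull(xx, Fl)
        lcm_fit, lcm_t = _upper_hull(xx, Fr)
        gap = lcm_fit - gcm_fit
        d_left_all = gap[gcm_t]
        d_right_all = gap[lcm_t]
        d_left = float(d_left_all.max())
        d_right = float(d_right_all.max())
        d = max(d_left, d_right)
        if d <= D:
            break
        if d_right > d_left:
            xr = int(lcm_t[d_right_all >= d_right - 1e-15][-1])
            cand = gcm_t[gcm_t <= xr]
            xl = int(cand[-1]) if len(cand) else 0
        else:
            xl = int(gcm_t[d_left_all >= d_left - 1e-15][0])
            cand = lcm_t[lcm_t >= xl]
            xr = int(cand[0]) if len(cand) else len(xx) - 1
        left_dev = float(np.max(Fr[: xl + 1] - gcm_fit[: xl + 1])) if xl >= 0 else 0.0
        right_dev = float(np.max(lcm_fit[xr:] - Fl[xr:])) if xr <= len(xx) - 1 else 0.0
        D = max(D, left_dev, right_dev)
        if xl >= xr or (xl == 0 and xr == len(xx) - 1):
            D = max(D, d)
            break
        lo, hi = lo + xl, lo + xr
    return D / 2.0


def dip_test(values, n_boot: int = 500, seed: int = 0):
    """Dip statistic with a bootstrap p-value against the uniform null."""
    values = np.asarray(values, dtype=float)
    d = dip_statistic(values)
    rng = np.random.default_rng(seed)
    n = len(values)
    boot = np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])
    p = (1 + np.sum(boot >= d)) / (n_boot + 1)
    return d, float(p)


def bimodality_assessment(values, seed: int = 0, n_boot: int = 500) -> dict:
    """Dip test plus 1- vs 2-component Gaussian-mixture BIC comparison.

    Verdict is 'bimodal' iff BIC(2) < BIC(1) - 2 or dip p < 0.05.
    Requires n >= 10.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 10:
        raise ValueError("bimodality assessment requires n >= 10")
    d, p = dip_test(values, n_boot=n_boot, seed=seed)
    if np.ptp(values) == 0:
        return {
            "dip_statistic": 0.0, "dip_p": 1.0,
            "means": (float(values[0]),), "weights": (1.0,),
            "bic_1comp": np.nan, "bic_2comp": np.nan,
            "verdict": "unimodal",
        }
    from sklearn.mixture import GaussianMixture

    X = values.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=seed).fit(X)
    gm2 = GaussianMixture(2, n_init=3, random_state=seed).fit(X)
    bic1, bic2 = float(gm1.bic(X)), float(gm2.bic(X))
    verdict = "bimodal" if (bic2 < bic1 - 2.0 or p < 0.05) else "unimodal"
    return {
        "dip_statistic": d,
        "dip_p": p,
        "means": tuple(float(m) for m in gm2.means_.ravel()),
        "weights": tuple(float(w) for w in gm2.weights_),
        "bic_1comp": bic1,
        "bic_2comp": bic2,
        "verdict": verdict,
    }


def regions_to_bed(regions, path, genome_length: int, chrom: str = "genome"):
    """Regions as BED with the orientation class (and TU relation) as name."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.orientation_class
            if r.tu_relation != "not_applicable":
                name += f"_{r.tu_relation}"
            if r.end > r.start:
                fh.write(f"{chrom}\t{r.start}\t{r.end}\t{name}\t0\t.\n")
            else:  # origin-spanning: emit two BED lines
                fh.write(f"{chrom}\t{r.start}\t{genome_length}\t{name}\t0\t.\n")
                fh.write(f"{chrom}\t0\t{r.end}\t{name}\t0\t.\n")
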