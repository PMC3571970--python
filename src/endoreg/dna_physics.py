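"""Per-base calculators for sequence-dependent physical properties of DNA.

Four properties are computed, each as one value per base of the input
sequence:

* **base-stacking energy** and **base-pair propeller twist** — direct
  dinucleotide-table lookups, averaged over the two steps flanking a
  position;
* **intrinsic curvature** — a wedge model: per-step deflection vectors
  (roll, tilt) are summed over a centred window with a helical phase
  rotation of 360°/``helical_repeat`` per step, and the magnitude of the
  resultant bend, normalised per step, is reported;
* **SIDD** (stress-induced duplex destabilization) — a statistical-
  mechanical model of local strand separation under negative
  superhelical stress.  A state opens ``r`` runs totalling ``n`` base
  pairs with free energy

      G = a·r + Σ_open b(base) + (K/2)·(σ·N/h + n/h)²

  where ``a`` is the run-nucleation cost, ``b`` the base-pair
  separation energy (b_GC > b_AT), and the quadratic term the torsional
  energy of the residual linking difference.  The per-base opening
  probability is the Boltzmann-weighted fraction of states in which the
  base is open, with the state space restricted to at most two
  simultaneous runs of bounded length within an energy threshold θ of
  the ground state.  The reported destabilization energy is
  ``G(x) = −RT·ln(p(x)/(1−p(x)))``, clipped to a ceiling of ``θ + 2RT``
  so profiles stay bounded where opening is negligible.

Parameter tables ship as editable YAML under ``endoreg/data``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .genome_model import AnnotatedGenome, AnchoredWindow

__all__ = [
    "DinucleotideTable",
    "WedgeModel",
    "SIDDParams",
    "StructuralProfile",
    "load_dinucleotide_table",
    "load_wedge_model",
    "default_sidd_params",
    "dinucleotide_profile",
    "curvature_profile",
    "sidd_profile",
    "sidd_opening_probability",
    "window_smooth",
    "aligned_mean_profile",
]

R_KCAL = 1.9872e-3  # gas constant, kcal/(mol*K)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DINUCS = [a + b for a in "ACGT" for b in "ACGT"]


def _encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes; non-ACGT symbols -> -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for base, code in _CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return out


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DinucleotideTable:
    name: str
    values: dict
    units: str = ""

    def __post_init__(self):
        if set(self.values) != set(_DINUCS):
            raise ValueError(
                f"table {self.name!r} must define exactly the 16 dinucleotides"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"table {self.name!r} contains non-finite values")

    def as_array(self) -> np.ndarray:
        """4x4 array indexed by (first base code, second base code)."""
        arr = np.empty((4, 4))
        for d, v in self.values.items():
            arr[_CODE[d[0]], _CODE[d[1]]] = v
        return arr


@dataclass(frozen=True)
class WedgeModel:
    """Wedge deflection angles per step plus helical geometry."""

    wedge_angles: dict          # dinucleotide -> (roll, tilt) degrees
    helical_repeat: float = 10.5
    window_bp: int = 31

    def __post_init__(self):
        if self.helical_repeat <= 0:
            raise ValueError("helical_repeat must be > 0")
        if self.window_bp < self.helical_repeat:
            raise ValueError("window_bp must be >= helical_repeat")
        if set(self.wedge_angles) != set(_DINUCS):
            raise ValueError("wedge table must define exactly the 16 dinucleotides")

    def deflections(self) -> np.ndarray:
        """4x4 complex array roll + i*tilt."""
        arr = np.empty((4, 4), dtype=complex)
        for d, (roll, tilt) in self.wedge_angles.items():
            arr[_CODE[d[0]], _CODE[d[1]]] = complex(roll, tilt)
        return arr


@dataclass(frozen=True)
class SIDDParams:
    sigma: float = -0.055
    temperature_K: float = 310.0
    nucleation_energy_a: float = 12.0
    separation_energy: dict = field(
        default_factory=lambda: {"AT": 0.255, "GC": 1.301}
    )
    torsional_stiffness_K: float = 9.0
    helical_repeat_h: float = 10.5
    energy_threshold_theta: float = 12.0
    max_run_length: int = 150
    window_bp: int = 250
    flank_bp: int = 50
    max_runs: int = 2

    def __post_init__(self):
        if self.energy_threshold_theta is not None and self.energy_threshold_theta <= 0:
            raise ValueError("energy_threshold_theta must be > 0")
        b_at = self.separation_energy["AT"]
        b_gc = self.separation_energy["GC"]
        if not (b_gc > b_at > 0):
            raise ValueError("require b_GC > b_AT > 0")
        if self.nucleation_energy_a <= 0:
            raise ValueError("nucleation energy must be > 0")
        if self.window_bp < self.max_run_length:
            raise ValueError("window_bp must be >= max_run_length")
        if self.window_bp <= 2 * self.flank_bp:
            raise ValueError("window_bp must exceed twice the flank")

    @property
    def rt(self) -> float:
        return R_KCAL * self.temperature_K

    @property
    def ceiling(self) -> float:
        """Reported G(x) where opening probability underflows: θ + 2RT.

        With an unbounded state space (theta None) the default threshold
        of 12 kcal/mol still anchors the reporting ceiling.
        """
        theta = self.energy_threshold_theta
        return (12.0 if theta is None else theta) + 2.0 * self.rt

    def per_base_energy(self, codes: np.ndarray) -> np.ndarray:
        """Separation energy per base; +inf for masked (non-ACGT) bases."""
        b = np.empty(len(codes))
        b_at = self.separation_energy["AT"]
        b_gc = self.separation_energy["GC"]
        lut = np.array([b_at, b_gc, b_gc, b_at])  # A C G T
        valid = codes >= 0
        b[valid] = lut[codes[valid]]
        b[~valid] = np.inf
        return b


def _load_yaml(name: str) -> dict:
    with resources.files("endoreg.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_dinucleotide_table(name: str) -> DinucleotideTable:
    """Load a shipped dinucleotide table: 'stacking_energy' or 'propeller_twist'."""
    raw = _load_yaml(f"{name}.yaml")
    return DinucleotideTable(raw["name"], dict(raw["values"]), raw.get("units", ""))


def load_wedge_model() -> WedgeModel:
    raw = _load_yaml("wedge_angles.yaml")
    angles = {d: (v["roll"], v["tilt"]) for d, v in raw["values"].items()}
    return WedgeModel(angles, raw["helical_repeat"], raw["window_bp"])


def default_sidd_params(**overrides) -> SIDDParams:
    raw = _load_yaml("sidd_params.yaml")
    params = SIDDParams(
        sigma=raw["sigma"],
        temperature_K=raw["temperature_K"],
        nucleation_energy_a=raw["nucleation_energy_a"],
        separation_energy=dict(raw["separation_energy"]),
        torsional_stiffness_K=raw["torsional_stiffness_K"],
        helical_repeat_h=raw["helical_repeat_h"],
        energy_threshold_theta=raw["energy_threshold_theta"],
        max_run_length=raw["max_run_length"],
        window_bp=raw["window_bp"],
        flank_bp=raw["flank_bp"],
        max_runs=raw["max_runs"],
    )
    return replace(params, **overrides) if overrides else params


# ---------------------------------------------------------------------------
# Dinucleotide-table profiles
# ---------------------------------------------------------------------------

def dinucleotide_profile(seq: str, table: DinucleotideTable,
                         circular: bool = False) -> np.ndarray:
    """Per-base profile of a dinucleotide property.

    The value at position i is the mean of the table values of the steps
    overlapping i (steps i-1..i and i..i+1; a single step at the ends of
    a linear sequence).  Steps containing a non-ACGT symbol are masked;
    a position whose overlapping steps are all masked is NaN.
    """
    n = len(seq)
    if n < 2:
        raise ValueError("sequence must be at least 2 bp")
    codes = _encode(seq)
    arr = table.as_array()
    first, second = codes[:-1], codes[1:]
    step = np.full(n - 1, np.nan)
    ok = (first >= 0) & (second >= 0)
    step[ok] = arr[first[ok], second[ok]]
    if circular:
        wrap = np.nan
        if codes[-1] >= 0 and codes[0] >= 0:
            wrap = arr[codes[-1], codes[0]]
        left = np.concatenate(([wrap], step))    # step ending at i
        right = np.concatenate((step, [wrap]))   # step starting at i
    else:
        left = np.concatenate(([np.nan], step))
        right = np.concatenate((step, [np.nan]))
    both = np.stack([left, right])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(both, axis=0)


# ---------------------------------------------------------------------------
# Curvature
# ---------------------------------------------------------------------------

def curvature_profile(seq: str, wedge: WedgeModel, circular: bool = False) -> np.ndarray:
    """Intrinsic curvature per base under the wedge model (degrees/step).

    Each dinucleotide step contributes a deflection vector (roll, tilt)
    rotated by 360°/helical_repeat per step; the curvature at a position
    is the magnitude of the resultant over the centred window divided by
    the number of steps summed.  Values are >= 0.
    """
    n = len(seq)
    w = wedge.window_bp
    if not circular and n < w:
        raise ValueError(f"sequence ({n} bp) shorter than curvature window ({w} bp)")
    codes = _encode(seq)
    defl = wedge.deflections()
    if circular:
        first = codes
        second = np.roll(codes, -1)
    else:
        first, second = codes[:-1], codes[1:]
    n_steps = len(first)
    ok = (first >= 0) & (second >= 0)
    z = np.zeros(n_steps, dtype=complex)
    z[ok] = defl[first[ok], second[ok]]
    omega = 2.0 * np.pi / wedge.helical_repeat
    phase = np.exp(1j * omega * np.arange(n_steps))
    zp = z * phase
    bad = (~ok).astype(np.int64)

    half = w // 2
    lo = np.arange(n) - half
    hi = lo + (w - 1)  # steps in [lo, hi): w-1 steps for a w-bp window
    if circular:
        reps = int(np.ceil((n + w) / n_steps)) + 1
        zt = np.tile(zp, reps)
        bt = np.tile(bad, reps)
        cz = np.concatenate(([0], np.cumsum(zt)))
        cb = np.concatenate(([0], np.cumsum(bt)))
        lo_i = lo % n_steps
        span = hi - lo
        s = cz[lo_i + span] - cz[lo_i]
        nbad = cb[lo_i + span] - cb[lo_i]
        count = span
    else:
        lo_c = np.clip(lo, 0, n_steps)
        hi_c = np.clip(hi, 0, n_steps)
        cz = np.concatenate(([0], np.cumsum(zp)))
        cb = np.concatenate(([0], np.cumsum(bad)))
        s = cz[hi_c] - cz[lo_c]
        nbad = cb[hi_c] - cb[lo_c]
        count = np.maximum(hi_c - lo_c, 1)
    out = np.abs(s) / count
    out[nbad > 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# SIDD
# ---------------------------------------------------------------------------

def _pair_valid_linear(s1, l1, s2, l2):
    """Two runs on a linear domain are a valid state iff separated by >=1 bp."""
    return (s2 >= s1 + l1 + 1) | (s1 >= s2 + l2 + 1)


def _domain_opening_probability(b: np.ndarray, params: SIDDParams,
                                circular: bool) -> np.ndarray:
    """Opening probability per base for one superhelical domain.

    ``b`` holds per-base separation energies (+inf for masked bases).
    Enumerates the closed state, all single-run states and (when
    ``max_runs >= 2``) two-run states, restricted to runs of at most
    ``max_run_length`` bp and to states within ``energy_threshold_theta``
    of the minimum-energy state (no restriction when the threshold is
    None).
    """
    n = len(b)
    rt = params.rt
    a = params.nucleation_energy_a
    h = params.helical_repeat_h
    K = params.torsional_stiffness_K
    theta = params.energy_threshold_theta
    alpha0 = params.sigma * n / h
    lmax = min(params.max_run_length, n - 1 if circular else n)

    def quad(n_open):
        return 0.5 * K * (alpha0 + n_open / h) ** 2

    g_closed = quad(0)

    # --- single runs -----------------------------------------------------
    finite_b = np.where(np.isfinite(b), b, np.inf)
    if circular:
        prefix = np.concatenate(([0.0], np.cumsum(np.concatenate((finite_b, finite_b)))))
        starts_all = np.arange(n)
    else:
        prefix = np.concatenate(([0.0], np.cumsum(finite_b)))
    runs_s, runs_l, runs_g = [], [], []
    g_min = g_closed
    for l in range(1, lmax + 1):
        if circular:
            s = starts_all
            B = prefix[s + l] - prefix[s]
        else:
            s = np.arange(0, n - l + 1)
            B = prefix[s + l] - prefix[s]
        G = a + B + quad(l)
        keep = np.isfinite(G)
        if not np.any(keep):
            continue
        runs_s.append(s[keep])
        runs_l.append(np.full(keep.sum(), l))
        runs_g.append(G[keep])
        g_min = min(g_min, float(G[keep].min()))

    if runs_s:
        rs = np.concatenate(runs_s)
        rl = np.concatenate(runs_l)
        rg = np.concatenate(runs_g)
    else:
        rs = np.empty(0, dtype=np.int64)
        rl = np.empty(0, dtype=np.int64)
        rg = np.empty(0)

    cutoff = np.inf if theta is None else g_min + theta
    keep1 = rg <= cutoff

    diff = np.zeros(n + 1)

    def add_interval(s_arr, l_arr, w_arr):
        if len(s_arr) == 0:
            return
        e_arr = s_arr + l_arr
        if circular:
            wrap = e_arr > n
            nw = ~wrap
            np.add.at(diff, s_arr[nw], w_arr[nw])
            np.add.at(diff, e_arr[nw], -w_arr[nw])
            if np.any(wrap):
                np.add.at(diff, s_arr[wrap], w_arr[wrap])
                diff[n] -= w_arr[wrap].sum()
                diff[0] += w_arr[wrap].sum()
                np.add.at(diff, e_arr[wrap] - n, -w_arr[wrap])
        else:
            np.add.at(diff, s_arr, w_arr)
            np.add.at(diff, e_arr, -w_arr)

    z = math.exp(-(g_closed - g_min) / rt)
    w1 = np.exp(-(rg[keep1] - g_min) / rt)
    z += float(w1.sum())
    add_interval(rs[keep1], rl[keep1], w1)

    # --- two-run states --------------------------------------------------
    if params.max_runs >= 2 and len(rs) > 0:
        # intrinsic run cost a + B; the pair energy is c1 + c2 + quad(l1+l2)
        # and quad >= 0, so runs with c above (cutoff - min c) cannot appear
        # in any retained pair.
        c = rg - quad(rl)  # = a + B
        c_min = float(c.min())
        if theta is None:
            cand = np.arange(len(rs))
        else:
            cand = np.nonzero(c <= cutoff - c_min)[0]
        max_cand = 5000
        if len(cand) > max_cand:
            warnings.warn(
                f"two-run candidate set truncated to the {max_cand} lowest-energy runs"
            )
            cand = cand[np.argsort(c[cand])[:max_cand]]
        cs, cl, cc = rs[cand], rl[cand], c[cand]
        order = np.argsort(cc)
        cs, cl, cc = cs[order], cl[order], cc[order]
        m = len(cs)
        for i in range(m - 1):
            if theta is not None and cc[i] + cc[i] > cutoff:
                break  # sorted: no later pair can pass either
            s1, l1, c1 = cs[i], cl[i], cc[i]
            s2, l2, c2 = cs[i + 1:], cl[i + 1:], cc[i + 1:]
            g_pair = c1 + c2 + quad(l1 + l2)
            ok = np.isfinite(g_pair)
            if theta is not None:
                ok &= g_pair <= cutoff
            if circular:
                g12 = (s2 - (s1 + l1)) % n
                g21 = (s1 - (s2 + l2)) % n
                ok &= (g12 >= 1) & (g21 >= 1) & (l1 + l2 + g12 + g21 == n)
            else:
                ok &= _pair_valid_linear(s1, l1, s2, l2)
            if not np.any(ok):
                continue
            w = np.exp(-(g_pair[ok] - g_min) / rt)
            z += float(w.sum())
            add_interval(np.full(ok.sum(), s1), np.full(ok.sum(), l1), w)
            add_interval(s2[ok], l2[ok], w)

    open_states = keep1.sum()
    p = np.cumsum(diff[:n]) / z
    p = np.clip(p, 0.0, 1.0)
    if open_states == 0 and theta is not None:
        warnings.warn(
            "energy threshold admits no open state; profile is all-ceiling"
        )
    p[~np.isfinite(b)] = np.nan
    return p


def sidd_opening_probability(seq: str, params: SIDDParams = None,
                             circular: bool = True) -> np.ndarray:
    """Per-base opening probability p(x) under superhelical stress.

    Sequences no longer than ``window_bp`` are solved as a single domain
    (circular domains enumerate wrapping runs exactly); longer sequences
    are processed in overlapping ``window_bp`` windows whose ``flank_bp``
    edges are discarded, each window being treated as an independent
    linear domain of its own length.
    """
    if params is None:
        params = default_sidd_params()
    n = len(seq)
    codes = _encode(seq)
    b = params.per_base_energy(codes)
    if n <= params.window_bp:
        return _domain_opening_probability(b, params, circular)

    window, flank = params.window_bp, params.flank_bp
    step = window - 2 * flank
    p = np.full(n, np.nan)
    n_windows = int(np.ceil(n / step))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n_windows):
            r0 = i * step
            r1 = min(r0 + step, n)  # retained genome positions [r0, r1)
            if circular:
                w0 = r0 - flank
                idx = (np.arange(w0, w0 + window)) % n
                pw = _domain_opening_probability(b[idx], params, circular=False)
                p[r0:r1] = pw[flank: flank + (r1 - r0)]
            else:
                w0 = max(0, r0 - flank)
                w1 = min(n, r1 + flank)
                pw = _domain_opening_probability(b[w0:w1], params, circular=False)
                p[r0:r1] = pw[r0 - w0: r1 - w0]
    return p


def sidd_profile(seq: str, params: SIDDParams = None,
                 circular: bool = True) -> np.ndarray:
    """SIDD destabilization energy G(x) in kcal/mol (lower = less stable).

    ``G(x) = -RT ln(p(x)/(1-p(x)))``, clipped to ``θ + 2RT`` where the
    opening probability underflows.  Masked (non-ACGT) positions are NaN.
    """
    if params is None:
        params = default_sidd_params()
    p = sidd_opening_probability(seq, params, circular)
    rt = params.rt
    ceiling = params.ceiling
    g = np.full(len(p), ceiling)
    mask = np.isnan(p)
    pos = (~mask) & (p > 0)
    with np.errstate(divide="ignore", over="ignore"):
        g[pos] = -rt * np.log(p[pos] / (1.0 - p[pos]))
    g = np.minimum(g, ceiling)
    g[mask] = np.nan
    return g


# ---------------------------------------------------------------------------
# Smoothing, profile container, aligned averaging
# ---------------------------------------------------------------------------

def window_smooth(per_base: np.ndarray, window_bp: int) -> np.ndarray:
    """Means of consecutive non-overlapping windows; trailing partial dropped."""
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    per_base = np.asarray(per_base, dtype=float)
    n_win = len(per_base) // window_bp
    if n_win == 0:
        warnings.warn("window longer than profile; returning empty vector")
        return np.empty(0)
    trimmed = per_base[: n_win * window_bp].reshape(n_win, window_bp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(trimmed, axis=1)


@dataclass
class StructuralProfile:
    """A per-base physical-property track with a window-smoothed view."""

    property_name: str
    per_base: np.ndarray
    window_bp: int
    windowed: np.ndarray = None

    def __post_init__(self):
        self.per_base = np.asarray(self.per_base, dtype=float)
        if self.windowed is None:
            self.windowed = window_smooth(self.per_base, self.window_bp)

    def to_frame(self):
        import pandas as pd

        pos = np.arange(len(self.per_base))
        widx = pos // self.window_bp
        wmean = np.full(len(pos), np.nan)
        ok = widx < len(self.windowed)
        wmean[ok] = self.windowed[widx[ok]]
        return pd.DataFrame(
            {
                "position": pos,
                "raw": self.per_base,
                "window_index": widx,
                "window_mean": wmean,
            }
        )

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_bedgraph(self, path, chrom: str = "genome"):
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{self.property_name}"\n')
            for i, w in enumerate(self.windowed):
                if np.isnan(w):
                    continue
                fh.write(
                    f"{chrom}\t{i * self.window_bp}\t{(i + 1) * self.window_bp}\t{w:.6g}\n"
                )


def aligned_mean_profile(genome: AnnotatedGenome, per_base: np.ndarray,
                         windows: "list[AnchoredWindow]"):
    """Strand-aware mean profile over anchored windows.

    Returns ``(offsets, mean, n)`` where offset -k aggregates the value
    k bp upstream of each anchor; masked or truncated positions are
    excluded from the means.
    """
    if not windows:
        raise ValueError("need at least one anchored window")
    per_base = np.asarray(per_base, dtype=float)
    n_genome = len(genome)
    span_up = windows[0].span_up
    span_down = windows[0].span_down
    offsets = np.arange(-span_up, span_down)
    total = np.zeros(len(offsets))
    count = np.zeros(len(offsets), dtype=np.int64)
    for w in windows:
        pos = w.genomic_positions(n_genome, genome.circular)
        valid = pos >= 0
        vals = np.full(len(offsets), np.nan)
        vals[valid] = per_base[pos[valid]]
        ok = ~np.isnan(vals)
        total[ok] += vals[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return offsets, mean, count
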