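"""Independent brute-force oracles used to validate the implementations.

These deliberately use naive enumeration/loops, not the package's code
paths.
"""

import math

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def naive_iupac_positions(seq, pattern):
    """Forward-strand start positions by per-character checking."""
    k = len(pattern)
    out = []
    for s in range(len(seq) - k + 1):
        if all(seq[s + j] in IUPAC[pattern[j]] for j in range(k)):
            out.append(s)
    return out


def naive_box_similarity(window, box):
    return sum(window[j] in IUPAC[box[j]] for j in range(len(box))) / len(box)


def naive_two_box(seq, box1, box2, smin, smax, min_sim):
    """(box1_start, spacer, box2_start, sim1, sim2) on the given string."""
    out = []
    k1, k2 = len(box1), len(box2)
    for p1 in range(len(seq) - k1 + 1):
        s1 = naive_box_similarity(seq[p1: p1 + k1], box1)
        if s1 < min_sim:
            continue
        for spacer in range(smin, smax + 1):
            p2 = p1 + k1 + spacer
            if p2 + k2 > len(seq):
                continue
            s2 = naive_box_similarity(seq[p2: p2 + k2], box2)
            if s2 >= min_sim:
                out.append((p1, spacer, p2, s1, s2))
    return out


def naive_dinucleotide_profile(seq, values):
    """Per-position mean of the table values of overlapping steps."""
    n = len(seq)
    out = []
    for i in range(n):
        vals = []
        for a, b in ((i - 1, i), (i, i + 1)):
            if 0 <= a and b < n:
                d = seq[a] + seq[b]
                vals.append(values[d] if set(d) <= set("ACGT") else np.nan)
        out.append(np.nanmean(vals) if vals else np.nan)
    return np.array(out)


def naive_curvature(seq, wedge_angles, helical_repeat, window_bp):
    """Windowed vector sum of phased wedge deflections, per position."""
    n = len(seq)
    omega = 2 * np.pi / helical_repeat
    steps = []
    for j in range(n - 1):
        roll, tilt = wedge_angles[seq[j: j + 2]]
        steps.append((roll + 1j * tilt) * np.exp(1j * omega * j))
    half = window_bp // 2
    out = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n - 1, i - half + window_bp - 1)
        window = steps[lo:hi]
        out.append(abs(sum(window)) / max(len(window), 1))
    return np.array(out)


def exhaustive_sidd_p(seq, params):
    """Exact per-base opening probability over all 0/1/2-run states.

    Linear domain, no run-length bound, no energy threshold; plain loops
    over every pair of disjoint non-adjacent open intervals.
    """
    n = len(seq)
    b = np.array([params.separation_energy["AT"] if c in "AT"
                  else params.separation_energy["GC"] for c in seq])
    pre = np.concatenate(([0.0], np.cumsum(b)))
    rt = params.rt
    a = params.nucleation_energy_a
    K = params.torsional_stiffness_K
    h = params.helical_repeat_h
    alpha0 = params.sigma * n / h

    def g_quad(n_open):
        return 0.5 * K * (alpha0 + n_open / h) ** 2

    energies = [g_quad(0)]
    opens = [()]
    for s in range(n):
        for e in range(s + 1, n + 1):
            energies.append(a + (pre[e] - pre[s]) + g_quad(e - s))
            opens.append(((s, e),))
    for s1 in range(n):
        for e1 in range(s1 + 1, n + 1):
            b1 = pre[e1] - pre[s1]
            for s2 in range(e1 + 1, n):
                for e2 in range(s2 + 1, n + 1):
                    energies.append(
                        2 * a + b1 + (pre[e2] - pre[s2])
                        + g_quad((e1 - s1) + (e2 - s2))
                    )
                    opens.append(((s1, e1), (s2, e2)))
    energies = np.array(energies)
    gmin = energies.min()
    w = np.exp(-(energies - gmin) / rt)
    z = w.sum()
    p = np.zeros(n)
    for weight, intervals in zip(w, opens):
        for s, e in intervals:
            p[s:e] += weight
    return p / z


def brute_force_ccc(nodes, edges1, edges2):
    """Maximal sets connected in both graphs, by recursive splitting."""
    adj1 = {v: set() for v in nodes}
    adj2 = {v: set() for v in nodes}
    for u, v in edges1:
        if u in adj1 and v in adj1:
            adj1[u].add(v)
            adj1[v].add(u)
    for u, v in edges2:
        if u in adj2 and v in adj2:
            adj2[u].add(v)
            adj2[v].add(u)

    def components(vertices, adj):
        seen = set()
        out = []
        for v in vertices:
            if v in seen:
                continue
            stack, comp = [v], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] & vertices - comp)
            seen |= comp
            out.append(comp)
        return out

    def recurse(vertices):
        parts1 = components(vertices, adj1)
        if len(parts1) > 1:
            out = []
            for p in parts1:
                out.extend(recurse(p))
            return out
        parts2 = components(vertices, adj2)
        if len(parts2) > 1:
            out = []
            for p in parts2:
                out.extend(recurse(p))
            return out
        return [vertices]

    return {frozenset(c) for c in recurse(set(nodes)) if len(c) >= 2}


def exact_rank_sum_p_less(x, y):
    """One-sided (x stochastically smaller) exact rank-sum p, no ties."""
    from itertools import combinations

    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(x)
    count = 0
    total = 0
    for combo in combinations(pooled, n):
        total += 1
        if sum(ranks[v] for v in combo) <= w_obs:
            count += 1
    return count / total


def hypergeom_tail_enrich(k, M, n, N):
    """P(X >= k) for hypergeom(M, n, N) via binomial coefficients."""
    total = math.comb(M, N)
    return sum(
        math.comb(n, i) * math.comb(M - n, N - i) for i in range(k, min(n, N) + 1)
    ) / total
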