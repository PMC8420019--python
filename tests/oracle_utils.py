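"""Independent brute-force oracles shared across the test modules."""

import numpy as np
from scipy import stats


def _window_counts(seq: str, window: int):
    """Per-window C, G and fully-contained-CpG counts via convolution."""
    a = np.frombuffer(seq.encode(), np.uint8)
    is_c = (a == ord("C")).astype(float)
    is_g = (a == ord("G")).astype(float)
    is_cg = np.zeros(len(a))
    is_cg[:-1] = (a[:-1] == ord("C")) & (a[1:] == ord("G"))
    kern = np.ones(window)
    n_c = np.convolve(is_c, kern, mode="valid")
    n_g = np.convolve(is_g, kern, mode="valid")
    n_cg = np.convolve(is_cg, np.ones(window - 1), mode="valid")[: len(n_c)]
    return n_c, n_g, n_cg


def brute_force_islands(seq, window=100, min_len=200, min_gc=50.0, min_obsexp=0.6):
    """All-windows/merge/trim CpG-island definition, reimplemented plainly."""
    if len(seq) < window:
        return []
    n_c, n_g, n_cg = _window_counts(seq, window)
    gc_ok = (n_c + n_g) / window * 100.0 > min_gc
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((n_c > 0) & (n_g > 0), n_cg * window / (n_c * n_g), 0.0)
    qual = gc_ok & (oe > min_obsexp)
    a = np.frombuffer(seq.encode(), np.uint8)
    cpg_mask = np.zeros(len(a), dtype=bool)
    cpg_mask[:-1] = (a[:-1] == ord("C")) & (a[1:] == ord("G"))
    cpgs = np.nonzero(cpg_mask)[0]
    segments = []
    i = 0
    while i < len(qual):
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(qual) and qual[j + 1]:
            j += 1
        segments.append((i, j + window))
        i = j + 1
    out = []
    for s, e in segments:
        inner = cpgs[(cpgs >= s) & (cpgs + 2 <= e)]
        if len(inner) == 0:
            continue
        ts, te = int(inner[0]), int(inner[-1] + 2)
        if te - ts <= min_len:
            continue
        seg = seq[ts:te]
        c = seg.count("C")
        g = seg.count("G")
        cg = seg.count("CG")
        gc = 100.0 * (c + g) / len(seg)
        obs_exp = cg * len(seg) / (c * g) if c and g else 0.0
        if gc > min_gc and obs_exp > min_obsexp:
            out.append((ts, te))
    return out


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration: sum of
    table probabilities no larger than the observed one."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = stats.hypergeom(n, c1, r1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = rv.pmf(support)
    return probs[probs <= rv.pmf(a) * (1 + 1e-9)].sum()


def step_up_bh_oracle(p):
    """Literal Benjamini–Hochberg step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        q[i] = prev
    return q
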