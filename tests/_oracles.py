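"""Independent brute-force reference implementations.

Everything here is deliberately naive — explicit double loops over the
recurrence plot, pure-Python dictionaries, no shared code with the package —
so that agreement with the fast count-based implementation is a real check.
"""

from __future__ import annotations

import math
from collections import Counter


def oracle_symbolize(values, m):
    """Ordinal pattern per window via sorted(); ties broken by earlier offset."""
    out = []
    for t in range(len(values) - m + 1):
        window = values[t : t + m]
        perm = tuple(sorted(range(m), key=lambda i: (window[i], i)))
        out.append(perm)
    return out


def oracle_profile(symbols):
    """SRR per symbol, total SRR, probabilities and entropy by double loop."""
    n = len(symbols)
    rec = Counter()
    for t in range(n):
        for s in range(n):
            if t != s and symbols[t] == symbols[s]:
                rec[symbols[t]] += 1
    srr_by = {pi: c / (n * (n - 1)) for pi, c in rec.items()}
    srr = sum(srr_by.values())
    if srr == 0:
        return srr_by, srr, {}, float("nan")
    probs = {pi: v / srr for pi, v in srr_by.items()}
    entropy = -sum(p * math.log2(p) for p in probs.values() if p > 0)
    return srr_by, srr, probs, entropy


def oracle_entropy(symbols):
    return oracle_profile(symbols)[3]


def oracle_srr(symbols):
    return oracle_profile(symbols)[1]


def oracle_mi_literal(sym_x, sym_y):
    """H(x) + H(y) - H(x, y), each entropy from its own tuple recurrences."""
    pairs = list(zip(sym_x, sym_y))
    return oracle_entropy(sym_x) + oracle_entropy(sym_y) - oracle_entropy(pairs)


def oracle_te_literal(sym_source, sym_target, lag=1):
    """H(x+|x) - H(x+|x,y) with H(A|B) = H(A,B) - H(B), tuple-wise."""
    x1 = sym_target[lag:]
    x0 = sym_target[:-lag]
    y0 = sym_source[:-lag]
    h_x1x0 = oracle_entropy(list(zip(x1, x0)))
    h_x0 = oracle_entropy(list(x0))
    h_tri = oracle_entropy(list(zip(x1, x0, y0)))
    h_x0y0 = oracle_entropy(list(zip(x0, y0)))
    return (h_x1x0 - h_x0) - (h_tri - h_x0y0)


def _dist_entropy(weights):
    tot = sum(weights.values())
    if tot == 0:
        return float("nan")
    return -sum(
        (w / tot) * math.log2(w / tot) for w in weights.values() if w > 0
    )


def oracle_mi_joint_marginal(sym_x, sym_y):
    """All entropies from the pair recurrence distribution and its marginals."""
    pairs = list(zip(sym_x, sym_y))
    counts = Counter(pairs)
    w = {k: c * (c - 1) for k, c in counts.items()}
    wx, wy = Counter(), Counter()
    for (a, b), v in w.items():
        wx[a] += v
        wy[b] += v
    return _dist_entropy(wx) + _dist_entropy(wy) - _dist_entropy(w)


def oracle_te_joint_marginal(sym_source, sym_target, lag=1):
    triples = list(zip(sym_target[lag:], sym_target[:-lag], sym_source[:-lag]))
    counts = Counter(triples)
    w = {k: c * (c - 1) for k, c in counts.items()}
    w_x1x0, w_x0, w_x0y0 = Counter(), Counter(), Counter()
    for (x1, x0, y0), v in w.items():
        w_x1x0[(x1, x0)] += v
        w_x0[x0] += v
        w_x0y0[(x0, y0)] += v
    return (
        _dist_entropy(w_x1x0)
        - _dist_entropy(w_x0)
        - _dist_entropy(w)
        + _dist_entropy(w_x0y0)
    )
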