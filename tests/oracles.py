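"""Independent brute-force oracles used to validate the solvers and the
discretiser.  These deliberately avoid the package's own code paths."""

from __future__ import annotations

import math

import numpy as np


def exhaustive_min_k(inter_masks, intra_masks, alpha, beta):
    """Minimum feasible subset size by enumerating all 2^n feature subsets.

    Masks are boolean (pairs x features) arrays.  Returns (k_min, witness
    boolean vector) or (None, None) when no subset is feasible.  Only usable
    for small n (<= ~16).
    """
    n = inter_masks.shape[1] if inter_masks.size else intra_masks.shape[1]
    subsets = np.arange(2**n, dtype=np.uint32)
    bits = ((subsets[:, None] >> np.arange(n)) & 1).astype(np.int32)
    ok = np.ones(len(subsets), dtype=bool)
    if alpha > 0 and inter_masks.shape[0]:
        cover = bits @ inter_masks.T.astype(np.int32)
        ok &= (cover >= alpha).all(axis=1)
    if beta > 0 and intra_masks.shape[0]:
        cover = bits @ intra_masks.T.astype(np.int32)
        ok &= (cover >= beta).all(axis=1)
    if not ok.any():
        return None, None
    sizes = bits.sum(axis=1)
    sizes[~ok] = n + 1
    best = int(sizes.argmin())
    if not ok[best]:
        return None, None
    return int(sizes[best]), bits[best].astype(bool)


def mdlp_oracle(values, klass):
    """Reference recursive MDLP trying every midpoint cut, no shortcuts."""

    def ent(y):
        n = len(y)
        if n == 0:
            return 0.0
        e = 0.0
        for c in set(y.tolist()):
            p = (y == c).mean()
            e -= p * math.log2(p)
        return e

    values = np.asarray(values, dtype=float)
    klass = np.asarray(klass, dtype=int)
    out: list[float] = []

    def rec(idx):
        v = values[idx]
        y = klass[idx]
        n = len(v)
        if n < 2 or len(set(y.tolist())) < 2:
            return
        order = np.argsort(v, kind="stable")
        v, y = v[order], y[order]
        best = None
        for pos in range(1, n):
            if v[pos - 1] == v[pos]:
                continue
            left, right = y[:pos], y[pos:]
            gain = ent(y) - (pos / n) * ent(left) - ((n - pos) / n) * ent(right)
            if best is None or gain > best[1] + 1e-12:
                best = ((v[pos - 1] + v[pos]) / 2.0, gain, left, right)
        if best is None:
            return
        t, gain, left, right = best
        k = len(set(y.tolist()))
        k1, k2 = len(set(left.tolist())), len(set(right.tolist()))
        delta = math.log2(3**k - 2) - (k * ent(y) - k1 * ent(left) - k2 * ent(right))
        if gain > (math.log2(n - 1) + delta) / n:
            out.append(t)
            rec(idx[values[idx] <= t])
            rec(idx[values[idx] > t])

    rec(np.arange(len(values)))
    return sorted(out)
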