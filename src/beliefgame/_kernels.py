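"""Compiled inner loop of the social-learning phase.

One round's social phase touches up to N egos, each folding a handful of
16-component mass vectors; the arithmetic is trivial but the call overhead in
pure numpy dominates the simulation, so the whole phase is jitted.  The
kernel mirrors the library operations exactly: cosine similarity, recursive
reliability over the weight-sorted prefix, the fair-reliability mapping, the
combined coefficient, and the WER fold with the ego entering first at c = 1
(which pins the unassigned slot at zero throughout).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def social_round(
    snapshot: np.ndarray,  # (N, S) round-start masses
    egos: np.ndarray,  # (L,) learner ids
    offsets: np.ndarray,  # (L+1,) CSR offsets into flat_src
    flat_src: np.ndarray,  # concatenated source ids per ego
    deg: np.ndarray,  # (N,) degrees
    denom: np.ndarray,  # (N,) sum of neighbour degrees per ego
    r_fair: float,
    r_eta: float,
    r_max: float,
) -> np.ndarray:
    n_nodes, S = snapshot.shape
    norms = np.empty(n_nodes)
    for i in range(n_nodes):
        s = 0.0
        for a in range(S):
            s += snapshot[i, a] * snapshot[i, a]
        norms[i] = np.sqrt(s)

    out = np.empty((egos.shape[0], S))
    tilde = np.empty(S)
    for idx in range(egos.shape[0]):
        ego = egos[idx]
        lo, hi = offsets[idx], offsets[idx + 1]
        k_tot = hi - lo
        src = flat_src[lo:hi].copy()
        # descending weight (degree share), ties to the lowest node id
        for a in range(1, k_tot):
            key = src[a]
            b = a - 1
            while b >= 0 and (
                deg[src[b]] < deg[key]
                or (deg[src[b]] == deg[key] and src[b] > key)
            ):
                src[b + 1] = src[b]
                b -= 1
            src[b + 1] = key

        acc = snapshot[ego].copy()
        pair_sum = 0.0
        for kk in range(k_tot):
            j = src[kk]
            d = 0.0
            for a in range(S):
                d += snapshot[ego, a] * snapshot[j, a]
            s_ego = d / (norms[ego] * norms[j])
            if kk == 0:
                r_raw = s_ego
            else:
                for a in range(kk):
                    ja = src[a]
                    d2 = 0.0
                    for t in range(S):
                        d2 += snapshot[ja, t] * snapshot[j, t]
                    pair_sum += d2 / (norms[ja] * norms[j])
                kf = kk + 1
                r_raw = s_ego / 2.0 + pair_sum / (kf * (kf - 1))
            if r_raw > 1.0:
                r_raw = 1.0
            if r_raw < r_eta:
                r = r_raw
            else:
                r = r_fair + (r_max - r_fair) * (r_raw - r_eta) / (1.0 - r_eta)
            w = deg[j] / denom[ego]
            c = w / (1.0 + w - r)

            # WER step; the unassigned slot is identically 0 with ego first
            for t in range(S):
                tilde[t] = (1.0 - c) * acc[t]
            for B in range(1, S):
                aB = acc[B]
                if aB > 0.0:
                    for C in range(1, S):
                        mC = snapshot[j, C]
                        if mC > 0.0:
                            tilde[B & C] += aB * c * mC
            tilde[0] = 0.0
            z = 0.0
            for t in range(S):
                z += tilde[t]
            for t in range(S):
                acc[t] = tilde[t] / z
        out[idx] = acc
    return out
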