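"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by the most direct route available —
explicit enumeration, brute-force loops, or closed forms — sharing no code
path with the implementation under test.
"""

import itertools
import math

import numpy as np


def coloc_enumeration(beta1, se1, beta2, se2, p1, p2, p12, w1, w2):
    """Colocalization posteriors by explicit linear-space enumeration.

    Walks every single-causal-variant configuration: the null, trait-1
    causal at i, trait-2 causal at j, distinct pairs (i, j != i), and shared
    (i, i); weighs each by its prior and the Wakefield Bayes factors.
    """

    def abf(b, s, w):
        r = w / (s**2 + w)
        z = b / s
        return math.sqrt(1 - r) * math.exp(0.5 * r * z * z)

    m = len(beta1)
    a1 = [abf(beta1[i], se1[i], w1) for i in range(m)]
    a2 = [abf(beta2[i], se2[i], w2) for i in range(m)]

    like = [1.0, 0.0, 0.0, 0.0, 0.0]  # H0..H4 unnormalized
    for i in range(m):
        like[1] += p1 * a1[i]
        like[2] += p2 * a2[i]
        like[4] += p12 * a1[i] * a2[i]
    for i, j in itertools.product(range(m), repeat=2):
        if i != j:
            like[3] += p1 * p2 * a1[i] * a2[j]
    total = sum(like)
    return np.array(like) / total


def brute_force_pwm_hits(seq, log_odds, min_score, max_score, threshold):
    """Per-offset, per-strand PWM rescoring with explicit loops."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(log_odds)
    hits = []
    n = len(seq)
    for off in range(n - L + 1):
        window = seq[off: off + L].upper()
        if any(b not in base_idx for b in window):
            continue
        s = sum(log_odds[k][base_idx[window[k]]] for k in range(L))
        scaled = (s - min_score) / (max_score - min_score)
        if scaled >= threshold:
            hits.append((off, "+", scaled))
        rc = "".join(comp[b] for b in reversed(window))
        s = sum(log_odds[k][base_idx[rc[k]]] for k in range(L))
        scaled = (s - min_score) / (max_score - min_score)
        if scaled >= threshold:
            hits.append((off, "-", scaled))
    return sorted(hits, key=lambda h: (h[0], h[1]))


def greedy_clump_reference(entries, r2, threshold):
    """Literal restatement of greedy clumping on explicit (id, rank) pairs.

    ``entries`` is a list of (variant_id, sort_key); ``r2`` a dict of
    frozenset pairs to r-squared values.
    """
    remaining = sorted(entries, key=lambda e: e[1])
    assigned = {}
    order = []
    while remaining:
        lead = remaining[0][0]
        order.append(lead)
        members = [lead]
        rest = []
        for vid, key in remaining[1:]:
            if r2.get(frozenset({lead, vid}), 1.0 if vid == lead else 0.0) >= threshold:
                members.append(vid)
            else:
                rest.append((vid, key))
        assigned[lead] = members
        remaining = rest
    return assigned, order


def bh_stepup(pvals):
    """Hand execution of the Benjamini-Hochberg step-up adjustment."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(pvals[i] * m / rank_from_end, prev)
        adj[i] = val
        prev = val
    return adj


def wls_through_origin(x, y, w):
    """Closed-form weighted least squares through the origin."""
    sw = sum(wi * xi * xi for wi, xi in zip(w, x))
    slope = sum(wi * xi * yi for wi, xi, yi in zip(w, x, y)) / sw
    return slope, math.sqrt(1.0 / sw)
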