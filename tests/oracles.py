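"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by explicit enumeration, separate from
the library's implementations, so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def brute_force_producer(kb, ko_set, vitamin) -> bool:
    """Enumerate every variant and role-KO intersection explicitly.

    A variant is satisfied when each indispensable role intersects the
    genome; a vitamin with a post-cobyrinate segment additionally requires
    that segment alongside an early segment.
    """
    satisfied: dict[str, bool] = {}
    for variant in kb.variants_for(vitamin):
        ok = True
        for rid in variant.indispensable_role_ids:
            hit = False
            for ko in kb.role(rid).ko_ids:
                if ko in ko_set:
                    hit = True
            if not hit:
                ok = False
        satisfied[variant.variant_id] = ok
    posts = [v for v in kb.variants_for(vitamin) if v.segment_tag == "post_cobyrinate"]
    earlies = [v for v in kb.variants_for(vitamin) if v.segment_tag != "post_cobyrinate"]
    if posts:
        return any(satisfied[e.variant_id] for e in earlies) and any(
            satisfied[p.variant_id] for p in posts
        )
    return any(satisfied[v.variant_id] for v in earlies)


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all rank assignments.

    Assumes no ties.  p = 2 * min(P(W <= w), P(W >= w)) capped at 1, where W
    is the rank sum of the first sample under the uniform null over all
    C(n+m, n) assignments.
    """
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == n + m, "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    total = comb(n + m, n)
    le = ge = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        w = sum(combo)
        if w <= w_obs:
            le += 1
        if w >= w_obs:
            ge += 1
    return min(1.0, 2 * min(le, ge) / total)


def procrustes_residual(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized residual after optimal translation/rotation/scaling."""
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(a, b)
    return float(disparity)
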