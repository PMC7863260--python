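"""Independent brute-force reference implementations used only by the tests.

These deliberately trade efficiency for obviousness so they can serve as
oracles for the optimized library code.
"""

import numpy as np


def cfdr_bruteforce(p_primary, p_cond):
    """O(n^2) double-loop conditional FDR with <= tie semantics, capped at 1."""
    p_primary = np.asarray(p_primary, dtype=float)
    p_cond = np.asarray(p_cond, dtype=float)
    n = len(p_primary)
    out = np.empty(n)
    for i in range(n):
        n_cond = int(np.sum(p_cond <= p_cond[i]))
        n_both = int(np.sum((p_primary <= p_primary[i]) & (p_cond <= p_cond[i])))
        out[i] = min(p_primary[i] * n_cond / n_both, 1.0)
    return out


def clump_bruteforce(ids, chrom, pos, rank_p, r2_lookup, r2_threshold, window_bp):
    """Exhaustive greedy clumping over explicit candidate scans.

    ``r2_lookup(a, b)`` returns r2 (0 when unknown).  Returns the set of
    retained variant IDs.
    """
    n = len(ids)
    order = sorted(range(n), key=lambda i: (rank_p[i], pos[i], ids[i]))
    removed, retained = set(), []
    for i in order:
        if i in removed:
            continue
        retained.append(i)
        for j in range(n):
            if j == i or j in removed or j in retained:
                continue
            if (chrom[j] == chrom[i] and abs(pos[j] - pos[i]) <= window_bp
                    and r2_lookup(ids[i], ids[j]) > r2_threshold):
                removed.add(j)
    return {ids[i] for i in retained}


def closest_gene_bruteforce(pos, starts, ends, names):
    """All-genes distance scan; returns (sorted tied names, min distance)."""
    best = None
    for s, e, nm in zip(starts, ends, names):
        d = 0 if s <= pos <= e else (s - pos if pos < s else pos - e)
        if best is None or d < best[0]:
            best = (d, {nm})
        elif d == best[0]:
            best[1].add(nm)
    return sorted(best[1]), best[0]
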