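"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive enumeration, cubic DP,
powerset classification) and shares no code with the package internals.
"""

from itertools import combinations

import numpy as np


# --- tryptic digestion ------------------------------------------------------

def oracle_digest(protein, max_missed_cleavages, min_len=None, max_len=None):
    """All substrings whose boundaries are cleavage boundaries, as a set of
    (sequence, start, missed_cleavages)."""
    n = len(protein)
    sites = {0, n}
    internal = set()
    for i in range(n - 1):
        if protein[i] in "KR" and protein[i + 1] != "P":
            sites.add(i + 1)
            internal.add(i + 1)
    out = set()
    for start in range(n):
        for end in range(start + 1, n + 1):
            if start not in sites or end not in sites:
                continue
            mc = sum(1 for s in internal if start < s < end)
            if mc > max_missed_cleavages:
                continue
            L = end - start
            if min_len is not None and L < min_len:
                continue
            if max_len is not None and L > max_len:
                continue
            out.add((protein[start:end], start, mc))
    return out


# --- Smith-Waterman via cubic gap-length enumeration ------------------------

def oracle_local_score(a, b, score_fn, gap_open=11, gap_extend=1):
    """Optimal local alignment score by Waterman-Smith-Beyer DP: every gap
    length is tried explicitly, so no affine-gap recurrence is shared with
    the implementation under test."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            val = max(0.0, H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]))
            for k in range(1, i + 1):
                val = max(val, H[i - k][j] - (gap_open + k * gap_extend))
            for k in range(1, j + 1):
                val = max(val, H[i][j - k] - (gap_open + k * gap_extend))
            H[i][j] = val
            best = max(best, val)
    return best


# --- core-set classification by explicit pattern logic ----------------------

def oracle_classify(present, focal, group_all, group_marine):
    """Class of one presence pattern (set of species where present)."""
    present = set(present)
    if set(group_all).issubset(present):
        return "shared_all"
    if set(group_marine).issubset(present):
        return "marine_only"
    if present == {focal}:
        return "focal_specific"
    if focal in present and len(present) == 2:
        partner = (present - {focal}).pop()
        return f"pair_shared:{partner}"
    return "other"


# --- Dollo parsimony by exhaustive single-gain enumeration -------------------

def oracle_dollo(parent_of, root, leaves, leaf_states):
    """Minimal-loss internal states subject to at most one gain.

    ``parent_of`` maps every non-root node name to its parent name. A gain is
    an edge whose parent is absent and child present; the root being present
    counts as the gain on the root edge. Returns the set of optimal full
    state assignments (as frozensets of present nodes).
    """
    internal = [n for n in set(parent_of) | {root} if n not in leaves]
    best_cost, best = None, []
    for bits in range(2 ** len(internal)):
        states = dict(leaf_states)
        for k, node in enumerate(internal):
            states[node] = bool(bits >> k & 1)
        gains = int(states[root])
        losses = 0
        for child, parent in parent_of.items():
            if states[parent] and not states[child]:
                losses += 1
            if not states[parent] and states[child]:
                gains += 1
        if gains > 1:
            continue
        if best_cost is None or losses < best_cost:
            best_cost, best = losses, [states]
        elif losses == best_cost:
            best.append(states)
    return best


# --- monophyly via graph edge cuts ------------------------------------------

def oracle_is_monophyletic(edges, leaves, subset):
    """Bipartition test on the unrooted tree graph: drop each edge in turn
    and compare the leaf sets of the two components."""
    subset = frozenset(subset)
    leaves = frozenset(leaves)
    if len(subset) in (1, len(leaves)):
        return True
    nodes = {u for e in edges for u in e}
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    for cut in edges:
        seen = {cut[0]}
        stack = [cut[0]]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen and {u, v} != set(cut):
                    seen.add(v)
                    stack.append(v)
        side = frozenset(seen) & leaves
        if side == subset or leaves - side == subset:
            return True
    return False


# --- N50 by cut-point enumeration -------------------------------------------

def oracle_n50(lengths):
    total = sum(lengths)
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            return L
    return min(lengths)
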