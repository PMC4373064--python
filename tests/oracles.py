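"""Independent brute-force oracles shared across the test suite.

These deliberately avoid the implementation's shortcuts: no seeding, no
union-find, no scipy distributions — enumeration and closure only (the
pairwise alignment primitive is the one shared ingredient, as the quantity
under test is the linkage logic, not the aligner).
"""

from math import comb

from wildtx._align import best_local_alignment


def brute_n50(lengths):
    """Enumerate prefixes of the descending-sorted length multiset."""
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    cum = 0
    for ln in lengths:
        cum += ln
        if 2 * cum >= total:
            return ln
    raise AssertionError("unreachable for non-empty input")


def brute_single_linkage(contigs, min_identity=0.97, min_overlap=100):
    """All-pairs alignment + transitive closure over qualifying edges."""
    n = len(contigs)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            hit = best_local_alignment(contigs[i].seq, contigs[j].seq)
            if hit and hit.columns >= min_overlap and hit.identity >= min_identity:
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(contigs[x].id for x in comp))
    return set(comps)


def exact_upper_tail(N, K, n, k):
    """Hypergeometric P(X >= k) by exact integer enumeration."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / comb(N, n)
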