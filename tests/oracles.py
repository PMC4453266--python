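"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own vectorized code paths: counting
is dict-based over explicitly enumerated token pairs, PPMI and cosine are
computed with ``math``, and permutation p-values are obtained by exhaustive
enumeration of label assignments.
"""

import itertools
import math


def brute_cooccurrence(token_docs, window):
    """Pair counts {(w1, w2): n} by explicit enumeration, both orders."""
    counts = {}
    for doc in token_docs:
        for i, w in enumerate(doc):
            for d in range(1, window + 1):
                j = i + d
                if j >= len(doc):
                    break
                if doc[j] == w:
                    continue  # no self co-occurrence
                counts[(w, doc[j])] = counts.get((w, doc[j]), 0) + 1
                counts[(doc[j], w)] = counts.get((doc[j], w), 0) + 1
    return counts


def brute_ppmi(counts, vocabulary):
    """PPMI from pair counts via the scalar closed form."""
    total = sum(counts.values())
    row = {w: sum(counts.get((w, v), 0) for v in vocabulary) for w in vocabulary}
    weighted = {}
    for (a, b), c in counts.items():
        if c == 0 or row[a] == 0 or row[b] == 0:
            continue
        value = math.log2(c * total / (row[a] * row[b]))
        weighted[(a, b)] = max(0.0, value)
    return weighted


def brute_cosine(weighted, vocabulary, word_a, word_b):
    dot = sum(
        weighted.get((word_a, v), 0.0) * weighted.get((word_b, v), 0.0)
        for v in vocabulary
    )
    na = math.sqrt(sum(weighted.get((word_a, v), 0.0) ** 2 for v in vocabulary))
    nb = math.sqrt(sum(weighted.get((word_b, v), 0.0) ** 2 for v in vocabulary))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return dot / (na * nb)


def brute_u(x, y):
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def exhaustive_mwu_p(x, y, alternative="greater"):
    """Exact permutation p-value by enumerating every n1-subset."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = brute_u(x, y)
    n_ge = n_le = total = 0
    for subset in itertools.combinations(range(len(pooled)), n1):
        chosen = [pooled[i] for i in subset]
        rest = [pooled[i] for i in range(len(pooled)) if i not in subset]
        u = brute_u(chosen, rest)
        total += 1
        if u >= u_obs:
            n_ge += 1
        if u <= u_obs:
            n_le += 1
    if alternative == "greater":
        return n_ge / total
    if alternative == "less":
        return n_le / total
    return min(1.0, 2.0 * min(n_ge / total, n_le / total))
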