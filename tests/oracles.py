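"""Independent brute-force oracles used by the test suite.

Plain-Python, loop-based reference implementations, deliberately kept free
of the package's own vectorized code paths.
"""

import math


def tanimoto_oracle(a, b):
    inter = sum(1 for x, y in zip(a, b) if x and y)
    union = sum(1 for x, y in zip(a, b) if x or y)
    return 1.0 if union == 0 else inter / union


def nn_profile_oracle(query, reference, thresholds):
    props = []
    nn = [max((tanimoto_oracle(q, r) for r in reference), default=0.0) for q in query]
    for t in thresholds:
        props.append(sum(1 for v in nn if v >= t) / len(nn))
    return props


def roc_auc_oracle(scores, labels):
    """Exhaustive pair counting, ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def bedroc_oracle(scores, labels, alpha=20.0):
    """Direct-summation BEDROC with explicit min-max rank placements."""
    N = len(scores)
    n = sum(labels)
    order = sorted(range(N), key=lambda i: (-scores[i], i))
    ranks = {idx: r + 1 for r, idx in enumerate(order)}
    s = sum(math.exp(-alpha * ranks[i] / N) for i in range(N) if labels[i] == 1)
    denom = (n / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
    rie = s / denom
    rie_max = sum(math.exp(-alpha * r / N) for r in range(1, n + 1)) / denom
    rie_min = sum(math.exp(-alpha * r / N) for r in range(N - n + 1, N + 1)) / denom
    return max(0.0, min(1.0, (rie - rie_min) / (rie_max - rie_min)))


def bedroc_random_expectation(N, n, alpha=20.0):
    """Expected BEDROC for uniformly random active ranks (closed form on
    the mean exponential rank weight)."""
    mean_w = sum(math.exp(-alpha * r / N) for r in range(1, N + 1)) / N
    denom = (n / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)
    rie = n * mean_w / denom
    rie_max = sum(math.exp(-alpha * r / N) for r in range(1, n + 1)) / denom
    rie_min = sum(math.exp(-alpha * r / N) for r in range(N - n + 1, N + 1)) / denom
    return (rie - rie_min) / (rie_max - rie_min)


def butina_oracle(fps, floor):
    """Sphere-exclusion clustering: neighbor lists computed once, centroids
    taken in descending neighbor-count order (ties: input order)."""
    n = len(fps)
    sims = [[tanimoto_oracle(fps[i], fps[j]) for j in range(n)] for i in range(n)]
    neighbors = [{j for j in range(n) if sims[i][j] >= floor} for i in range(n)]
    order = sorted(range(n), key=lambda i: (-len(neighbors[i]), i))
    assigned = {}
    next_id = 0
    for c in order:
        if c in assigned:
            continue
        members = {j for j in neighbors[c] if j not in assigned} | {c}
        for j in members:
            assigned[j] = next_id
        next_id += 1
    return [assigned[i] for i in range(n)]
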