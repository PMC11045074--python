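"""Independent brute-force oracles used by the test suite.

Everything here is computed by explicit enumeration of generative
mechanisms — no shared code with the package's cached-table machinery, so
agreement is a genuine cross-check.
"""

from collections import defaultdict


def allele_error_matrix(p, eps, mode="freq_draw"):
    """A[obs][true] = P(observed allele | true allele), explicit loops."""
    k = len(p)
    A = [[0.0] * k for _ in range(k)]
    for t in range(k):
        for o in range(k):
            if mode == "freq_draw":
                A[o][t] = (1.0 - eps) * (o == t) + eps * p[o]
            else:
                A[o][t] = (1.0 - eps) if o == t else (eps / (k - 1) if k > 1 else 0.0)
    return A


def obs_given_true_ordered(p, eps, mode="freq_draw"):
    """P(unordered observed genotype | ordered true genotype).

    Enumerates both observed alleles independently through the error
    channel and accumulates onto sorted pairs.
    """
    k = len(p)
    A = allele_error_matrix(p, eps, mode)
    table = {}
    for t1 in range(k):
        for t2 in range(k):
            dist = defaultdict(float)
            for o1 in range(k):
                for o2 in range(k):
                    dist[tuple(sorted((o1, o2)))] += A[o1][t1] * A[o2][t2]
            table[(t1, t2)] = dict(dist)
    return table


def true_joint_ordered(p, kappa):
    """Joint over ordered true genotype pairs, by generative enumeration.

    kappa0: four independent population draws.  kappa1: individual 1 drawn,
    one of its alleles transmitted (probability 1/2 each), partner allele a
    population draw.  kappa2: identical ordered genotypes.
    """
    k = len(p)
    k0, k1, k2 = kappa
    joint = defaultdict(float)
    for x1 in range(k):
        for x2 in range(k):
            px = p[x1] * p[x2]
            if k0:
                for y1 in range(k):
                    for y2 in range(k):
                        joint[(x1, x2, y1, y2)] += k0 * px * p[y1] * p[y2]
            if k1:
                for transmitted in (x1, x2):
                    for z in range(k):
                        joint[(x1, x2, transmitted, z)] += k1 * px * 0.5 * p[z]
            if k2:
                joint[(x1, x2, x1, x2)] += k2 * px
    return joint


def oracle_observed_pair_prob(p, kappa, eps, mode="freq_draw"):
    """P(unordered observed pair | kinship) for every genotype pair.

    Returns ``{(g1, g2): prob}`` with g = sorted allele-index pairs.
    """
    joint = true_joint_ordered(p, kappa)
    channel = obs_given_true_ordered(p, eps, mode)
    out = defaultdict(float)
    for (x1, x2, y1, y2), w in joint.items():
        if w == 0.0:
            continue
        for g1, w1 in channel[(x1, x2)].items():
            for g2, w2 in channel[(y1, y2)].items():
                out[(g1, g2)] += w * w1 * w2
    return dict(out)


def hand_chi_square(observed, expected):
    """Plain chi-square statistic from paired (observed, expected) counts."""
    return sum((o - e) ** 2 / e for o, e in zip(observed, expected))


def wilcoxon_exact_two_sided(x, y):
    """Two-sided rank-sum p-value by exhaustive enumeration of assignments."""
    from itertools import combinations

    pooled = sorted(x) + sorted(y)
    n, m = len(x), len(y)
    values = sorted(pooled)

    def rank_sum(subset):
        # midranks for ties
        ranks = {}
        i = 0
        while i < len(values):
            j = i
            while j < len(values) and values[j] == values[i]:
                j += 1
            mid = (i + 1 + j) / 2.0
            ranks.setdefault(values[i], []).extend([mid] * (j - i))
            i = j
        pool = {v: list(r) for v, r in ranks.items()}
        total = 0.0
        for v in subset:
            total += pool[v].pop()
        return total

    observed = rank_sum(sorted(x))
    count = 0
    total = 0
    for combo in combinations(range(n + m), n):
        subset = [pooled[i] for i in combo]
        total += 1
        stat = rank_sum(subset)
        if abs(stat - (n * (n + m + 1) / 2.0)) >= abs(observed - (n * (n + m + 1) / 2.0)) - 1e-12:
            count += 1
    return count / total
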