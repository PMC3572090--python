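"""Independent brute-force oracles for the statistics under test.

These are deliberately naive, loop-based transcriptions of the published
formulas, kept free of any code path from the package so they can serve as
independent references.
"""

import math
from itertools import combinations


def hd_nei(counts):
    """Nei's haplotype diversity and its sampling SD, direct transcription."""
    n = sum(counts)
    p = [c / n for c in counts]
    sum_p2 = sum(x * x for x in p)
    sum_p3 = sum(x**3 for x in p)
    hd = n / (n - 1) * (1 - sum_p2)
    var = (
        2.0 / (n * (n - 1))
        * (2.0 * (n - 2) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2)
    )
    return hd, math.sqrt(max(var, 0.0))


def hamming_pairwise_deletion(a, b):
    """Differences between two sequences, skipping '-'/'N' in either."""
    d = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        if x != y:
            d += 1
    return d


def mean_pairwise_differences(seqs):
    total, n_pairs = 0, 0
    for a, b in combinations(seqs, 2):
        total += hamming_pairwise_deletion(a, b)
        n_pairs += 1
    return total / n_pairs


def raggedness_harpending(seqs):
    """r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2 by direct summation."""
    diffs = [hamming_pairwise_deletion(a, b) for a, b in combinations(seqs, 2)]
    d_max = max(diffs)
    n_pairs = len(diffs)
    x = [diffs.count(i) / n_pairs for i in range(d_max + 1)] + [0.0]
    return sum((x[i] - x[i - 1]) ** 2 for i in range(1, len(x)))


def segregating_sites(seqs):
    s = 0
    for col in zip(*seqs):
        called = {c for c in col if c not in "-N"}
        if len(called) >= 2:
            s += 1
    return s


def tajima_d(seqs):
    """Tajima's D, textbook constants, direct transcription."""
    n = len(seqs)
    s = segregating_sites(seqs)
    if s == 0:
        return None
    pi = mean_pairwise_differences(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def theta_watterson(seqs):
    n = len(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    return segregating_sites(seqs) / a1


def theta_homozygosity(seqs):
    counts = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    n = len(seqs)
    f_hat = sum((c / n) ** 2 for c in counts.values())
    return 1.0 / f_hat - 1.0


def amova_phist(d2, labels):
    """One-level AMOVA Phi-st from squared distances, direct sums of squares."""
    n = len(labels)
    groups = sorted(set(labels))
    ssd_total = sum(d2[i][j] for i in range(n) for j in range(n)) / (2.0 * n)
    ssd_within = 0.0
    sizes = []
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        sizes.append(len(idx))
        ssd_within += sum(d2[i][j] for i in idx for j in idx) / (2.0 * len(idx))
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n - len(groups))
    n_c = (n - sum(s * s for s in sizes) / n) / (len(groups) - 1)
    sigma_a = (ssd_among / (len(groups) - 1) - sigma_w) / n_c
    return sigma_a / (sigma_a + sigma_w)


def _partitions(n, max_part=None):
    """Yield integer partitions of n as non-increasing tuples."""
    if max_part is None:
        max_part = n
    if n == 0:
        yield ()
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def ewens_k_distribution(n, theta):
    """P(K = k) by exhaustive enumeration of partitions of n.

    Ewens sampling formula for a partition with multiplicities a_j:
    P = n! / theta_(n) * prod_j theta^{a_j} / (j^{a_j} a_j!).
    """
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    pk = [0.0] * (n + 1)
    for part in _partitions(n):
        a = {}
        for j in part:
            a[j] = a.get(j, 0) + 1
        prob = math.factorial(n) / rising
        for j, aj in a.items():
            prob *= theta**aj / (j**aj * math.factorial(aj))
        pk[len(part)] += prob
    return pk


def fu_fs(n, k_obs, theta):
    """Fs via the enumerated Ewens K distribution (n small)."""
    pk = ewens_k_distribution(n, theta)
    s_prime = sum(pk[k_obs:])
    return math.log(s_prime / (1.0 - s_prime))
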