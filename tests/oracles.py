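"""Independent brute-force oracles, re-derived from first principles.

These deliberately avoid every helper in the package under test: distances
are counted pair by pair, Tajima constants re-derived from the published
formulas, and Ewens probabilities computed with exact integer Stirling
numbers.
"""

import math


def pairwise_diffs(seqs):
    names = list(seqs)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = sum(x != y for x, y in zip(seqs[a], seqs[b]))
    return out


def pi(seqs):
    d = pairwise_diffs(seqs)
    return sum(d.values()) / len(d)


def segregating_sites(seqs):
    return sum(1 for col in zip(*seqs.values()) if len(set(col)) > 1)


def watterson(seqs):
    n = len(seqs)
    return segregating_sites(seqs) / sum(1 / i for i in range(1, n))


def haplotype_diversity(seqs):
    n = len(seqs)
    counts = {}
    for s in seqs.values():
        counts[s] = counts.get(s, 0) + 1
    return n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts.values()))


def tajimas_d(seqs):
    n = len(seqs)
    S = segregating_sites(seqs)
    if S == 0:
        return None
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi(seqs) - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def stirling_unsigned(n):
    """Exact integer |s(n, k)|, k = 0..n."""
    row = [1]
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (m - 1) * (row[k] if k < m else 0) + row[k - 1]
        row = new
    return row


def fus_fs(seqs):
    """Fu's Fs via exact Ewens sampling probabilities (small n only)."""
    n = len(seqs)
    theta = pi(seqs)
    if theta == 0:
        return None
    k_obs = len(set(seqs.values()))
    s = stirling_unsigned(n)
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    probs = [s[k] * theta ** k / rising for k in range(1, n + 1)]
    sp = sum(probs[k_obs - 1:])
    if sp >= 1:
        return None
    return math.log(sp / (1 - sp))
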