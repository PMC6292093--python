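"""Independent brute-force oracles used only by tests.

These deliberately avoid the package's vectorized code paths: pure-Python
enumeration and math so they can certify the fast implementations.
"""

from itertools import product
from math import comb, log


def set_partitions(items):
    """Every set partition of ``items`` as a list of blocks (lists)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def partition_to_labels(blocks, items):
    """Canonical first-appearance labels for a block partition."""
    label_of = {}
    for i, block in enumerate(blocks):
        for item in block:
            label_of[item] = block
    labels, mapping = [], {}
    for item in items:
        key = id(label_of[item])
        if key not in mapping:
            mapping[key] = len(mapping) + 1
        labels.append(mapping[key])
    return tuple(labels)


def canonical_partition_labels(k):
    """All canonical label tuples for partitions of range(k), as a set."""
    items = list(range(k))
    return {partition_to_labels(p, items) for p in set_partitions(items)}


def hwe_probs(f):
    return ((1 - f) ** 2, 2 * f * (1 - f), f * f)


def binom_pmf(n_b, n, p):
    return comb(n, n_b) * (1 - p) ** (n - n_b) * p ** n_b


def genotype_vector_prior(G, S_labels, f):
    """P(G | S) by explicit block consistency check; linear space."""
    blocks = {}
    for d, lab in enumerate(S_labels):
        blocks.setdefault(lab, []).append(d)
    prior = 1.0
    for members in blocks.values():
        genotypes = {G[d] for d in members}
        if len(genotypes) > 1:
            return 0.0
        prior *= hwe_probs(f)[genotypes.pop()]
    return prior


def brute_force_site_loglik(depths, f, S_labels, e):
    """Explicit sum over all 3**k genotype vectors; pure Python."""
    k = len(depths)
    total = 0.0
    for G in product(range(3), repeat=k):
        prior = genotype_vector_prior(G, S_labels, f)
        if prior == 0.0:
            continue
        lik = 1.0
        for d, (n_a, n_b) in enumerate(depths):
            p_b = (e, 0.5, 1 - e)[G[d]]
            lik *= binom_pmf(n_b, n_a + n_b, p_b)
        total += prior * lik
    return log(total)
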