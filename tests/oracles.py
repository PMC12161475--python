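"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the implementation: exact-test p-values come from
explicit fixed-margin enumeration with integer binomial coefficients, and
the gene-set enrichment score from a literal walk along the ranked list.
"""

import itertools
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def table_prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return 0.0
        return comb(row1, x) * comb(row2, col1 - x) / comb(n, col1)

    p_obs = table_prob(a)
    total = sum(p for x in range(min(row1, col1) + 1)
                if (p := table_prob(x)) <= p_obs * (1 + 1e-9))
    return min(total, 1.0)


def ora_oracle_enumeration(hits, universe, members) -> float:
    """P(overlap >= observed) by enumerating every equal-size hit subset."""
    universe = sorted(universe)
    k = len(hits)
    annotated = set(members) & set(universe)
    observed = len(set(hits) & annotated)
    n_total = n_extreme = 0
    for draw in itertools.combinations(universe, k):
        n_total += 1
        if len(set(draw) & annotated) >= observed:
            n_extreme += 1
    return n_extreme / n_total


def ssgsea_es_oracle(values: dict, members: set, alpha: float) -> float:
    """Sum-form enrichment score via an explicit ranked-list walk."""
    ordered = sorted(values, key=lambda g: (-values[g], g))
    in_weights = {g: abs(values[g]) ** alpha for g in ordered if g in members}
    total_in = sum(in_weights.values())
    n_out = sum(1 for g in ordered if g not in members)
    es = cum_in = 0.0
    cum_out = 0
    for g in ordered:
        if g in members:
            cum_in += in_weights[g]
        else:
            cum_out += 1
        es += cum_in / total_in - cum_out / n_out
    return es
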