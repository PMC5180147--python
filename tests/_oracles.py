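"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — plain-Python enumeration over all
draw orders — and shares no code with the implementation under test.
"""

from __future__ import annotations

from itertools import permutations

_EPS = 1e-9


def exact_expected_sqs_richness(
    counts: dict[str, int],
    q: float,
    coverage_rule: str = "good",
    exclude_dominant: bool = False,
) -> float | None:
    """Exact expected subsampled richness for occurrence-unit SQS.

    Enumerates every permutation of the cell's occurrence list (multiset
    permutations arise with their natural multiplicity) and replays the
    stopping rule.  Returns None when the quorum is unattainable (u < q).
    Feasible for cells with O <= 8 (8! = 40320 orders).
    """
    items = [g for g, c in counts.items() for _ in range(c)]
    O = len(items)
    n1 = sum(1 for c in counts.values() if c == 1)
    u = 1.0 - n1 / O
    if u < q - _EPS:
        return None

    shares = {g: c / O for g, c in counts.items()}
    dominant = max(sorted(counts), key=lambda g: counts[g])
    if coverage_rule == "good":
        inc = {g: u * s for g, s in shares.items()}
        target = q
    elif coverage_rule == "deficit":
        inc, target = dict(shares), q * u
    elif coverage_rule == "raw":
        inc, target = dict(shares), q
    else:
        raise ValueError(coverage_rule)
    if exclude_dominant:
        target *= 1.0 - shares[dominant]
        inc[dominant] = 0.0

    total = 0
    n_orders = 0
    for order in permutations(range(O)):
        seen: set[str] = set()
        cov = 0.0
        for idx in order:
            g = items[idx]
            if g not in seen:
                seen.add(g)
                cov += inc[g]
            if cov >= target - _EPS:
                break
        total += len(seen)
        n_orders += 1
    return total / n_orders
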