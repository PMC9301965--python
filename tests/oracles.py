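"""Independent brute-force oracles used by unit and acceptance tests."""

import math


def dtw_enumerate(u, v, weights=(1.0, 1.0, 1.0)) -> float:
    """Minimum weighted alignment cost over ALL monotone warping paths.

    Exhaustive recursion over paths from (1, 1) to (len(u), len(v)) taking
    horizontal/diagonal/vertical steps; the step entering cell (i, j) incurs
    |u_i - v_j| times its direction weight (the first cell counts with the
    diagonal weight).  Weight pairing matches the implementation: w_V for a
    step from (i, j-1), w_H for a step from (i-1, j).
    """
    w_h, w_d, w_v = weights
    tu, tv = len(u), len(v)
    best = [math.inf]

    def walk(i, j, cost):
        if cost >= best[0]:
            return
        if i == tu and j == tv:
            best[0] = cost
            return
        if i < tu:
            walk(i + 1, j, cost + abs(u[i] - v[j - 1]) * w_h)
        if j < tv:
            walk(i, j + 1, cost + abs(u[i - 1] - v[j]) * w_v)
        if i < tu and j < tv:
            walk(i + 1, j + 1, cost + abs(u[i] - v[j]) * w_d)

    walk(1, 1, abs(u[0] - v[0]) * w_d)
    return best[0]


def cv_two_pass(values) -> float:
    """Coefficient of variation, percent, by an explicit two-pass loop."""
    n = len(values)
    mean = sum(values) / n
    acc = 0.0
    for x in values:
        acc += (x - mean) ** 2
    sd = math.sqrt(acc / (n - 1))
    return 100.0 * sd / mean
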