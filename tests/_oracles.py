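"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: displacement by
step-simulating the drag, path costs by exhaustive grid search over click
and re-click positions, and the within-participant ANOVA by definitional
sums-of-squares loops.
"""

import itertools
import math

import numpy as np

GRID = 0.001


def step_simulated_displacement(target, config, tol=1e-12, coarse=1e-3):
    """Drag the line in small steps until the target square is centered,
    accumulating the displacement; the final partial step closes the
    observed residual exactly (the line moves in sync with the cursor)."""
    offset = 0.0
    accumulated = 0.0
    for _ in range(10000):
        center = 0.5 + (config.center_number - target) * config.square_edge + offset
        residual = 0.5 - center
        if abs(residual) <= tol:
            return accumulated
        step = math.copysign(min(coarse, abs(residual)), residual)
        offset += step
        accumulated += step
    raise AssertionError("step simulation did not converge")


def _clickable(config, offset):
    lo = max(0.0, config.line_bottom + offset)
    hi = min(1.0, config.line_top + offset)
    return lo, hi


_completion_tables = {}


def _completion_table(d, config):
    """Exhaustive completion costs after a drag has hit the border.

    ``C[i]`` is the minimal remaining path (travel + drags) when the cursor
    sits at the border it just hit and the line still needs ``i * GRID``
    units of movement toward the target. Because every drag moves the line
    exactly with the cursor, the line offset at that moment is a function
    of the remaining displacement alone, so the table can be filled bottom
    up over the 0.001 grid of remaining displacements, minimizing over all
    grid re-click positions at each step.
    """
    key = (round(d, 9), id(config))
    if key in _completion_tables:
        return _completion_tables[key]
    sign = 1.0 if d > 0 else -1.0
    n = int(round(abs(d) / GRID))
    C = np.full(n + 1, np.inf)
    C[0] = 0.0
    for i in range(1, n + 1):
        rem = i * GRID
        offset = d - sign * rem
        lo, hi = _clickable(config, offset)
        ys = np.arange(math.ceil(lo / GRID - 1e-9),
                       math.floor(hi / GRID + 1e-9) + 1) * GRID
        cursor = 0.0 if sign < 0 else 1.0
        best = math.inf
        for y in ys:
            cap = y if sign < 0 else 1.0 - y
            travel = abs(y - cursor)
            if cap >= rem - 1e-12:
                cost = travel + rem
            elif cap > 1e-12:
                j = i - int(round(cap / GRID))
                cost = travel + cap + C[j]
            else:
                continue
            if cost < best:
                best = cost
        C[i] = best
    _completion_tables[key] = C
    return C


def oracle_scroll_cost(click_y, d, config):
    """Minimal vertical path to finish displacement d from click_y under the
    drag-to-border policy, searching re-click positions on a 0.001 grid.

    ``click_y`` and ``d`` must lie on the 0.001 grid."""
    if d == 0:
        return 0.0
    r = abs(d)
    capacity = (1.0 - click_y) if d > 0 else click_y
    if capacity >= r - 1e-12:
        return r
    C = _completion_table(d, config)
    j = int(round((r - capacity) / GRID))
    return capacity + C[j]


def oracle_minimal_path(start, d, config):
    """Grid search over click positions for the minimal total trajectory;
    ties broken toward the start height, then the screen center."""
    start_x, start_y = start
    hw = config.line_half_width
    gap = max(0.0, abs(start_x - 0.5) - hw)
    lo, hi = _clickable(config, 0.0)
    ys = np.arange(round(lo / GRID), round(hi / GRID) + 1) * GRID
    totals = np.array([math.hypot(gap, start_y - y)
                       + oracle_scroll_cost(y, d, config) for y in ys])
    best = totals.min()
    tied = ys[totals <= best + 1e-12]
    tied = sorted(tied, key=lambda y: (abs(y - start_y), abs(y - 0.5)))
    return float(tied[0]), float(best)


def oracle_two_way_rm_anova(Y):
    """Definitional two-way within-participant ANOVA on Y[n, a, b].

    Returns dict effect -> (F, ss_effect, ss_error, eta_g) computed with
    explicit loops over the classical mean decomposition.
    """
    n, a, b = Y.shape
    gm = Y.mean()
    pm = Y.mean(axis=(1, 2))          # participant means
    am = Y.mean(axis=(0, 2))          # factor A level means
    bm = Y.mean(axis=(0, 1))
    abm = Y.mean(axis=0)              # A x B cell means
    pam = Y.mean(axis=2)              # participant x A
    pbm = Y.mean(axis=1)

    ss_s = a * b * sum((pm[i] - gm) ** 2 for i in range(n))
    ss_a = n * b * sum((am[j] - gm) ** 2 for j in range(a))
    ss_b = n * a * sum((bm[k] - gm) ** 2 for k in range(b))
    ss_ab = n * sum((abm[j, k] - am[j] - bm[k] + gm) ** 2
                    for j in range(a) for k in range(b))
    ss_as = b * sum((pam[i, j] - pm[i] - am[j] + gm) ** 2
                    for i in range(n) for j in range(a))
    ss_bs = a * sum((pbm[i, k] - pm[i] - bm[k] + gm) ** 2
                    for i in range(n) for k in range(b))
    ss_abs = sum((Y[i, j, k] - pam[i, j] - pbm[i, k] - abm[j, k]
                  + pm[i] + am[j] + bm[k] - gm) ** 2
                 for i in range(n) for j in range(a) for k in range(b))

    subj = ss_s + ss_as + ss_bs + ss_abs
    out = {}
    for name, ss_e, ss_err, df_e in (
            ("A", ss_a, ss_as, a - 1),
            ("B", ss_b, ss_bs, b - 1),
            ("A:B", ss_ab, ss_abs, (a - 1) * (b - 1))):
        df_err = df_e * (n - 1)
        F = (ss_e / df_e) / (ss_err / df_err)
        out[name] = (F, ss_e, ss_err, ss_e / (ss_e + subj))
    return out


def oracle_epsilon(Y_cells, contrast):
    """GG epsilon from an arbitrary orthonormal contrast basis C (rows
    orthonormal, orthogonal to the constant): invariant to the basis."""
    W = Y_cells @ contrast.T
    S = np.cov(W, rowvar=False)
    S = np.atleast_2d(S)
    d = S.shape[0]
    return float(np.trace(S) ** 2 / (d * np.sum(S * S)))


def random_orthonormal_contrast(k, rng):
    """A random orthonormal basis of the (k-1)-dim space orthogonal to 1."""
    A = rng.normal(size=(k, k - 1))
    A -= A.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(A)
    return Q.T  # (k-1, k)


def paired_t(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    se = d.std(ddof=1) / math.sqrt(n)
    return d.mean() / se, n - 1
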