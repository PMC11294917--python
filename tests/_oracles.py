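"""Independent brute-force oracles used to validate closed-form fits.

These deliberately avoid the code paths under test: plain grid searches over
the objective surfaces, refined around the running minimum.
"""

from __future__ import annotations

import numpy as np

# IUPAC 2021 atomic masses (most abundant isotope) for the adduct oracle
ATOMIC_MASS = {"C": 12.0, "H": 1.00782503207, "O": 15.99491461956, "N": 14.0030740048}
PROTON_MASS = 1.007276466


def formula_mass(formula: dict[str, int]) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


def _refined_grid_search(objective, center0, spans, n=41, iterations=60):
    """Minimize objective(a, b) by iteratively refined 2-D grid search.

    The window shrinks gently (x0.4 per pass, i.e. the new half-span is eight
    grid pitches) so a narrow diagonal valley cannot escape the window
    between passes."""
    a0, b0 = center0
    sa, sb = spans
    for _ in range(iterations):
        avals = np.linspace(a0 - sa, a0 + sa, n)
        bvals = np.linspace(b0 - sb, b0 + sb, n)
        aa, bb = np.meshgrid(avals, bvals, indexing="ij")
        sse = objective(aa[..., None], bb[..., None])
        idx = np.unravel_index(np.argmin(sse), sse.shape)
        a0, b0 = float(avals[idx[0]]), float(bvals[idx[1]])
        sa *= 0.4
        sb *= 0.4
    return a0, b0


def wls_oracle(x, y, weights, slope_span=5.0, intercept_span=5.0):
    """Weighted least squares via refined grid search on the weighted SSE."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)

    def objective(m, b):
        return np.sum(w * (y - m * x - b) ** 2, axis=-1)

    m0 = (y[-1] - y[0]) / (x[-1] - x[0])
    return _refined_grid_search(objective, (m0, 0.0), (slope_span, intercept_span))


def deming_oracle(x, y, slope_span=5.0, intercept_span=5.0):
    """Orthogonal regression via grid search on perpendicular-distance SSE."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def objective(beta, alpha):
        return np.sum((y - alpha - beta * x) ** 2, axis=-1) / (1.0 + beta[..., 0] ** 2)

    b0 = (y[-1] - y[0]) / (x[-1] - x[0])
    return _refined_grid_search(objective, (b0, 0.0), (slope_span, intercept_span))


def dda_schedule_oracle(
    cycle_time_s, gradient_min, exclusion_after, exclusion_s, eligible=lambda t_s: True
):
    """Cycle indices at which a lone always-intense precursor is fragmented
    under top-N DDA with dynamic exclusion (independent re-simulation)."""
    selected = []
    count = 0
    excluded_until = -1.0
    n_cycles = int(np.floor(gradient_min * 60.0 / cycle_time_s))
    for k in range(n_cycles):
        t = k * cycle_time_s
        if not eligible(t) or t < excluded_until:
            continue
        selected.append(k)
        count += 1
        if count >= exclusion_after:
            excluded_until = t + exclusion_s
            count = 0
    return selected
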