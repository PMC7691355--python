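"""Independent numerical oracles used by the tests.

These deliberately avoid the closed forms under test: state probabilities
come from fine-step RK4 integration of the Kolmogorov forward equations, and
AUC standard errors can be cross-checked by brute-force Mann-Whitney
resampling.
"""

from __future__ import annotations

import numpy as np


def rk4_state_probs(
    lambda1: float, mst: float, t: float, steps_per_year: int = 400
) -> tuple[float, float, float]:
    """Integrate dP0/dt = -l1 P0, dP1/dt = l1 P0 - l2 P1 with classic RK4."""
    l1, l2 = lambda1, 1.0 / mst
    n = max(int(np.ceil(t * steps_per_year)), 1) if t > 0 else 0
    h = t / n if n else 0.0

    def deriv(y):
        p0, p1 = y
        return np.array([-l1 * p0, l1 * p0 - l2 * p1])

    y = np.array([1.0, 0.0])
    for _ in range(n):
        k1 = deriv(y)
        k2 = deriv(y + 0.5 * h * k1)
        k3 = deriv(y + 0.5 * h * k2)
        k4 = deriv(y + h * k3)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    p0, p1 = y
    return float(p0), float(p1), float(1.0 - p0 - p1)


def mann_whitney_auc(cases: np.ndarray, noncases: np.ndarray) -> float:
    """Empirical AUC as the Wilcoxon two-sample statistic."""
    greater = (cases[:, None] > noncases[None, :]).mean()
    ties = (cases[:, None] == noncases[None, :]).mean()
    return float(greater + 0.5 * ties)
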