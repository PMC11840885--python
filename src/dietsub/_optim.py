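"""Newton solver for weighted logistic estimating equations.

Solves, for theta in R^p,

    0 = (1/n) sum_i w_i s_i ( y_i - expit(o_i + s_i' theta) )

with step-halving on the score norm. Used for the TMLE fluctuation (s = 1
or s = s(Z), w = substitution weights, o = logit of the current outcome
fit) and for the MSM projection / weighted-logistic fits (o = 0). The
responses y may be fractional (e.g., fitted outcome-regression values).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["solve_weighted_logistic_score"]


def solve_weighted_logistic_score(
    S: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, int]:
    """Return (theta, final mean-score norm, iterations).

    Raises RuntimeError on non-convergence or a singular Hessian.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    n, p = S.shape
    y = np.asarray(y, dtype=float)
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    o = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    theta = np.zeros(p) if theta0 is None else np.asarray(theta0, dtype=float).copy()

    def mean_score(th):
        g = expit(o + S @ th)
        return S.T @ (w * (y - g)) / n, g

    score, g = mean_score(theta)
    norm = np.linalg.norm(score)
    for it in range(1, max_iter + 1):
        if norm < tol:
            return theta, norm, it - 1
        H = (S * (w * g * (1.0 - g))[:, None]).T @ S / n
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "singular Hessian in weighted logistic score solve; "
                "check design rank and weight support"
            ) from exc
        # step-halving: require the score norm to decrease
        lam = 1.0
        for _ in range(50):
            cand = theta + lam * step
            new_score, new_g = mean_score(cand)
            new_norm = np.linalg.norm(new_score)
            if new_norm < norm:
                break
            lam *= 0.5
        else:
            raise RuntimeError(
                f"weighted logistic score solve stalled at norm {norm:.3e}"
            )
        theta, score, g, norm = cand, new_score, new_g, new_norm
    if norm < tol:
        return theta, norm, max_iter
    raise RuntimeError(
        f"weighted logistic score solve did not converge in {max_iter} iterations "
        f"(score norm {norm:.3e})"
    )
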