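"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths (and numpy's percentile
helper where the library uses it): plain Python loops and explicit
order-statistic interpolation, so agreement with the implementation is a
genuine cross-check.
"""

from __future__ import annotations

import math


def percentile_linear(values, p: int) -> float:
    """p-th percentile with linear interpolation between order statistics."""
    s = sorted(float(v) for v in values)
    n = len(s)
    idx = (n - 1) * (p / 100.0)
    lo = math.floor(idx)
    hi = min(lo + 1, n - 1)
    frac = idx - lo
    return s[lo] + (s[hi] - s[lo]) * frac


def sweep_brute_force(ccl_values, correct):
    """Recompute every sweep point with plain loops.

    Returns a list of dicts with keys p, t_p, n_p, a_p, m_p.
    """
    N = len(ccl_values)
    out = []
    for p in range(1, 100):
        t_p = percentile_linear(ccl_values, p)
        kept = [c for v, c in zip(ccl_values, correct) if v > t_p]
        n_p = len(kept)
        a_p = (sum(1 for c in kept if c) / n_p) if n_p else 0.0
        m_p = a_p * (n_p / N) * t_p
        out.append({"p": p, "t_p": t_p, "n_p": n_p, "a_p": a_p, "m_p": m_p})
    return out


def evaluate_brute_force(ccl_values, correct):
    """(m, p_opt) by scanning the brute-force sweep, smallest-p tie-break."""
    pts = sweep_brute_force(ccl_values, correct)
    best = pts[0]
    for s in pts[1:]:
        if s["m_p"] > best["m_p"]:
            best = s
    return best["m_p"], best["p"]


def finite_difference_alphas(model, x, target_class, layer_idx, eps=1e-5):
    """Central-difference estimate of the Grad-CAM channel weights
    alpha_k = (1/Z) sum_ij d y_c / d A_kij, perturbing each feature-map
    entry and re-running the network tail."""
    model.forward(x)
    A = model.activations[layer_idx + 1].copy()
    K, h, w = A.shape[1], A.shape[2], A.shape[3]
    Z = h * w
    alphas = []
    for k in range(K):
        acc = 0.0
        for i in range(h):
            for j in range(w):
                up = A.copy()
                up[0, k, i, j] += eps
                down = A.copy()
                down[0, k, i, j] -= eps
                y_up = model.forward_from(layer_idx, up)[0, target_class]
                y_dn = model.forward_from(layer_idx, down)[0, target_class]
                acc += (y_up - y_dn) / (2 * eps)
        alphas.append(acc / Z)
    return alphas
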