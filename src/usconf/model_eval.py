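"""Multicriteria model evaluation via a CCL percentile sweep.

A model is scored by sweeping a confidence cutoff over the percentiles
``p = 1..99`` of its CCL values on the whole evaluated dataset. At each
``p`` the dataset is restricted to the ``n_p`` samples whose CCL strictly
exceeds the threshold ``t_p`` (the p-th percentile), the partial accuracy
``a_p`` is computed there, and the combined measure is

.. math::  m_p = a_p \\cdot \\frac{n_p}{N} \\cdot t_p,

rewarding simultaneously high accuracy, high confidence, and large
retained coverage. The model's score is :math:`m = \\max_p m_p`, attained
at the optimal cutoff ``p_opt`` (ties broken toward the smallest ``p``,
i.e. the largest retained dataset). As ``p`` grows, ``t_p`` is
non-decreasing and ``n_p`` non-increasing; when confidence and correctness
are positively associated, the partial accuracy tends to rise with ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PERCENTILES = range(1, 100)


@dataclass
class SweepPoint:
    p: int
    t_p: float
    n_p: int
    a_p: float
    m_p: float


@dataclass
class ModelEvalResult:
    m: float
    p_opt: int
    sweep: list[SweepPoint]
    N: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.p, s.t_p, s.n_p, s.a_p, s.m_p) for s in self.sweep],
            columns=["p", "t_p", "n_p", "a_p", "m_p"],
        )

    def at_opt(self) -> SweepPoint:
        return self.sweep[self.p_opt - 1]


def ccl_percentile(values, p: int, method: str = "linear") -> float:
    """The p-th percentile of the CCL values (linear interpolation between
    order statistics by default; the method is a knob because the final
    measure is threshold-sensitive)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty CCL list")
    if not 1 <= p <= 99:
        raise ValueError("percentile index must be in 1..99")
    if method != "linear":
        return float(np.percentile(values, p, method=method))
    s = np.sort(values)
    idx = (s.size - 1) * (p / 100.0)
    lo = int(np.floor(idx))
    hi = min(lo + 1, s.size - 1)
    frac = idx - lo
    return float(s[lo] + (s[hi] - s[lo]) * frac)


def sweep(ccl_values, correct, N: int | None = None,
          method: str = "linear") -> list[SweepPoint]:
    """Full percentile sweep.

    Parameters
    ----------
    ccl_values, correct:
        Per-sample CCLs and correctness flags, equal length ``N``.
    N:
        Total sample count (defaults to ``len(ccl_values)``).
    """
    ccl_values = np.asarray(ccl_values, dtype=np.float64)
    correct = np.asarray(correct, dtype=bool)
    if ccl_values.shape != correct.shape:
        raise ValueError("CCL values and correctness flags differ in length")
    if N is None:
        N = ccl_values.size
    if N <= 0:
        raise ValueError("need at least one sample")

    points = []
    for p in PERCENTILES:
        t_p = ccl_percentile(ccl_values, p, method=method)
        keep = ccl_values > t_p
        n_p = int(keep.sum())
        a_p = float(correct[keep].mean()) if n_p else 0.0
        m_p = a_p * (n_p / N) * t_p
        points.append(SweepPoint(p=p, t_p=t_p, n_p=n_p, a_p=a_p, m_p=m_p))
    return points


def evaluate_model(ccl_values, correct, method: str = "linear") -> ModelEvalResult:
    """Maximize ``m_p`` over the sweep; smallest-``p`` tie-break."""
    pts = sweep(ccl_values, correct, method=method)
    best = max(pts, key=lambda s: (s.m_p, -s.p))
    return ModelEvalResult(m=best.m_p, p_opt=best.p, sweep=pts,
                           N=len(np.asarray(ccl_values)))


def write_sweep_csv(result: ModelEvalResult, path: str | Path) -> None:
    result.to_frame().to_csv(Path(path), index=False)


def plot_sweep(result: ModelEvalResult, path: str | Path, title: str = "") -> None:
    """Charts of t_p, n_p, a_p, m_p against the cutoff percentile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.to_frame()
    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True)
    for ax, col, lab in zip(
        axes.ravel(), ["t_p", "n_p", "a_p", "m_p"],
        ["CCL threshold $t_p$", "retained samples $n_p$",
         "partial accuracy $a_p$", "measure $m_p$"],
    ):
        ax.plot(df["p"], df[col])
        ax.set_ylabel(lab)
        ax.grid(alpha=0.3)
    for ax in axes[1]:
        ax.set_xlabel("cutoff percentile $p$")
    axes.ravel()[3].axvline(result.p_opt, color="r", ls="--", lw=1)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=110)
    plt.close(fig)
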