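"""Community diversity and evenness indices from endpoint compositions.

All indices operate on proportional abundances. Inputs are renormalized to
sum to one before any index is computed (printed percent compositions carry
rounding error, e.g. columns summing to 99.8), zeros are dropped (richness
counts detected species only), and the Shannon index is natural-log based
throughout; there is no log-base option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiversityReport",
    "shannon_index",
    "simpson_index",
    "equitability",
    "diversity_report",
]


def _clean(proportions) -> np.ndarray:
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1:
        raise ValueError("proportions must be one-dimensional")
    if np.any(p < 0):
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector has no diversity")
    p = p[p > 0] / total
    return p[p > 0]  # guard against underflow of extreme ratios


def shannon_index(proportions) -> float:
    """Shannon diversity H = -sum p_i ln p_i, in nats.

    Zeros contribute nothing; the input is renormalized first, so the
    index is invariant to uniform scaling (percentages work as-is).
    """
    p = _clean(proportions)
    return float(-(p * np.log(p)).sum())


def simpson_index(proportions, variant: str = "lambda") -> float:
    """Simpson concentration and its common transforms.

    variant:
        ``lambda``  — Simpson concentration, sum of squared proportions;
        ``gini``    — Gini–Simpson, 1 - lambda (probability two random
                      draws are different species);
        ``inverse`` — inverse Simpson, 1 / lambda (effective species
                      number).
    """
    lam = float((_clean(proportions) ** 2).sum())
    if variant == "lambda":
        return lam
    if variant == "gini":
        return 1.0 - lam
    if variant == "inverse":
        return 1.0 / lam
    raise ValueError(f"unknown Simpson variant {variant!r}")


def equitability(shannon_h: float, richness: int) -> float:
    """Pielou evenness J = H / ln S; 1 means a perfectly even community."""
    if richness < 2:
        raise ValueError("equitability needs at least two species")
    if shannon_h < 0:
        raise ValueError("Shannon index cannot be negative")
    return float(shannon_h / np.log(richness))


@dataclass(frozen=True)
class DiversityReport:
    """All indices computed from one composition."""

    simpson_lambda: float
    gini_simpson: float
    inverse_simpson: float
    shannon_h: float
    richness: int
    equitability_j: float


def diversity_report(proportions) -> DiversityReport:
    """Compute every index for one composition vector."""
    p = _clean(proportions)
    h = float(-(p * np.log(p)).sum())
    lam = float((p**2).sum())
    s = int(p.size)
    j = h / np.log(s) if s >= 2 else 1.0
    return DiversityReport(
        simpson_lambda=lam,
        gini_simpson=1.0 - lam,
        inverse_simpson=1.0 / lam,
        shannon_h=h,
        richness=s,
        equitability_j=float(j),
    )
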