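"""Statistical comparisons for the dropout study.

Three procedures cover the study's inference needs:

* Dunnett's many-to-one test — every community compared against the full
  mix with family-wise error control over the whole figure panel
  (one-way ANOVA omnibus F reported alongside);
* a two-way (species x condition) ANOVA on composition replicates with
  per-species Sidak-adjusted contrasts, for comparing +Cg and -Cg
  endpoint compositions;
* the robust/non-robust classification: an enzyme's community output is
  robust iff no single-species dropout differs significantly from the
  full mix at the family-wise level.

Significance tiers mirror the conventional figure symbols: ``*`` p<0.05,
``**`` p<0.01, ``#`` p<0.001, ``ns`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

__all__ = [
    "ComparisonResult",
    "DunnettTable",
    "significance_tier",
    "dunnett_vs_reference",
    "dunnett_critical_value",
    "simulate_null_fwer",
    "sidak_adjust",
    "sidak_composition_test",
    "RobustnessVerdict",
    "classify_robustness",
]


def significance_tier(p_adj: float) -> str:
    """Figure symbol for an adjusted p-value."""
    if not 0.0 <= p_adj <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if p_adj < 0.001:
        return "#"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    """One group-vs-reference comparison with FWER-adjusted p."""

    group_label: str
    reference_label: str
    estimate: float  # mean(group) - mean(reference)
    statistic: float
    p_adj: float
    significance_tier: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_adj < self.alpha


@dataclass(frozen=True)
class DunnettTable:
    """Omnibus ANOVA plus the many-to-one comparisons."""

    anova_f: float
    anova_p: float
    comparisons: tuple[ComparisonResult, ...]


def dunnett_vs_reference(
    groups: Mapping[str, Sequence[float]],
    reference_label: str,
    alpha: float = 0.05,
    rng: int | np.random.Generator | None = 0,
) -> DunnettTable:
    """Compare every group to the reference, Dunnett-adjusted.

    The multivariate-t quadrature behind the adjusted p-values is
    randomized; a fixed ``rng`` (default seed 0) keeps results
    reproducible to well below the reporting precision.
    """
    if reference_label not in groups:
        raise KeyError(f"reference group {reference_label!r} missing")
    labels = [k for k in groups if k != reference_label]
    if not labels:
        raise ValueError("need at least one non-reference group")
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    control = np.asarray(groups[reference_label], dtype=float)
    if control.size < 2 or any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least two replicates")
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(control) == 0:
        raise ValueError("zero within-group variance everywhere: degenerate data")

    f_stat, f_p = sps.f_oneway(control, *samples)
    res = sps.dunnett(*samples, control=control, rng=rng)
    comparisons = tuple(
        ComparisonResult(
            group_label=label,
            reference_label=reference_label,
            estimate=float(np.mean(groups[label]) - control.mean()),
            statistic=float(stat),
            p_adj=float(min(max(p, 0.0), 1.0)),
            significance_tier=significance_tier(float(min(max(p, 0.0), 1.0))),
            alpha=alpha,
        )
        for label, stat, p in zip(labels, res.statistic, res.pvalue)
    )
    return DunnettTable(
        anova_f=float(f_stat), anova_p=float(f_p), comparisons=comparisons
    )


def dunnett_critical_value(
    n_comparisons: int,
    df: int,
    alpha: float = 0.05,
    rng: int | np.random.Generator | None = 0,
) -> float:
    """Two-sided critical value of the balanced many-to-one statistic.

    Root of P(max_i |T_i| <= c) = 1 - alpha where T follows the central
    multivariate t with the many-to-one correlation structure (rho = 1/2
    for a balanced layout) and ``df`` error degrees of freedom.
    """
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    corr = np.full((n_comparisons, n_comparisons), 0.5)
    np.fill_diagonal(corr, 1.0)
    mvt = sps.multivariate_t(shape=corr, df=df, seed=rng)

    def coverage(c: float) -> float:
        if n_comparisons == 1:
            return sps.t.cdf(c, df) - sps.t.cdf(-c, df)
        return float(
            mvt.cdf(
                np.full(n_comparisons, c),
                lower_limit=np.full(n_comparisons, -c),
            )
        )

    return float(brentq(lambda c: coverage(c) - (1 - alpha), 1.0, 8.0, xtol=1e-4))


def simulate_null_fwer(
    n_groups: int = 10,
    n_per_group: int = 9,
    n_datasets: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical family-wise error rate of the Dunnett procedure.

    Simulates ``n_datasets`` null datasets (all groups from one normal
    distribution), computes the balanced many-to-one t statistics with a
    pooled variance, and counts datasets where any |t| exceeds the
    Dunnett critical value — an event equivalent to min adjusted p <
    alpha. Returns the rejection fraction, which should match alpha.
    """
    rng = np.random.default_rng(seed)
    k = n_groups - 1
    df = n_groups * (n_per_group - 1)
    crit = dunnett_critical_value(k, df, alpha, rng=0)

    data = rng.standard_normal((n_datasets, n_groups, n_per_group))
    means = data.mean(axis=2)
    pooled_var = data.var(axis=2, ddof=1).mean(axis=1)
    t = (means[:, 1:] - means[:, :1]) / np.sqrt(pooled_var * 2.0 / n_per_group)[:, None]
    return float((np.abs(t).max(axis=1) > crit).mean())


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment for m independent comparisons."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if m < 1:
        raise ValueError("m must be at least 1")
    return float(1.0 - (1.0 - p) ** m)


def sidak_composition_test(
    comp_a: pd.DataFrame,
    comp_b: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[ComparisonResult, ...]:
    """Per-species comparison of two composition conditions.

    ``comp_a`` and ``comp_b`` hold replicate compositions (rows =
    replicates, columns = species, identical column sets). The layout is
    a two-way species x condition ANOVA: the within-cell mean square is
    pooled over every (species, condition) cell and each species'
    condition contrast is tested against it, with Sidak adjustment over
    the number of species. Estimates are mean(b) - mean(a).
    """
    if set(comp_a.columns) != set(comp_b.columns):
        raise ValueError("both conditions must cover the same species set")
    species = list(comp_a.columns)
    if len(comp_a) < 2 or len(comp_b) < 2:
        raise ValueError("need at least two replicates per condition")
    comp_b = comp_b[species]

    sse = 0.0
    df_resid = 0
    for frame in (comp_a, comp_b):
        resid = frame - frame.mean(axis=0)
        sse += float((resid**2).to_numpy().sum())
        df_resid += (len(frame) - 1) * len(species)
    if df_resid <= 0 or sse <= 0:
        raise ValueError("no residual variance: degenerate data")
    mse = sse / df_resid

    n_a, n_b = len(comp_a), len(comp_b)
    results = []
    for sp in species:
        diff = float(comp_b[sp].mean() - comp_a[sp].mean())
        se = np.sqrt(mse * (1.0 / n_a + 1.0 / n_b))
        t = diff / se
        p = 2.0 * sps.t.sf(abs(t), df_resid)
        p_adj = sidak_adjust(min(p, 1.0), len(species))
        results.append(
            ComparisonResult(
                group_label=sp,
                reference_label="condition_a",
                estimate=diff,
                statistic=float(t),
                p_adj=p_adj,
                significance_tier=significance_tier(p_adj),
                alpha=alpha,
            )
        )
    return tuple(results)


@dataclass(frozen=True)
class RobustnessVerdict:
    """Per-enzyme robustness call from the dropout comparisons."""

    enzyme: str
    robust: bool
    offending_designs: tuple[str, ...]


def classify_robustness(
    results: Mapping[str, Sequence[ComparisonResult]],
    dropout_labels: Sequence[str],
    alpha: float = 0.05,
) -> dict[str, RobustnessVerdict]:
    """Call each enzyme robust iff no dropout design is significant.

    ``results`` maps enzyme class to its Dunnett comparison list (which
    may also contain monoculture rows — only ``dropout_labels`` rows
    enter the verdict). Every dropout label must be present for every
    enzyme.
    """
    verdicts: dict[str, RobustnessVerdict] = {}
    for enzyme, comparisons in results.items():
        by_label = {c.group_label: c for c in comparisons}
        missing = [lab for lab in dropout_labels if lab not in by_label]
        if missing:
            raise ValueError(f"{enzyme}: missing dropout comparisons {missing}")
        offending = tuple(
            lab for lab in dropout_labels if by_label[lab].p_adj < alpha
        )
        verdicts[enzyme] = RobustnessVerdict(
            enzyme=enzyme, robust=not offending, offending_designs=offending
        )
    return verdicts
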