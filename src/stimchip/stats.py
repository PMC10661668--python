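"""Group comparison of normalized spike rates with culture-aware inference.

Neuron-level comparisons use the classical unpaired two-sample t-test
(Welch by default, pooled-variance optional).  Because neurons recorded in
the same culture are not independent, conclusions are double-checked with a
cluster bootstrap: cultures — not neurons — are resampled with replacement
within each condition and the neuron-weighted mean difference is
recomputed, yielding a percentile confidence interval and bootstrap p-value
that respect the clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ClusteringError, DomainError

__all__ = [
    "RateSample",
    "TTestResult",
    "BootstrapResult",
    "unpaired_t",
    "cluster_bootstrap_diff",
]


@dataclass(frozen=True)
class RateSample:
    """One neuron's normalized spike rate with its grouping metadata."""

    value: float
    neuron: str
    culture: str
    condition: str


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float
    ci: tuple[float, float]
    variant: str


@dataclass(frozen=True)
class BootstrapResult:
    mean_diff: float
    ci: tuple[float, float]
    p_boot: float
    n_boot: int


def unpaired_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    *,
    equal_var: bool = False,
    ci_level: float = 0.95,
) -> TTestResult:
    """Two-sided unpaired Student's t-test (Welch default).

    The statistic is for ``mean(a) - mean(b)``.  When both groups have zero
    variance and equal means the comparison is degenerate and the contract
    is t = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DomainError("each group needs n >= 2")
    if not 0 < ci_level < 1:
        raise DomainError("ci_level must be in (0, 1)")

    diff = float(a.mean() - b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))

    if equal_var:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        variant = "pooled"
    else:
        sa, sb = va / na, vb / nb
        se = math.sqrt(sa + sb)
        df = (
            (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
            if (sa + sb) > 0
            else float(na + nb - 2)
        )
        variant = "welch"

    if se == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0, 0.0, (0.0, 0.0), variant)
        t = math.copysign(math.inf, diff)
        return TTestResult(t, df, 0.0, diff, (diff, diff), variant)

    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    half = float(sps.t.ppf(0.5 + ci_level / 2.0, df)) * se
    return TTestResult(t, df, p, diff, (diff - half, diff + half), variant)


def cluster_bootstrap_diff(
    samples: pd.DataFrame | list[RateSample],
    n_boot: int = 2000,
    seed: int = 0,
    *,
    condition_a: str = "treatment",
    condition_b: str = "baseline",
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Culture-level bootstrap of the mean difference ``A - B``.

    Within each condition the cultures are resampled with replacement; the
    replicate statistic is the difference of neuron-weighted means (all
    neurons of the drawn cultures pooled, repeats included).  The CI is the
    percentile interval and ``p_boot`` is twice the smaller tail fraction of
    the replicate distribution around zero.  Deterministic under ``seed``.
    """
    if not isinstance(samples, pd.DataFrame):
        samples = pd.DataFrame(
            [(s.value, s.neuron, s.culture, s.condition) for s in samples],
            columns=["value", "neuron", "culture", "condition"],
        )
    if n_boot < 1:
        raise DomainError("n_boot must be >= 1")

    groups: dict[str, list[np.ndarray]] = {}
    for cond in (condition_a, condition_b):
        sub = samples[samples["condition"] == cond]
        by_culture = [
            g["value"].to_numpy(dtype=float) for _, g in sub.groupby("culture")
        ]
        if len(by_culture) < 2:
            raise ClusteringError(
                f"condition {cond!r} has {len(by_culture)} culture(s); need >= 2"
            )
        groups[cond] = by_culture

    def pooled_mean(cultures: list[np.ndarray], idx: np.ndarray) -> float:
        chosen = np.concatenate([cultures[i] for i in idx])
        return float(chosen.mean())

    na, nb = len(groups[condition_a]), len(groups[condition_b])
    observed = pooled_mean(groups[condition_a], np.arange(na)) - pooled_mean(
        groups[condition_b], np.arange(nb)
    )

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for r in range(n_boot):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        reps[r] = pooled_mean(groups[condition_a], ia) - pooled_mean(
            groups[condition_b], ib
        )

    alpha = 1.0 - ci_level
    ci = (
        float(np.quantile(reps, alpha / 2)),
        float(np.quantile(reps, 1 - alpha / 2)),
    )
    frac_le = float(np.mean(reps <= 0))
    frac_ge = float(np.mean(reps >= 0))
    p_boot = min(1.0, 2.0 * min(frac_le, frac_ge))
    return BootstrapResult(observed, ci, p_boot, n_boot)
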