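"""Group comparisons and multiplicity adjustment for ASL endpoints.

Two-group endpoints (e.g. wild-type vs βENaC-Tg well means, CF vs non-CF)
are compared with two-tailed Student's t-tests (paired or unpaired) or the
Wilcoxon signed-rank test; families of p-values are adjusted with the
two-stage linear step-up FDR procedure of Benjamini, Krieger and Yekutieli.

Repeated-measures designs (sequential drug additions to the same well) are
out of scope here: export the tidy per-position CSV and fit a linear
mixed-effects model with Tukey post-hoc contrasts in a dedicated package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "compare_groups",
    "bky_adjust",
    "percent_of_control",
    "rejection_rate",
]

_TESTS = ("unpaired_t", "paired_t", "wilcoxon_signed_rank")


@dataclass(frozen=True)
class GroupComparison:
    """Result of one two-group comparison."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    test: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


def compare_groups(
    a,
    b,
    test: str = "unpaired_t",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-tailed comparison of two groups of per-well values.

    ``paired_t`` and ``wilcoxon_signed_rank`` require equal-length, paired
    samples.  Degenerate no-effect cases (all paired differences zero, or
    two identical constant groups) are reported as statistic 0, p = 1 rather
    than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if test not in _TESTS:
        raise ValueError(f"test must be one of {_TESTS}")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test != "unpaired_t" and a.size != b.size:
        raise ValueError("paired tests require equal group sizes")

    if test == "unpaired_t":
        stat, p = sps.ttest_ind(a, b)
    elif test == "paired_t":
        stat, p = sps.ttest_rel(a, b)
    else:
        if np.all(a - b == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(a, b, zero_method="wilcox")
    if np.isnan(p):
        # zero-variance degenerate input: no detectable effect
        stat, p = 0.0, 1.0
    return GroupComparison(
        label_a=labels[0],
        label_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        test=test,
        statistic=float(stat),
        p_value=float(p),
    )


def bky_adjust(p_values, alpha: float = 0.05) -> np.ndarray:
    """Two-stage linear step-up FDR adjustment (Benjamini–Krieger–Yekutieli).

    Stage one estimates the number of true nulls with a BH pass at
    alpha/(1+alpha); stage two reruns BH scaled by that estimate.  Returns
    adjusted p-values in the input order (backed by statsmodels'
    ``fdr_tsbky`` implementation).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("all p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_tsbky")
    return np.minimum(adjusted, 1.0)


def percent_of_control(treated_mean: float, control_mean: float) -> float:
    """Treated group mean as a percentage of the control group mean."""
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    return 100.0 * treated_mean / control_mean


def rejection_rate(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    n_sims: int = 1000,
    alpha: float = 0.05,
    test: str = "unpaired_t",
    seed: int = 0,
) -> float:
    """Monte-Carlo power of a two-group comparison at the given parameters.

    Draws ``n_sims`` pairs of normal samples and reports the fraction of
    runs rejected at ``alpha`` — used to check that group differences of the
    magnitude seen between genotypes are reliably detected at realistic n.
    """
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(n_sims):
        a = rng.normal(mean_a, sd_a, n_a)
        b = rng.normal(mean_b, sd_b, n_b)
        if compare_groups(a, b, test=test).p_value < alpha:
            rejected += 1
    return rejected / n_sims
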