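"""Condensation statistics: RRR normalization, t tests, star coding.

The relative response ratio (RRR) maps a test construct's mutant/wild-type
integrated-density response onto a scale anchored at the controls:

    RRR = (R_test - R_neg) / (R_pos - R_neg),   R_x = I_x,mut / I_x,wt

with ``I`` the integrated density per cell.  The empty-vector negative
control sits at RRR = 0 and the reference-scaffold positive control at
RRR = 1 by construction.

Two-group comparisons use the classical pooled-variance Student t test or,
for values nested within independent replicate experiments, a nested
(hierarchical) t test whose error term is the between-experiment
mean square — the guard against pseudoreplication when hundreds of puncta
come from a handful of experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RRRInputs",
    "NestedSample",
    "TestResult",
    "ZeroWildTypeDenominatorError",
    "DegenerateControlsError",
    "compute_rrr",
    "student_t",
    "nested_t",
    "star_code",
    "mean_sem",
]


class ZeroWildTypeDenominatorError(ValueError):
    """A wild-type integrated density used as a denominator is not positive."""


class DegenerateControlsError(ValueError):
    """Negative- and positive-control ratios coincide: RRR is undefined."""


@dataclass(frozen=True)
class RRRInputs:
    """The six integrated-density-per-cell values entering the RRR.

    ``test`` is the construct under study, ``neg`` the empty-vector negative
    control, ``pos`` the reference-scaffold positive control; each is
    measured in the mutant (``mut``) and wild-type (``wt``) backgrounds.
    """

    I_test_mut: float
    I_test_wt: float
    I_neg_mut: float
    I_neg_wt: float
    I_pos_mut: float
    I_pos_wt: float

    def validate(self) -> None:
        for name in ("I_test_wt", "I_neg_wt", "I_pos_wt"):
            if getattr(self, name) <= 0:
                raise ZeroWildTypeDenominatorError(
                    f"{name} must be strictly positive"
                )
        if math.isclose(
            self.I_pos_mut / self.I_pos_wt,
            self.I_neg_mut / self.I_neg_wt,
            rel_tol=0.0,
            abs_tol=0.0,
        ):
            raise DegenerateControlsError(
                "positive- and negative-control ratios are equal; "
                "the RRR denominator is zero"
            )


def compute_rrr(inputs: RRRInputs) -> float:
    """Relative response ratio of the test construct.

    Exactly 0 when the test ratio equals the negative control's, exactly 1
    when it equals the positive control's.
    """
    inputs.validate()
    r_test = inputs.I_test_mut / inputs.I_test_wt
    r_neg = inputs.I_neg_mut / inputs.I_neg_wt
    r_pos = inputs.I_pos_mut / inputs.I_pos_wt
    return (r_test - r_neg) / (r_pos - r_neg)


# ---------------------------------------------------------------------------
# tests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    stars: str
    method: str  # "student" | "welch" | "nested"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.stars != star_code(self.p):
            raise ValueError("stars inconsistent with p")


def star_code(p: float) -> str:
    """GraphPad-style significance stars with strict thresholds.

    ``****`` p < 0.0001, ``***`` p < 0.001, ``**`` p < 0.01, ``*`` p < 0.05,
    otherwise ``n.s.`` (so p exactly 0.05 is non-significant).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard error of the mean (sample SD / sqrt(n)).

    A single value yields ``(value, nan)`` — the SEM is undefined.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("mean_sem of an empty sample")
    if v.size == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def _finish(t: float, df: float, method: str) -> TestResult:
    p = float(2.0 * sps.t.sf(abs(t), df))
    p = min(max(p, 0.0), 1.0)
    return TestResult(statistic=float(t), df=float(df), p=p,
                      stars=star_code(p), method=method)


def student_t(
    a: Sequence[float], b: Sequence[float], *, welch: bool = False
) -> TestResult:
    """Two-sided two-sample t test (pooled variance; Welch behind a flag).

    Degenerate zero-variance samples follow the convention: equal means give
    ``t = 0, p = 1``; unequal means with zero pooled variance are an error
    (the statistic is undefined).
    """
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    na, nb = x.size, y.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    dx = float(x.mean() - y.mean())
    ssx = float(((x - x.mean()) ** 2).sum())
    ssy = float(((y - y.mean()) ** 2).sum())
    if welch:
        vx, vy = ssx / (na - 1), ssy / (nb - 1)
        se2 = vx / na + vy / nb
        if se2 == 0.0:
            if dx == 0.0:
                return _finish(0.0, na + nb - 2, "welch")
            raise ValueError("zero variance with unequal means: t undefined")
        df = se2**2 / (
            (vx / na) ** 2 / (na - 1) + (vy / nb) ** 2 / (nb - 1)
        )
        return _finish(dx / math.sqrt(se2), df, "welch")
    df = na + nb - 2
    sp2 = (ssx + ssy) / df
    if sp2 == 0.0:
        if dx == 0.0:
            return _finish(0.0, df, "student")
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = dx / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return _finish(t, df, "student")


@dataclass
class NestedSample:
    """One group's values together with their experiment memberships."""

    group: str
    values: Sequence[float]
    experiment_of: Sequence[str]
    """Experiment id of each value (parallel to ``values``)."""

    def __post_init__(self) -> None:
        if len(self.values) != len(self.experiment_of):
            raise ValueError("values and experiment_of lengths differ")
        if len(self.values) == 0:
            raise ValueError(f"group {self.group!r} has no values")

    def experiment_stats(self) -> list[tuple[str, int, float]]:
        """(experiment id, n, mean) per experiment, in sorted-id order."""
        order: dict[str, list[float]] = {}
        for v, e in zip(self.values, self.experiment_of):
            order.setdefault(str(e), []).append(float(v))
        return [
            (e, len(vs), float(np.mean(vs))) for e, vs in sorted(order.items())
        ]

    @property
    def n_experiments(self) -> int:
        return len(set(map(str, self.experiment_of)))


def nested_t(a: NestedSample, b: NestedSample) -> TestResult:
    """Nested (hierarchical) two-group t test.

    Values are nested within independent experiments; the test compares the
    group means against the between-experiment-within-group mean square:

        t^2 = SS(group) / MS(experiment within group),
        df  = m_a + m_b - 2

    with ``m`` the experiment counts and sums of squares weighted by the
    per-experiment sample sizes.  In the balanced case this is the exact
    ANOVA equivalent of a mixed-model nested t test, and when every
    experiment contributes exactly one value it reduces exactly to
    :func:`student_t` on the raw values.
    """
    for s in (a, b):
        if s.n_experiments < 2:
            raise ValueError(
                f"group {s.group!r} has {s.n_experiments} experiment(s); "
                "the nested test needs at least 2 per group"
            )
    stats_a = a.experiment_stats()
    stats_b = b.experiment_stats()
    n_a = sum(n for _, n, _ in stats_a)
    n_b = sum(n for _, n, _ in stats_b)
    gm_a = sum(n * m for _, n, m in stats_a) / n_a
    gm_b = sum(n * m for _, n, m in stats_b) / n_b
    grand = (n_a * gm_a + n_b * gm_b) / (n_a + n_b)

    ss_group = n_a * (gm_a - grand) ** 2 + n_b * (gm_b - grand) ** 2
    ss_exp = sum(n * (m - gm_a) ** 2 for _, n, m in stats_a) + sum(
        n * (m - gm_b) ** 2 for _, n, m in stats_b
    )
    df_exp = len(stats_a) + len(stats_b) - 2
    ms_exp = ss_exp / df_exp
    if ms_exp == 0.0:
        if ss_group == 0.0:
            return _finish(0.0, df_exp, "nested")
        raise ValueError(
            "zero between-experiment mean square with unequal group means: "
            "t undefined"
        )
    t = math.copysign(math.sqrt(ss_group / ms_exp), gm_a - gm_b)
    return _finish(t, df_exp, "nested")
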