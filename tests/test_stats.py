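"""RRR normalization, t tests, star coding, and their oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from punctaquant import (
    DegenerateControlsError,
    NestedSample,
    RRRInputs,
    ZeroWildTypeDenominatorError,
    compute_rrr,
    mean_sem,
    nested_t,
    star_code,
    student_t,
)


def nested_anova_oracle(va, ea, vb, eb):
    """Explicit sums-of-squares nested ANOVA, pure-python loops."""
    exp_means = []  # (group index, n, mean)
    for gi, (vals, exps) in enumerate(((va, ea), (vb, eb))):
        per = {}
        for v, e in zip(vals, exps):
            per.setdefault(e, []).append(v)
        for e in sorted(per):
            exp_means.append((gi, len(per[e]), sum(per[e]) / len(per[e])))
    n_tot = [0, 0]
    s_tot = [0.0, 0.0]
    for gi, n, m in exp_means:
        n_tot[gi] += n
        s_tot[gi] += n * m
    gm = [s_tot[i] / n_tot[i] for i in range(2)]
    grand = (s_tot[0] + s_tot[1]) / (n_tot[0] + n_tot[1])
    ss_group = sum(n_tot[i] * (gm[i] - grand) ** 2 for i in range(2))
    ss_exp = sum(n * (m - gm[gi]) ** 2 for gi, n, m in exp_means)
    df = len(exp_means) - 2
    t = math.copysign(math.sqrt(ss_group / (ss_exp / df)), gm[0] - gm[1])
    return t, df, 2.0 * sps.t.sf(abs(t), df)


# ---------------------------------------------------------------------------
# RRR


def test_rrr_control_anchoring():
    """Test inputs equal to the negative control give 0; equal to the
    positive control give 1 — the two anchored control values."""
    neg = (6.0, 10.0)
    pos = (16.0, 10.0)
    at_neg = RRRInputs(*neg, *neg, *pos)
    at_pos = RRRInputs(*pos, *neg, *pos)
    assert compute_rrr(at_neg) == 0.0
    assert compute_rrr(at_pos) == 1.0


def test_rrr_hand_computed_example():
    inputs = RRRInputs(5.0, 10.0, 6.0, 10.0, 16.0, 10.0)
    assert math.isclose(compute_rrr(inputs), -0.1, rel_tol=1e-12)


def test_rrr_named_errors():
    with pytest.raises(ZeroWildTypeDenominatorError):
        compute_rrr(RRRInputs(5.0, 0.0, 6.0, 10.0, 16.0, 10.0))
    with pytest.raises(DegenerateControlsError):
        compute_rrr(RRRInputs(5.0, 10.0, 6.0, 10.0, 12.0, 20.0))


def test_rrr_background_rescaling_invariance(rng):
    """Scaling all mutant (or all wild-type) inputs by one positive constant
    leaves the RRR unchanged."""
    for _ in range(50):
        vals = rng.uniform(0.5, 20.0, 6)
        if math.isclose(vals[4] / vals[5], vals[2] / vals[3]):
            continue
        base = compute_rrr(RRRInputs(*vals))
        km, kw = rng.uniform(0.1, 10.0, 2)
        scaled = RRRInputs(
            vals[0] * km, vals[1] * kw, vals[2] * km,
            vals[3] * kw, vals[4] * km, vals[5] * kw,
        )
        assert math.isclose(compute_rrr(scaled), base, rel_tol=1e-9)


def test_rrr_is_affine_in_test_ratio(rng):
    """RRR is linear in I_test_mut / I_test_wt with slope 1/(R_pos - R_neg)."""
    neg = (6.0, 10.0)
    pos = (16.0, 10.0)
    r_neg, r_pos = 0.6, 1.6
    for r in rng.uniform(0.0, 3.0, 20):
        got = compute_rrr(RRRInputs(r * 10.0, 10.0, *neg, *pos))
        assert math.isclose(got, (r - r_neg) / (r_pos - r_neg), rel_tol=1e-9)


# ---------------------------------------------------------------------------
# Student t


def test_student_t_hand_example():
    res = student_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
    assert math.isclose(res.statistic, -1.224744871, rel_tol=1e-8)
    assert res.df == 4
    assert math.isclose(res.p, 0.2878641347, rel_tol=1e-8)
    assert res.stars == "n.s."


def test_student_t_matches_scipy(rng):
    for _ in range(25):
        a = rng.normal(0.0, 1.0, rng.integers(2, 12))
        b = rng.normal(0.5, 2.0, rng.integers(2, 12))
        ours = student_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert math.isclose(ours.statistic, ref.statistic, rel_tol=1e-10)
        assert math.isclose(ours.p, ref.pvalue, rel_tol=1e-10)
        ours_w = student_t(a, b, welch=True)
        ref_w = sps.ttest_ind(a, b, equal_var=False)
        assert math.isclose(ours_w.statistic, ref_w.statistic, rel_tol=1e-10)
        assert math.isclose(ours_w.p, ref_w.pvalue, rel_tol=1e-10)


def test_student_t_degenerate_conventions():
    res = student_t([3.0, 3.0], [3.0, 3.0])
    assert res.statistic == 0.0 and res.p == 1.0
    with pytest.raises(ValueError, match="undefined"):
        student_t([3.0, 3.0], [4.0, 4.0])


def test_student_t_antisymmetry(rng):
    a = rng.normal(size=6)
    b = rng.normal(size=9)
    fwd, rev = student_t(a, b), student_t(b, a)
    assert math.isclose(fwd.statistic, -rev.statistic, rel_tol=1e-12)
    assert math.isclose(fwd.p, rev.p, rel_tol=1e-12)


# ---------------------------------------------------------------------------
# nested t


def _nested(group, values, exps):
    return NestedSample(group, list(values), list(exps))


def test_nested_identical_experiment_means():
    a = _nested("a", [1.0, 1.0, 2.0, 2.0], ["e1", "e1", "e2", "e2"])
    b = _nested("b", [0.5, 1.5, 1.0, 3.0], ["e1", "e1", "e2", "e2"])
    res = nested_t(a, b)  # both groups: experiment means 1 and 2
    assert res.statistic == 0.0 and res.p == 1.0


def test_nested_reduces_to_student_with_one_value_per_experiment(rng):
    for _ in range(20):
        va = rng.normal(0.0, 1.0, 5)
        vb = rng.normal(1.0, 1.0, 7)
        a = _nested("a", va, [f"a{i}" for i in range(5)])
        b = _nested("b", vb, [f"b{i}" for i in range(7)])
        nested = nested_t(a, b)
        student = student_t(va, vb)
        assert math.isclose(nested.statistic, student.statistic, abs_tol=1e-12)
        assert nested.df == student.df
        assert math.isclose(nested.p, student.p, abs_tol=1e-12)


def test_nested_matches_sums_of_squares_oracle(rng):
    """200 random balanced designs: agree with the explicit nested-ANOVA
    oracle to 1e-10 in t and p."""
    for _ in range(200):
        m = int(rng.integers(2, 5))
        n = int(rng.integers(2, 7))
        shift = rng.normal(0.0, 2.0)
        va, ea, vb, eb = [], [], [], []
        for e in range(m):
            off_a, off_b = rng.normal(0.0, 1.0, 2)
            va += list(rng.normal(off_a, 1.0, n))
            ea += [f"e{e}"] * n
            vb += list(rng.normal(shift + off_b, 1.0, n))
            eb += [f"e{e}"] * n
        got = nested_t(_nested("a", va, ea), _nested("b", vb, eb))
        t_ref, df_ref, p_ref = nested_anova_oracle(va, ea, vb, eb)
        assert math.isclose(got.statistic, t_ref, rel_tol=1e-10, abs_tol=1e-10)
        assert got.df == df_ref
        assert math.isclose(got.p, p_ref, rel_tol=1e-10, abs_tol=1e-10)


def test_nested_guards_against_pseudoreplication(rng):
    """With positive between-experiment variance, the nested p is never
    smaller than a naive Student t on the pooled replicates."""
    for _ in range(200):
        shift = 2.0  # two between-experiment SDs
        va, ea, vb, eb = [], [], [], []
        for e in range(3):
            va += list(rng.normal(rng.normal(0.0, 1.0), 1.0, 5))
            ea += [f"e{e}"] * 5
            vb += list(rng.normal(rng.normal(shift, 1.0), 1.0, 5))
            eb += [f"e{e}"] * 5
        nested = nested_t(_nested("a", va, ea), _nested("b", vb, eb))
        naive = student_t(va, vb)
        assert nested.p >= naive.p


def test_nested_requires_two_experiments_per_group():
    a = _nested("a", [1.0, 2.0], ["e1", "e1"])
    b = _nested("b", [3.0, 4.0], ["e1", "e2"])
    with pytest.raises(ValueError, match="at least 2"):
        nested_t(a, b)


# ---------------------------------------------------------------------------
# stars and mean +/- SEM


@pytest.mark.parametrize(
    "p,code",
    [
        (0.00005, "****"), (0.0001, "***"), (0.0005, "***"), (0.001, "**"),
        (0.005, "**"), (0.01, "*"), (0.049, "*"), (0.05, "n.s."),
        (0.2, "n.s."), (1.0, "n.s."),
    ],
)
def test_star_code_thresholds(p, code):
    assert star_code(p) == code


def test_star_code_is_monotone(rng):
    rank = {"****": 4, "***": 3, "**": 2, "*": 1, "n.s.": 0}
    ps = np.sort(rng.random(50))
    codes = [rank[star_code(p)] for p in ps]
    assert all(a >= b for a, b in zip(codes, codes[1:]))


def test_star_code_domain():
    with pytest.raises(ValueError):
        star_code(-0.01)
    with pytest.raises(ValueError):
        star_code(1.01)


def test_mean_sem_values():
    mean, sem = mean_sem([1.0, 2.0, 3.0])
    assert mean == 2.0
    assert math.isclose(sem, 1.0 / math.sqrt(3.0), rel_tol=1e-9)
    assert mean_sem([5.0, 5.0, 5.0])[1] == 0.0


def test_mean_sem_scaling_linearity(rng):
    vals = rng.normal(10.0, 3.0, 8)
    m1, s1 = mean_sem(vals)
    m2, s2 = mean_sem(vals * 10.0)
    assert math.isclose(m2, 10.0 * m1, rel_tol=1e-12)
    assert math.isclose(s2, 10.0 * s1, rel_tol=1e-12)


def test_mean_sem_degenerate_inputs():
    mean, sem = mean_sem([4.2])
    assert mean == 4.2 and math.isnan(sem)
    with pytest.raises(ValueError):
        mean_sem([])
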