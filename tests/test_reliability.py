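"""ICC(2, A1) against brute-force ANOVA and an independent implementation."""
import numpy as np
import pandas as pd
import pytest

from equipain.exceptions import (DegenerateVarianceError, InsufficientDataError)
from equipain.reliability import (RatingsMatrix, build_ratings_matrix,
                                  classify_reliability, icc_agreement,
                                  icc_by_scale)


def brute_force_icc_a1(x):
    """Independent two-way ANOVA ICC(A,1) via explicit cell sums."""
    n, k = x.shape
    grand = x.mean()
    msr = k / (n - 1) * sum((x[i].mean() - grand) ** 2 for i in range(n))
    msc = n / (k - 1) * sum((x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = sum((x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def test_identical_raters_give_one():
    col = np.arange(1.0, 9.0)
    res = icc_agreement(RatingsMatrix(np.column_stack([col, col, col])))
    assert res.estimate == pytest.approx(1.0)
    assert res.label == "excellent"


def test_small_matrix_matches_hand_anova():
    x = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0], [5.0, 6.0]])
    res = icc_agreement(RatingsMatrix(x))
    assert res.estimate == pytest.approx(brute_force_icc_a1(x), abs=1e-12)


def test_random_matrices_match_brute_force():
    rng = np.random.default_rng(17)
    for _ in range(20):
        x = rng.integers(0, 12, size=(10, 3)).astype(float)
        if np.ptp(x) == 0:
            continue
        res = icc_agreement(RatingsMatrix(x))
        assert res.estimate == pytest.approx(brute_force_icc_a1(x), abs=1e-10)
        assert res.ci_low <= res.estimate <= res.ci_high


def test_matches_pingouin_reference():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    subj = rng.normal(0, 2, 30)
    x = subj[:, None] + rng.normal(0, 1, (30, 3)) + np.array([0.0, 0.5, 1.0])
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(30), 3),
        "rater": np.tile(["a", "b", "c"], 30),
        "score": x.ravel(),
    })
    ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
    ref2 = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
    res = icc_agreement(RatingsMatrix(x))
    assert res.estimate == pytest.approx(ref2["ICC"], abs=1e-6)
    # pingouin reports the CI rounded to 2 decimals
    assert res.ci_low == pytest.approx(ref2["CI95"][0], abs=0.01)
    assert res.ci_high == pytest.approx(ref2["CI95"][1], abs=0.01)


def test_independent_raters_near_zero():
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, size=(500, 2))
    res = icc_agreement(RatingsMatrix(x))
    assert abs(res.estimate) < 0.1


def test_constant_offset_lowers_agreement():
    rng = np.random.default_rng(23)
    subj = rng.normal(0, 2, 40)
    base = np.column_stack([subj + rng.normal(0, 0.5, 40) for _ in range(3)])
    shifted = base.copy()
    shifted[:, 2] += 3.0
    icc0 = icc_agreement(RatingsMatrix(base)).estimate
    icc1 = icc_agreement(RatingsMatrix(shifted)).estimate
    assert icc1 < icc0
    assert icc1 == pytest.approx(brute_force_icc_a1(shifted), abs=1e-10)


def test_row_permutation_invariance():
    rng = np.random.default_rng(29)
    x = rng.normal(0, 1, (20, 3)) + rng.normal(0, 2, 20)[:, None]
    a = icc_agreement(RatingsMatrix(x)).estimate
    b = icc_agreement(RatingsMatrix(x[rng.permutation(20)])).estimate
    assert a == pytest.approx(b, abs=1e-12)


def test_variance_component_recovery():
    """Mean estimate approaches sigma2_s / (sigma2_s + sigma2_r + sigma2_e)."""
    rng = np.random.default_rng(31)
    s2_s, s2_r, s2_e = 4.0, 1.0, 1.0
    truth = s2_s / (s2_s + s2_r + s2_e)
    estimates = []
    for _ in range(200):
        subj = rng.normal(0, np.sqrt(s2_s), 200)
        rater = rng.normal(0, np.sqrt(s2_r), 3)
        x = subj[:, None] + rater[None, :] + rng.normal(0, np.sqrt(s2_e), (200, 3))
        estimates.append(icc_agreement(RatingsMatrix(x)).estimate)
    assert np.mean(estimates) == pytest.approx(truth, abs=0.03)


def test_insufficient_and_degenerate_errors():
    with pytest.raises(InsufficientDataError):
        icc_agreement(RatingsMatrix(np.ones((4, 2)) + np.arange(4)[:, None]))
    with pytest.raises(DegenerateVarianceError):
        icc_agreement(RatingsMatrix(np.full((6, 3), 2.0)))
    # missing data: complete-case deletion drops incomplete rows
    x = np.column_stack([np.arange(8.0), np.arange(8.0) + 1])
    x[0, 1] = np.nan
    res = icc_agreement(RatingsMatrix(x))
    assert res.n_subjects == 7


@pytest.mark.parametrize("estimate,label", [
    (0.753, "good"),
    (0.648, "moderate"),
    (0.522, "moderate"),
    (0.432, "poor"),
    (0.95, "excellent"),
    (0.49999, "poor"),
    (0.9, "excellent"),
])
def test_reliability_labels(estimate, label):
    assert classify_reliability(estimate) == label


def test_rotating_third_observer_pooling():
    rows = []
    rng = np.random.default_rng(3)
    for ev in range(12):
        third = ["3", "4", "5"][ev % 3]
        for obs in ["1", "2", third]:
            rows.append({"horse": "H01", "occasion": f"occ{ev:02d}",
                         "observer": obs, "scale": "CPS",
                         "timing": "after_gait", "phase": "post_induction",
                         "total": int(rng.integers(0, 10))})
    df = pd.DataFrame(rows)
    m = build_ratings_matrix(df, "CPS")
    assert m.values.shape[1] == 3  # observers 3/4/5 pooled into one column
    assert not np.isnan(m.values).any()
    m_sep = build_ratings_matrix(df, "CPS", pool_third=False)
    assert m_sep.values.shape[1] == 5
    out = icc_by_scale(df, ["CPS"])
    assert set(out.columns) == {"scale", "icc", "ci_low", "ci_high", "label", "n", "k"}
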