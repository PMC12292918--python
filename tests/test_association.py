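"""Association engine: OLS against brute-force solvers, scan decomposition,
omnibus identities and permutation-threshold mechanics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repqtl.association import (
    conditional_scan,
    encode_covariates,
    fit_additive,
    kmer_hla_scan,
    omnibus_position_test,
    permutation_threshold,
    scan,
)
from repqtl.io import ValidationError


def _cov(n, rng, ncov=2):
    return pd.DataFrame(
        rng.normal(size=(n, ncov)),
        index=[f"I{i}" for i in range(n)],
        columns=[f"c{j}" for j in range(ncov)],
    )


def _ols_oracle(y, X):
    """Pseudo-inverse brute-force OLS: beta, se of the last column."""
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return beta[-1], np.sqrt(cov[-1, -1]), dof


def test_fit_additive_matches_pinv_oracle(rng):
    for _ in range(10):
        n = 50
        cov = _cov(n, rng, 3)
        d = pd.Series(rng.binomial(2, 0.3, n).astype(float), index=cov.index)
        y = pd.Series(rng.normal(size=n), index=cov.index)
        res = fit_additive(y, d, cov)
        X = np.column_stack([np.ones(n), cov.to_numpy(), d.to_numpy()])
        b, se, dof = _ols_oracle(y.to_numpy(), X)
        assert res.beta == pytest.approx(b, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(b / se), dof), abs=1e-12)


def test_fit_additive_textbook_six_points():
    # y = 2 + 0.5 d + noise chosen so the normal equations solve by hand
    idx = list("abcdef")
    d = pd.Series([0, 0, 1, 1, 2, 2.0], index=idx)
    y = pd.Series([2.1, 1.9, 2.4, 2.6, 3.1, 2.9], index=idx)
    cov = pd.DataFrame(index=idx)
    res = fit_additive(y, d, cov)
    # hand solution: beta = Sxy/Sxx with Sxx = 4, Sxy = 2
    assert res.beta == pytest.approx(0.5, abs=1e-12)
    assert res.n == 6


def test_fit_additive_perfect_fit_caps_p(rng):
    cov = _cov(30, rng, 1)
    d = pd.Series(rng.binomial(2, 0.4, 30).astype(float), index=cov.index)
    y = 0.5 * d
    res = fit_additive(y, d, cov)
    assert res.beta == pytest.approx(0.5, abs=1e-10)
    assert res.p <= 1e-290


def test_fit_additive_null_p_uniform(rng):
    ps = []
    for _ in range(300):
        n = 40
        cov = _cov(n, rng, 1)
        d = pd.Series(rng.binomial(2, 0.3, n).astype(float), index=cov.index)
        y = pd.Series(rng.normal(size=n), index=cov.index)
        ps.append(fit_additive(y, d, cov).p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_zero_variance_dosage_flagged(rng):
    cov = _cov(20, rng)
    d = pd.Series(np.ones(20), index=cov.index)
    y = pd.Series(rng.normal(size=20), index=cov.index)
    res = fit_additive(y, d, cov)
    assert res.note == "untestable"
    assert np.isnan(res.p)


def test_collinear_covariates_error(rng):
    cov = _cov(20, rng, 2)
    cov["c2"] = 2 * cov["c0"]
    d = pd.Series(rng.binomial(2, 0.4, 20).astype(float), index=cov.index)
    y = pd.Series(rng.normal(size=20), index=cov.index)
    with pytest.raises(ValidationError, match="collinear"):
        fit_additive(y, d, cov)


def test_scan_decomposes_into_fit_additive(rng):
    n = 60
    cov = _cov(n, rng, 3)
    X = pd.DataFrame(rng.binomial(2, 0.3, size=(n, 3)).astype(float),
                     index=cov.index, columns=["v1", "v2", "v3"])
    Y = pd.DataFrame(rng.normal(size=(n, 2)), index=cov.index,
                     columns=["f1", "f2"])
    res = scan(Y, X, cov)
    assert len(res) == 6  # 2 features x 3 variants
    for row in res.itertuples():
        single = fit_additive(Y[row.feature], X[row.predictor], cov)
        assert row.beta == pytest.approx(single.beta, abs=1e-10)
        assert row.se == pytest.approx(single.se, abs=1e-10)
        assert row.p == pytest.approx(single.p, rel=1e-8, abs=1e-12)


def test_scan_invariances(rng):
    n = 50
    cov = _cov(n, rng, 2)
    X = pd.DataFrame(rng.binomial(2, 0.3, size=(n, 4)).astype(float),
                     index=cov.index,
                     columns=[f"v{j}" for j in range(4)])
    Y = pd.DataFrame(rng.normal(size=(n, 3)), index=cov.index,
                     columns=[f"f{j}" for j in range(3)])
    base = scan(Y, X, cov)
    # individual reordering
    perm = rng.permutation(n)
    res_perm = scan(Y.iloc[perm], X.iloc[perm], cov.iloc[perm])
    assert np.allclose(base["p"], res_perm["p"], atol=1e-10)
    # affine rescaling of covariates
    cov2 = cov * 7.0 - 3.0
    res_affine = scan(Y, X, cov2)
    assert np.allclose(base["beta"], res_affine["beta"], atol=1e-10)
    assert np.allclose(base["p"], res_affine["p"], atol=1e-10)


def test_scan_flags_zero_variance_rows_without_aborting(rng):
    n = 30
    cov = _cov(n, rng, 1)
    X = pd.DataFrame({"ok": rng.binomial(2, 0.4, n).astype(float),
                      "flat": np.ones(n)}, index=cov.index)
    Y = pd.DataFrame({"f": rng.normal(size=n)}, index=cov.index)
    res = scan(Y, X, cov)
    flat = res[res.predictor == "flat"].iloc[0]
    assert flat.note == "untestable" and np.isnan(flat.p)
    assert res[res.predictor == "ok"].iloc[0].note == ""


def test_conditional_scan_on_independent_variant_is_noop_like(rng):
    n = 80
    cov = _cov(n, rng, 2)
    X = pd.DataFrame(rng.binomial(2, 0.3, size=(n, 3)).astype(float),
                     index=cov.index, columns=["a", "b", "c"])
    Y = pd.DataFrame({"f": 0.8 * X["a"] + rng.normal(size=n)}, index=cov.index)
    marg = scan(Y, X, cov)
    cond = conditional_scan(Y, X, cov, ["c"])
    a_m = marg[marg.predictor == "a"].iloc[0].beta
    a_c = cond[cond.predictor == "a"].iloc[0].beta
    assert a_c == pytest.approx(a_m, abs=0.15)
    # conditioning on the tested predictor itself -> untestable
    self_row = cond[cond.predictor == "c"].iloc[0]
    assert self_row.note == "untestable"


def test_encode_covariates_reference_levels():
    df = pd.DataFrame(
        {
            "age": [60.0, 70.0, 65.0, 50.0],
            "sex": ["F", "M", "F", "F"],
            "cancer_type": ["mel", "mel", "renal", "mel"],
        },
        index=list("wxyz"),
    )
    enc = encode_covariates(df)
    # largest level is the reference -> only the minority levels get columns
    assert set(enc.columns) == {"age", "sex_M", "cancer_type_renal"}
    assert enc["sex_M"].tolist() == [0.0, 1.0, 0.0, 0.0]


# ---------------------------------------------------------------------------
# omnibus
# ---------------------------------------------------------------------------


def _residues_biallelic(n, rng, p=0.4):
    a = rng.binomial(2, p, n).astype(float)
    return pd.DataFrame({"S": a, "Y": 2 - a},
                        index=[f"I{i}" for i in range(n)])


def test_omnibus_biallelic_equals_single_residue_t_test(rng):
    for _ in range(5):
        n = 60
        cov = _cov(n, rng, 2)
        res_d = _residues_biallelic(n, rng)
        y = pd.Series(
            0.3 * res_d["S"].to_numpy() + rng.normal(size=n), index=cov.index
        )
        omni = omnibus_position_test(y, res_d, cov)
        # the rarer residue is the non-reference dosage column
        minor = res_d.sum().idxmin()
        single = fit_additive(y, res_d[minor], cov)
        assert omni.df_num == 1
        assert omni.p == pytest.approx(single.p, abs=1e-10)
        assert omni.t == pytest.approx(single.t**2, rel=1e-8)


def test_omnibus_reference_choice_irrelevant(rng):
    n = 50
    cov = _cov(n, rng, 1)
    hap = rng.choice(3, size=(n, 2), p=[0.5, 0.3, 0.2])
    res_d = pd.DataFrame(
        {r: (hap == i).sum(axis=1).astype(float)
         for i, r in enumerate("DHN")},
        index=cov.index,
    )
    y = pd.Series(rng.normal(size=n), index=cov.index)
    p1 = omnibus_position_test(y, res_d, cov).p
    p2 = omnibus_position_test(y, res_d[["N", "H", "D"]], cov).p
    assert p1 == pytest.approx(p2, abs=1e-10)


def test_omnibus_null_uniform(rng):
    ps = []
    for _ in range(400):
        n = 50
        cov = _cov(n, rng, 1)
        hap = rng.choice(3, size=(n, 2), p=[0.5, 0.3, 0.2])
        res_d = pd.DataFrame(
            {r: (hap == i).sum(axis=1).astype(float)
             for i, r in enumerate("DHN")},
            index=cov.index,
        )
        if (res_d.std() > 0).sum() < 2:
            continue
        y = pd.Series(rng.normal(size=n), index=cov.index)
        ps.append(omnibus_position_test(y, res_d, cov).p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_omnibus_monomorphic_untestable(rng):
    n = 30
    cov = _cov(n, rng, 1)
    res_d = pd.DataFrame({"Y": np.full(n, 2.0), "S": np.zeros(n)},
                         index=cov.index)
    y = pd.Series(rng.normal(size=n), index=cov.index)
    out = omnibus_position_test(y, res_d, cov)
    assert out.note == "untestable"


def test_omnibus_requires_dosage_sum_two(rng):
    n = 20
    cov = _cov(n, rng, 1)
    res_d = pd.DataFrame({"Y": np.ones(n), "S": np.zeros(n)}, index=cov.index)
    with pytest.raises(ValidationError, match="sum to 2"):
        omnibus_position_test(pd.Series(rng.normal(size=n), index=cov.index),
                              res_d, cov)


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------


def _null_setup(rng, n=40, n_var=30, n_feat=5):
    cov = _cov(n, rng, 2)
    X = pd.DataFrame(rng.binomial(2, 0.3, size=(n, n_var)).astype(float),
                     index=cov.index,
                     columns=[f"v{j}" for j in range(n_var)])
    Y = pd.DataFrame(rng.normal(size=(n, n_feat)), index=cov.index,
                     columns=[f"f{j}" for j in range(n_feat)])
    return Y, X, cov


def test_permutation_threshold_deterministic_and_alpha_one(rng):
    Y, X, cov = _null_setup(rng)
    null1 = permutation_threshold(Y, X, cov, B=40, alpha=0.05, seed=9)
    null2 = permutation_threshold(Y, X, cov, B=40, alpha=0.05, seed=9)
    assert np.array_equal(null1.min_p, null2.min_p)
    full = permutation_threshold(Y, X, cov, B=40, alpha=1.0, seed=9)
    assert full.threshold == pytest.approx(full.min_p.max())
    assert null1.threshold == pytest.approx(np.quantile(null1.min_p, 0.05))


def test_permutation_threshold_min_b(rng):
    Y, X, cov = _null_setup(rng)
    with pytest.raises(ValidationError, match="B"):
        permutation_threshold(Y, X, cov, B=10)


def test_permutation_min_p_matches_direct_scan_of_permuted_rows(rng):
    """One permutation round equals scanning the permuted phenotype matrix."""
    Y, X, cov = _null_setup(rng, n=30, n_var=10, n_feat=3)
    null = permutation_threshold(Y, X, cov, B=20, alpha=0.5, seed=4)
    rng2 = np.random.default_rng(4)
    perm = rng2.permutation(len(Y))
    Yp = pd.DataFrame(Y.to_numpy()[perm], index=Y.index, columns=Y.columns)
    direct = scan(Yp, X, cov)
    assert null.min_p[0] == pytest.approx(direct["p"].min(), rel=1e-9)


def test_freedman_lane_variant_runs(rng):
    Y, X, cov = _null_setup(rng)
    null = permutation_threshold(Y, X, cov, B=25, seed=3, method="freedman-lane")
    assert ((null.min_p > 0) & (null.min_p <= 1)).all()


def test_kmer_scan_conditioning_appends_covariate(rng):
    n = 70
    cov = _cov(n, rng, 2)
    hla = pd.DataFrame(rng.binomial(2, 0.3, size=(n, 2)).astype(float),
                       index=cov.index, columns=["B*44", "B*35"])
    vg = pd.Series(rng.normal(size=n), index=cov.index, name="TRBV19")
    Y = pd.DataFrame({"TGDSNQP": 0.9 * hla["B*44"] + 0.5 * vg
                      + rng.normal(size=n)}, index=cov.index)
    plain = kmer_hla_scan(Y, hla, cov)
    conditioned = kmer_hla_scan(Y, hla, cov, condition_vgene=vg)
    assert (conditioned["model"] == "conditional").all()
    b_plain = plain[plain.predictor == "B*44"].iloc[0].beta
    b_cond = conditioned[conditioned.predictor == "B*44"].iloc[0].beta
    # direct effect retains its sign under conditioning
    assert b_plain > 0 and b_cond > 0
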