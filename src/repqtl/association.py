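"""Additive association scans, conditional analysis, amino-acid omnibus tests
and permutation-derived family-wise significance thresholds.

The model throughout is ordinary least squares on the INRT phenotype scale:

    trait ~ predictor dosage + genetic PC1/2 + TCR PC1/2 + age + sex + cancer type

``scan`` evaluates every feature x predictor pair with the
Frisch-Waugh-Lovell shortcut (phenotypes and dosages residualised against
the covariates once, then per-pair simple regression), which is numerically
identical to the full OLS fit done by :func:`fit_additive`.

The permutation null applies a single random row permutation to the whole
phenotype matrix per round - all features move together, preserving
inter-feature correlation, while genotypes and covariates stay fixed - and
records the minimum p over all feature x predictor tests; the family-wise
threshold is the alpha-quantile (linear interpolation) of those minima.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, ValidationError
from .phenotypes import PhenotypeMatrix

__all__ = [
    "AssociationResult",
    "PermutationNull",
    "encode_covariates",
    "fit_additive",
    "scan",
    "conditional_scan",
    "omnibus_position_test",
    "permutation_threshold",
    "kmer_hla_scan",
]

P_FLOOR = 1e-300  # underflow cap, flagged in the `note` column

RESULT_COLUMNS = [
    "feature", "predictor", "beta", "se", "t", "p", "n", "df_num",
    "model", "conditioned_on", "note",
]


@dataclasses.dataclass
class AssociationResult:
    feature: str
    predictor: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    df_num: int = 1
    model: str = "marginal"
    conditioned_on: tuple = ()
    note: str = ""

    def to_row(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditioned_on"] = ";".join(self.conditioned_on)
        return d


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns (no intercept): numeric columns pass through;
    categorical columns become indicators with the largest level as
    reference."""
    out = {}
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
            out[col] = s.astype(float)
        else:
            levels = s.value_counts().index  # largest level first -> reference
            for lv in levels[1:]:
                out[f"{col}_{lv}"] = (s == lv).astype(float)
    return pd.DataFrame(out, index=covariates.index)


def _cap_p(p: float) -> tuple[float, str]:
    if p < P_FLOOR:
        return P_FLOOR, "p_underflow"
    return p, ""


def _design(covariates: pd.DataFrame) -> np.ndarray:
    X = covariates.to_numpy(float)
    return np.column_stack([np.ones(len(X)), X])


def _check_collinear(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            f"collinear covariate design (rank {rank} < {X.shape[1]}): "
            f"columns {list(names)}"
        )


def fit_additive(
    y: pd.Series,
    dosage: pd.Series,
    covariates: pd.DataFrame,
    feature: str = "y",
    predictor: str = "dosage",
    model: str = "marginal",
    conditioned_on: tuple = (),
) -> AssociationResult:
    """OLS fit of one phenotype on one predictor dosage plus covariates.

    Complete cases only; two-sided p from the t distribution with residual
    degrees of freedom.
    """
    df = pd.concat(
        [y.rename("_y"), dosage.rename("_d"), covariates], axis=1, join="inner"
    ).dropna()
    n, p_cov = len(df), covariates.shape[1]
    if n < p_cov + 3:
        raise ValidationError(f"too few complete cases ({n})")
    d = df["_d"].to_numpy(float)
    if d.std() == 0:
        return AssociationResult(
            feature, predictor, np.nan, np.nan, np.nan, np.nan, n,
            model=model, conditioned_on=conditioned_on, note="untestable",
        )
    C = _design(df[covariates.columns])
    _check_collinear(C, ["intercept", *covariates.columns])
    X = np.column_stack([C, d])
    yv = df["_y"].to_numpy(float)
    coef, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    if rank < X.shape[1]:
        return AssociationResult(
            feature, predictor, np.nan, np.nan, np.nan, np.nan, n,
            model=model, conditioned_on=conditioned_on, note="untestable",
        )
    resid = yv - X @ coef
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    beta = float(coef[-1])
    if se == 0:
        t = np.inf if beta != 0 else 0.0
        p, note = ((P_FLOOR, "p_underflow") if beta != 0 else (1.0, "perfect_fit"))
    else:
        t = beta / se
        p, note = _cap_p(float(2 * stats.t.sf(abs(t), dof)))
    return AssociationResult(
        feature, predictor, beta, se, float(t), p, n,
        model=model, conditioned_on=conditioned_on, note=note,
    )


# ---------------------------------------------------------------------------
# matrix scan
# ---------------------------------------------------------------------------


def _as_pheno_frame(phenos) -> pd.DataFrame:
    if isinstance(phenos, PhenotypeMatrix):
        phenos._require("inrt", "scan")
        return phenos.values
    return phenos


def _as_predictor_frame(predictors) -> pd.DataFrame:
    if isinstance(predictors, GenotypeMatrix):
        return predictors.dosage
    return predictors


def _aligned(phenos, predictors, covariates):
    Y = _as_pheno_frame(phenos)
    X = _as_predictor_frame(predictors)
    ids = Y.index.intersection(X.index).intersection(covariates.index)
    return Y.loc[ids], X.loc[ids], covariates.loc[ids]


def _residual_parts(Y, X, covariates):
    """Residualise phenotypes and (mean-imputed) dosages against covariates."""
    C = _design(covariates)
    _check_collinear(C, ["intercept", *covariates.columns])
    Q, _ = np.linalg.qr(C)
    Yv = Y.to_numpy(float)
    Xv = X.to_numpy(float)
    if np.isnan(Xv).any():
        mean = np.nanmean(Xv, axis=0)
        nan_idx = np.where(np.isnan(Xv))
        Xv = Xv.copy()
        Xv[nan_idx] = np.take(mean, nan_idx[1])
    Yr = Yv - Q @ (Q.T @ Yv)
    Xr = Xv - Q @ (Q.T @ Xv)
    dof = len(Yv) - C.shape[1] - 1
    return Yr, Xr, Q, dof


def _pairwise_stats(Yr, Xr, dof):
    """beta/se/t/p for every predictor x feature pair on residualised data."""
    xx = (Xr * Xr).sum(axis=0)
    yy = (Yr * Yr).sum(axis=0)
    xy = Xr.T @ Yr  # variants x features
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / xx[:, None]
        rss = np.maximum(yy[None, :] - xy**2 / xx[:, None], 0.0)
        se = np.sqrt(rss / dof / xx[:, None])
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, p, xx


def scan(
    phenos,
    predictors,
    covariates: pd.DataFrame,
    model: str = "marginal",
    conditioned_on: tuple = (),
) -> pd.DataFrame:
    """Additive OLS of every feature x predictor pair.

    Missing dosages are mean-imputed within the scan (complete-case behaviour
    is available through :func:`fit_additive`).  Zero-variance predictors are
    emitted as flagged untestable rows rather than aborting.
    """
    Y, X, cov = _aligned(phenos, predictors, covariates)
    Yr, Xr, _, dof = _residual_parts(Y, X, cov)
    if dof < 2:
        raise ValidationError("not enough residual degrees of freedom")
    beta, se, t, p, xx = _pairwise_stats(Yr, Xr, dof)
    n_var, n_feat = beta.shape
    untestable = xx <= 1e-12
    rows = {
        "feature": np.tile(Y.columns.to_numpy(object), n_var),
        "predictor": np.repeat(X.columns.to_numpy(object), n_feat),
        "beta": beta.ravel(),
        "se": se.ravel(),
        "t": t.ravel(),
        "p": np.maximum(p.ravel(), P_FLOOR),
        "n": len(Y),
        "df_num": 1,
        "model": model,
        "conditioned_on": ";".join(conditioned_on),
    }
    out = pd.DataFrame(rows)
    note = np.where(np.repeat(untestable, n_feat), "untestable", "")
    note = np.where((out["p"] <= P_FLOOR) & (note == ""), "p_underflow", note)
    out["note"] = note
    out.loc[out["note"] == "untestable", ["beta", "se", "t", "p"]] = np.nan
    return out


def conditional_scan(
    phenos,
    predictors,
    covariates: pd.DataFrame,
    condition_on: Sequence[str],
) -> pd.DataFrame:
    """Scan with the conditioned predictors' dosages added to the covariates.

    Testing a predictor that is itself conditioned on is flagged untestable.
    """
    X = _as_predictor_frame(predictors)
    missing = [c for c in condition_on if c not in X.columns]
    if missing:
        raise ValidationError(f"conditioned predictors not found: {missing}")
    cond = X[list(condition_on)]
    if cond.isna().any().any():
        cond = cond.fillna(cond.mean())
    cov = covariates.join(cond.add_prefix("cond_"), how="inner")
    res = scan(phenos, X, cov, model="conditional", conditioned_on=tuple(condition_on))
    self_rows = res["predictor"].isin(condition_on)
    res.loc[self_rows, ["beta", "se", "t", "p"]] = np.nan
    res.loc[self_rows, "note"] = "untestable"
    return res


def omnibus_position_test(
    y: pd.Series,
    residue_dosages: pd.DataFrame,
    covariates: pd.DataFrame,
    feature: str = "y",
    position: str = "position",
) -> AssociationResult:
    """Multi-residue omnibus F-test at one HLA amino-acid position.

    Compares covariates + (k-1) residue dosage columns (most common residue
    dropped as reference) against covariates alone; p from F(k-1, residual
    df).  Residue columns collinear with the covariates are dropped with a
    warning, reducing the numerator df.
    """
    df = pd.concat([y.rename("_y"), residue_dosages, covariates], axis=1,
                   join="inner").dropna()
    res = df[residue_dosages.columns]
    sums = res.sum(axis=1)
    if not np.allclose(sums, 2):
        raise ValidationError("residue dosages must sum to 2 per individual")
    observed = [c for c in res.columns if res[c].std() > 0]
    if len(observed) < 1 or res[observed].shape[1] + 1 < 2:
        return AssociationResult(
            feature, position, np.nan, np.nan, np.nan, np.nan, len(df),
            df_num=0, model="omnibus", note="untestable",
        )
    # reference residue: the most common one
    totals = res.sum(axis=0)
    reference = totals.idxmax()
    keep = [c for c in res.columns if c != reference and res[c].std() > 0]
    if not keep:
        return AssociationResult(
            feature, position, np.nan, np.nan, np.nan, np.nan, len(df),
            df_num=0, model="omnibus", note="untestable",
        )
    C = _design(df[covariates.columns])
    _check_collinear(C, ["intercept", *covariates.columns])
    # drop residue columns that add no rank beyond the covariates
    cols, X = [], C
    for c in keep:
        cand = np.column_stack([X, df[c].to_numpy(float)])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
            X, cols = cand, cols + [c]
        else:
            warnings.warn(
                f"residue {c!r} collinear with covariates; dropped from the "
                "omnibus test", stacklevel=2,
            )
    q = len(cols)
    if q == 0:
        return AssociationResult(
            feature, position, np.nan, np.nan, np.nan, np.nan, len(df),
            df_num=0, model="omnibus", note="untestable",
        )
    yv = df["_y"].to_numpy(float)
    coef0, *_ = np.linalg.lstsq(C, yv, rcond=None)
    rss0 = float(np.sum((yv - C @ coef0) ** 2))
    coef1, *_ = np.linalg.lstsq(X, yv, rcond=None)
    rss1 = float(np.sum((yv - X @ coef1) ** 2))
    dof = len(df) - X.shape[1]
    F = ((rss0 - rss1) / q) / (rss1 / dof)
    p, note = _cap_p(float(stats.f.sf(F, q, dof)))
    # report the first residue's coefficient as the headline effect
    beta = float(coef1[C.shape[1]])
    return AssociationResult(
        feature, position, beta, np.nan, float(F), p, len(df),
        df_num=q, model="omnibus", note=note,
    )


@dataclasses.dataclass
class PermutationNull:
    """Empirical family-wise null: per-permutation minimum p-values and the
    alpha-quantile threshold."""

    chain: str | None
    B: int
    min_p: np.ndarray
    alpha: float
    threshold: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Null vector plus the derived threshold, for audit trails."""
        return pd.DataFrame({
            "permutation": np.arange(self.B),
            "min_p": self.min_p,
            "alpha": self.alpha,
            "threshold": self.threshold,
        })


def permutation_threshold(
    phenos,
    predictors,
    covariates: pd.DataFrame,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    method: str = "samples",
) -> PermutationNull:
    """Permutation-derived family-wise significance threshold.

    ``method='samples'`` permutes phenotype rows jointly against fixed
    genotype + covariate rows (the default); ``method='freedman-lane'``
    permutes covariate-residualised phenotypes instead.  The threshold is the
    alpha-quantile (linear interpolation) of the B per-permutation minimum
    p-values over all feature x predictor tests.
    """
    if B < 20:
        raise ValidationError("B < 20 gives an unstable quantile")
    if method not in ("samples", "freedman-lane"):
        raise ValidationError(f"unknown permutation method {method!r}")
    Y, X, cov = _aligned(phenos, predictors, covariates)
    Yv = Y.to_numpy(float)
    Yr, Xr, Q, dof = _residual_parts(Y, X, cov)
    xx = (Xr * Xr).sum(axis=0)
    ok = xx > 1e-12
    Xn = Xr[:, ok] / np.sqrt(xx[ok])
    rng = np.random.default_rng(seed)
    n = len(Yv)
    min_p = np.empty(B)
    base = Yr if method == "freedman-lane" else Yv
    for b in range(B):
        perm = rng.permutation(n)
        Yp = base[perm]
        Zp = Yp - Q @ (Q.T @ Yp)  # re-residualise after permuting rows
        norms = np.sqrt((Zp * Zp).sum(axis=0))
        norms[norms == 0] = np.inf
        R = Xn.T @ (Zp / norms)
        r2max = min(np.max(R**2), 1.0 - 1e-15)
        tmax = np.sqrt(r2max * dof / (1.0 - r2max))
        min_p[b] = max(2 * stats.t.sf(tmax, dof), P_FLOOR)
    threshold = float(np.quantile(min_p, alpha))  # linear interpolation
    chain = phenos.chain if isinstance(phenos, PhenotypeMatrix) else None
    return PermutationNull(chain, B, min_p, alpha, threshold, seed)


def kmer_hla_scan(
    kmer_phenos,
    predictors,
    covariates: pd.DataFrame,
    condition_vgene: pd.Series | None = None,
) -> pd.DataFrame:
    """CDR3 k-mer usage against HLA alleles / MHC variants; optionally
    conditions on one V-gene usage column (added to the covariates)."""
    if condition_vgene is None:
        return scan(kmer_phenos, predictors, covariates)
    cov = covariates.join(condition_vgene.rename("cond_vgene"), how="inner")
    return scan(kmer_phenos, predictors, cov, model="conditional",
                conditioned_on=(str(condition_vgene.name),))
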