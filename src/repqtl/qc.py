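"""Sample/variant quality control, genotype principal components and LD.

Thresholds follow standard array-genotyping practice: samples are dropped for
heterozygosity outside mean +/- 3.5 SD or for > 10 % missing SNPs; variants
for minor-allele frequency < 0.01, Hardy-Weinberg exact-test p < 1e-6 or call
rate < 90 %.  The pipeline applies variant QC first, so heterozygosity SDs
are computed on post-variant-QC calls (the QCReport thresholds record this);
each filter is also callable standalone in either order.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, ValidationError

__all__ = [
    "QCReport",
    "sample_qc",
    "variant_qc",
    "hwe_exact_p",
    "genetic_pcs",
    "ld_r2",
]


@dataclasses.dataclass
class QCReport:
    dropped_samples: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    dropped_variants: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    thresholds: dict = dataclasses.field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", i, r) for i, r in self.dropped_samples]
        rows += [("variant", v, r) for v, r in self.dropped_variants]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def sample_qc(
    g: GenotypeMatrix, het_sd: float = 3.5, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples with outlying heterozygosity or excess missingness.

    Heterozygosity is the fraction of (rounded) non-missing calls equal to 1;
    outliers lie outside mean +/- ``het_sd`` standard deviations.
    """
    if g.n_individuals < 3:
        raise ValidationError("sample_qc needs >= 3 samples")
    d = g.dosage.to_numpy()
    missing = np.isnan(d)
    miss_frac = missing.mean(axis=1)
    calls = np.round(d)
    het = np.nansum(calls == 1, axis=1) / np.maximum((~missing).sum(axis=1), 1)
    report = QCReport(thresholds={"het_sd": het_sd, "max_missing": max_missing,
                                  "het_basis": "calls present at input"})
    drop_miss = miss_frac > max_missing
    mu, sd = het[~drop_miss].mean(), het[~drop_miss].std(ddof=0)
    drop_het = np.zeros_like(drop_miss)
    if sd > 0:
        drop_het = np.abs(het - mu) > het_sd * sd
    for i, ind in enumerate(g.individuals):
        if drop_miss[i]:
            report.dropped_samples.append((ind, "missingness"))
        elif drop_het[i]:
            report.dropped_samples.append((ind, "heterozygosity"))
    keep = ~(drop_miss | drop_het)
    if not keep.any():
        raise ValidationError("sample_qc dropped every sample")
    out = GenotypeMatrix(g.dosage.loc[keep], g.variants)
    return out, report


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (conditional enumeration over
    heterozygote counts given the allele counts; two-sided by summing the
    probabilities of all configurations no more likely than the observed)."""
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele count
    # enumerate P(het = h | n, rare) via the standard recurrence
    h_vals = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(h_vals))
    # start from the mid heterozygote count for numerical stability
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    i_mid = int((mid - h_vals[0]) // 2)
    probs[i_mid] = 1.0
    for i in range(i_mid, 0, -1):  # downward: h -> h - 2
        h = h_vals[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for i in range(i_mid, len(h_vals) - 1):  # upward: h -> h + 2
        h = h_vals[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[int((n_het - h_vals[0]) // 2)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def variant_qc(
    g: GenotypeMatrix,
    min_maf: float = 0.01,
    hwe_p: float = 1e-6,
    min_call: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants by call rate, minor-allele frequency and HWE exact p.

    HWE uses hard calls (dosages rounding to an integer); fractional imputed
    dosages are excluded from the HWE counts but kept for analysis.
    """
    d = g.dosage.to_numpy()
    report = QCReport(
        thresholds={"min_maf": min_maf, "hwe_p": hwe_p, "min_call": min_call}
    )
    keep = []
    for j, vid in enumerate(g.variant_ids):
        col = d[:, j]
        obs = col[~np.isnan(col)]
        call_rate = len(obs) / len(col)
        if call_rate < min_call:
            report.dropped_variants.append((vid, "call_rate"))
            continue
        af = obs.mean() / 2 if len(obs) else 0.0
        maf = min(af, 1 - af)
        if maf < min_maf:
            report.dropped_variants.append((vid, "maf"))
            continue
        hard = obs[np.isclose(obs, np.round(obs))]
        counts = [int((np.round(hard) == k).sum()) for k in (0, 1, 2)]
        if hwe_exact_p(counts[1], counts[0], counts[2]) < hwe_p:
            report.dropped_variants.append((vid, "hwe"))
            continue
        keep.append(vid)
    if not keep:
        warnings.warn("variant_qc removed every variant", stacklevel=2)
    out = GenotypeMatrix(g.dosage[keep], g.variants.loc[keep])
    return out, report


def _standardized_pcs(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCs of a column-standardised, mean-imputed matrix.

    Returns (scores n x k, loadings m x k, explained-variance fractions).
    The sign of each component is fixed by making its largest-magnitude
    loading positive.
    """
    X = np.asarray(X, float).copy()
    col_mean = np.nanmean(X, axis=0)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = np.take(col_mean, nan_idx[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    informative = sd > 0
    X = X[:, informative] / sd[informative]
    if k == 0:
        return np.zeros((X.shape[0], 0)), np.zeros((informative.sum(), 0)), np.zeros(0)
    rank = np.linalg.matrix_rank(X)
    if k > rank:
        raise ValidationError(f"requested {k} PCs but matrix rank is {rank}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for c in range(k):
        peak = np.argmax(np.abs(loadings[:, c]))
        if loadings[peak, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    explained = (S**2) / (S**2).sum()
    return scores, loadings, explained[:k]


def genetic_pcs(g: GenotypeMatrix, k: int = 2) -> pd.DataFrame:
    """Principal-component scores of the dosage matrix (post-QC input)."""
    scores, _, _ = _standardized_pcs(g.dosage.to_numpy(), k)
    return pd.DataFrame(
        scores, index=g.individuals, columns=[f"genetic_pc{i + 1}" for i in range(k)]
    )


def ld_r2(g: GenotypeMatrix, variant_a: str, variant_b: str) -> float:
    """Squared Pearson correlation of two dosage vectors over complete cases.

    Returns NaN when either variant has zero variance among complete cases.
    """
    a = g.dosage[variant_a].to_numpy()
    b = g.dosage[variant_b].to_numpy()
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValidationError("need >= 2 complete observations")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)
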