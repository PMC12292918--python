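"""Repertoire-derived quantitative traits.

V-gene usage is the number of *unique* clones per V-gene per individual
(clone identity key: chain + V-gene + CDR3 amino acids; read multiplicity is
ignored).  CDR3 7-mer usage counts, per individual, the unique clones whose
CDR3 (length 12-18) contains a motif as a contiguous substring - a CDR3 of
length L yields L-6 sliding windows and contributes at most once per motif.

Counts are carried through a fixed stage order, enforced at run time:

    raw_counts -> (TMM) normalized -> batch_corrected -> inrt

TMM is the trimmed-mean-of-M-values library normalisation (reference sample
chosen by upper quartile; weighted trimmed mean of log2 ratios; factors have
geometric mean 1); normalisation is counts-per-million on the effective
library; batch correction removes per-feature batch main effects by least
squares; INRT is the rank-based inverse normal transform with the Blom offset
Phi^-1((r - 3/8) / (n + 1/4)).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .io import ValidationError
from .qc import _standardized_pcs

__all__ = [
    "PhenotypeMatrix",
    "count_vgene_usage",
    "count_kmers",
    "tmm_factors",
    "normalize_counts",
    "remove_batch",
    "inrt",
    "tcr_pcs",
    "vgene_phenotype_pipeline",
    "kmer_phenotype_pipeline",
]

STAGES = ("raw_counts", "normalized", "batch_corrected", "inrt")
CLONE_KEY = ["individual_id", "chain", "v_gene", "cdr3_aa"]


@dataclasses.dataclass
class PhenotypeMatrix:
    """Individuals x features with transform provenance (``stage``)."""

    values: pd.DataFrame
    stage: str
    chain: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")

    def _require(self, stage: str, op: str) -> None:
        if self.stage != stage:
            raise ValidationError(
                f"{op} expects a {stage!r} matrix, got {self.stage!r} "
                "(stage order is raw_counts -> normalized -> batch_corrected -> inrt)"
            )


def _unique_clones(clones: pd.DataFrame, chain: str, timepoint: str,
                   productive_only: bool = True) -> pd.DataFrame:
    df = clones
    if productive_only:
        df = df[df["productive"].astype(bool)]
    df = df[(df["chain"] == chain) & (df["timepoint"] == timepoint)]
    return df.drop_duplicates(CLONE_KEY)


def count_vgene_usage(
    clones: pd.DataFrame,
    chain: str,
    timepoint: str = "C1",
    individuals=None,
) -> PhenotypeMatrix:
    """Unique-clone count per (individual, V-gene); multiplicity is ignored."""
    uniq = _unique_clones(clones, chain, timepoint)
    counts = (
        uniq.groupby(["individual_id", "v_gene"]).size().unstack(fill_value=0)
    )
    if individuals is not None:
        missing = [i for i in individuals if i not in counts.index]
        if missing:
            warnings.warn(
                f"{len(missing)} individual(s) with no {chain} clones at "
                f"{timepoint}; rows of zeros emitted", stacklevel=2,
            )
        counts = counts.reindex(individuals, fill_value=0)
    return PhenotypeMatrix(counts.sort_index(axis=1), "raw_counts", chain)


_AA_LUT = np.zeros(256, dtype=np.int64)
for _i, _c in enumerate("ACDEFGHIKLMNPQRSTVWY"):
    _AA_LUT[ord(_c)] = _i
_KMER_BASE = 20


def _kmer_windows(cdr3: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-windows of an array of strings -> (clone row index, window id).

    Windows are encoded as base-20 integers (a 7-mer fits in 35 bits), so the
    per-clone dedup and the (individual, k-mer) aggregation reduce to integer
    sorts instead of string hashing.
    """
    lens = np.char.str_len(cdr3.astype(str))
    powers = _KMER_BASE ** np.arange(k, dtype=np.int64)
    rows, kmers = [], []
    for L in np.unique(lens):
        if L < k:
            continue
        idx = np.nonzero(lens == L)[0]
        block = _AA_LUT[
            cdr3[idx].astype(f"S{L}").view(np.uint8).reshape(len(idx), L)
        ]
        for off in range(L - k + 1):
            rows.append(idx)
            kmers.append(block[:, off: off + k] @ powers)
    if not rows:
        return np.empty(0, int), np.empty(0, dtype=np.int64)
    return np.concatenate(rows), np.concatenate(kmers)


def _unique_sorted(arr: np.ndarray, return_counts: bool = False):
    """Sort-based unique (predictable O(n log n); avoids hash overhead on
    multi-million-element int64 keys)."""
    s = np.sort(arr)
    if len(s) == 0:
        return (s, s.astype(np.intp)) if return_counts else s
    edge = np.empty(len(s), dtype=bool)
    edge[0] = True
    np.not_equal(s[1:], s[:-1], out=edge[1:])
    vals = s[edge]
    if not return_counts:
        return vals
    idx = np.flatnonzero(edge)
    counts = np.diff(np.append(idx, len(s)))
    return vals, counts


def _decode_kmers(codes: np.ndarray, k: int) -> list[str]:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for code in codes:
        chars = []
        for _ in range(k):
            chars.append(alphabet[code % _KMER_BASE])
            code //= _KMER_BASE
        out.append("".join(chars))
    return out


def count_kmers(
    clones: pd.DataFrame,
    chain: str,
    timepoint: str = "C1",
    k: int = 7,
    min_len: int = 12,
    max_len: int = 18,
    min_prevalence: float = 0.0,
    individuals=None,
) -> PhenotypeMatrix:
    """Unique clones per individual containing each CDR3 k-mer.

    Only CDR3s with length in [min_len, max_len] contribute; a motif occurring
    twice within one CDR3 still counts that clone once.  ``min_prevalence``
    optionally drops k-mers observed in fewer than that fraction of
    individuals (useful at synthetic scale, where random CDR3s make almost
    every 7-mer private).
    """
    if k != 7:
        warnings.warn(
            f"k={k}; 7 is the conventional window (ITAM-sized motif)",
            stacklevel=2,
        )
    uniq = _unique_clones(clones, chain, timepoint)
    lens = uniq["cdr3_aa"].str.len()
    uniq = uniq[(lens >= min_len) & (lens <= max_len)]
    cdr3 = uniq["cdr3_aa"].to_numpy(dtype=object)
    rows, kmers = _kmer_windows(cdr3, k)
    ind_codes, ind_levels = pd.factorize(uniq["individual_id"], sort=True)
    span = np.int64(_KMER_BASE) ** k
    # per-clone presence: dedupe (clone row, k-mer) pairs
    pair_keys = _unique_sorted(rows.astype(np.int64) * span + kmers)
    pair_rows = (pair_keys // span).astype(np.int64)
    pair_kmers = pair_keys % span
    # count unique clones per (individual, k-mer)
    ik_keys, ik_counts = _unique_sorted(
        ind_codes[pair_rows].astype(np.int64) * span + pair_kmers,
        return_counts=True,
    )
    ik_ind = (ik_keys // span).astype(np.intp)
    ik_kmer = ik_keys % span
    kept_kmers, n_carriers = _unique_sorted(ik_kmer, return_counts=True)
    kmer_pos = np.searchsorted(kept_kmers, ik_kmer)
    n_ind = len(individuals) if individuals is not None else len(ind_levels)
    if min_prevalence > 0 and len(kept_kmers):
        # filter before densifying: the all-k-mer matrix is enormous
        ok = n_carriers[kmer_pos] >= min_prevalence * max(n_ind, 1)
        ik_ind, ik_counts = ik_ind[ok], ik_counts[ok]
        kept_kmers = _unique_sorted(ik_kmer[ok])
        kmer_pos = np.searchsorted(kept_kmers, ik_kmer[ok])
    dense = np.zeros((len(ind_levels), len(kept_kmers)), dtype=np.int64)
    dense[ik_ind, kmer_pos] = ik_counts
    counts = pd.DataFrame(dense, index=pd.Index(ind_levels, name="individual_id"),
                          columns=_decode_kmers(kept_kmers, k))
    if individuals is not None:
        counts = counts.reindex(individuals, fill_value=0)
    return PhenotypeMatrix(counts.sort_index(axis=1), "raw_counts", chain)


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------


def _tmm_one(obs, ref, lib_obs, lib_ref, trim_m, trim_a) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
        # asymptotic binomial variance of M; weights are its inverse
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if len(m) == 0:
        return float("nan")
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or np.sum(1.0 / v[keep]) == 0:
        return float("nan")
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(
    counts: PhenotypeMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-individual TMM scaling factors (geometric mean 1).

    The reference sample is the one whose 75th-percentile count/library ratio
    is closest to the mean such ratio; each sample's factor is the weighted
    (inverse asymptotic binomial variance), doubly trimmed mean of log2
    count ratios against the reference.
    """
    counts._require("raw_counts", "tmm_factors")
    x = counts.values.to_numpy(float)
    if x.shape[0] < 2:
        raise ValidationError("TMM needs >= 2 individuals")
    lib = x.sum(axis=1)
    if (lib == 0).any():
        raise ValidationError("individual with all-zero counts")
    uq = np.quantile(x, 0.75, axis=1) / lib
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = x[ref_idx]
    factors = np.ones(len(lib))
    for i in range(len(lib)):
        f = _tmm_one(x[i], ref, lib[i], lib[ref_idx], trim_m, trim_a)
        if np.isnan(f):
            warnings.warn(
                f"sample {counts.values.index[i]!r} shares no usable features "
                "with the reference; factor set to 1", stacklevel=2,
            )
            f = 1.0
        factors[i] = f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.values.index, name="tmm_factor")


def normalize_counts(counts: PhenotypeMatrix, factors: pd.Series) -> PhenotypeMatrix:
    """Counts-per-million on the effective (TMM-scaled) library size."""
    counts._require("raw_counts", "normalize_counts")
    x = counts.values
    lib = x.sum(axis=1)
    eff = lib * factors.reindex(x.index)
    if (eff <= 0).any():
        raise ValidationError("zero effective library size")
    vals = x.div(eff, axis=0) * 1e6
    return PhenotypeMatrix(vals, "normalized", counts.chain)


def remove_batch(matrix: PhenotypeMatrix, batch: pd.Series) -> PhenotypeMatrix:
    """Remove per-feature batch main effects by least squares.

    Returns residuals plus the reference-batch level (grand structure kept).
    A single batch is a no-op; a batch containing one individual is refused
    as confounded.
    """
    matrix._require("normalized", "remove_batch")
    b = batch.reindex(matrix.values.index)
    levels = b.value_counts()
    if (levels < 2).any() and len(levels) > 1:
        bad = levels.index[levels < 2].tolist()
        raise ValidationError(f"batch(es) {bad} have a single individual")
    if len(levels) == 1:
        return PhenotypeMatrix(matrix.values.copy(), "batch_corrected", matrix.chain)
    ref = levels.index[0]  # largest batch as reference level
    others = [lv for lv in levels.index if lv != ref]
    X = np.column_stack(
        [np.ones(len(b))] + [(b == lv).to_numpy(float) for lv in others]
    )
    Y = matrix.values.to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    corrected = Y - X[:, 1:] @ coef[1:]
    return PhenotypeMatrix(
        pd.DataFrame(corrected, index=matrix.values.index,
                     columns=matrix.values.columns),
        "batch_corrected",
        matrix.chain,
    )


def inrt(matrix: PhenotypeMatrix) -> PhenotypeMatrix:
    """Rank-based inverse normal transform, per feature, Blom offset 3/8.

    Ties get average ranks; constant columns map to all zeros (warned).
    """
    matrix._require("batch_corrected", "inrt")
    Y = matrix.values.to_numpy(float)
    n = Y.shape[0]
    if n < 3:
        raise ValidationError("INRT needs n >= 3")
    ranks = rankdata(Y, axis=0)
    out = ndtri((ranks - 0.375) / (n + 0.25))
    const_mask = (Y == Y[0]).all(axis=0)
    out[:, const_mask] = 0.0
    constant = list(matrix.values.columns[const_mask])
    if constant:
        warnings.warn(
            f"{len(constant)} constant feature column(s) set to 0 by INRT",
            stacklevel=2,
        )
    return PhenotypeMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        "inrt",
        matrix.chain,
    )


def tcr_pcs(matrix: PhenotypeMatrix, k: int = 2) -> pd.DataFrame:
    """TCR-usage principal components (computed pre-INRT, on the
    batch-corrected normalised usage matrix)."""
    matrix._require("batch_corrected", "tcr_pcs")
    scores, _, _ = _standardized_pcs(matrix.values.to_numpy(float), k)
    return pd.DataFrame(
        scores,
        index=matrix.values.index,
        columns=[f"tcr_pc{i + 1}" for i in range(k)],
    )


def _finish_pipeline(counts: PhenotypeMatrix, batch: pd.Series):
    factors = tmm_factors(counts)
    normalized = normalize_counts(counts, factors)
    corrected = remove_batch(normalized, batch)
    return inrt(corrected), corrected


def vgene_phenotype_pipeline(
    clones: pd.DataFrame,
    chain: str,
    batch: pd.Series,
    timepoint: str = "C1",
    individuals=None,
) -> tuple[PhenotypeMatrix, PhenotypeMatrix]:
    """counts -> TMM -> CPM -> batch correction -> INRT for V-gene usage.

    Returns (inrt matrix, batch-corrected matrix); the latter feeds
    :func:`tcr_pcs`.
    """
    counts = count_vgene_usage(clones, chain, timepoint, individuals)
    return _finish_pipeline(counts, batch)


def kmer_phenotype_pipeline(
    clones: pd.DataFrame,
    chain: str,
    batch: pd.Series,
    timepoint: str = "C1",
    k: int = 7,
    min_len: int = 12,
    max_len: int = 18,
    min_prevalence: float = 0.0,
    individuals=None,
) -> tuple[PhenotypeMatrix, PhenotypeMatrix]:
    """Same pipeline for CDR3 k-mer usage."""
    counts = count_kmers(
        clones, chain, timepoint, k, min_len, max_len, min_prevalence, individuals
    )
    return _finish_pipeline(counts, batch)
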