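"""Cell-level analyses: inclusion filters, per-subset V-gene usage, the
20-gene tumour-reactivity score (TRS), and TRS vs HLA-matching tests.

Cells are included if they have >= 300 transcripts, <= 20 % mitochondrial
reads and a valid chain configuration (one alpha + one beta, or two alpha +
one beta).  A clone at the single-cell level is a distinct alpha+beta CDR3
combination within an individual; *expanded* clones have >= 2 cells,
*singlets* exactly one.  TRS is the per-cell sum of a 20-gene panel,
standardised to mean 0 / SD 1 across the analysis set, and is tested against
HLA-matching status by comparing nested linear models

    H1: TRS ~ matching status + protocol        H0: TRS ~ protocol

with an F-test (experimental protocol as fixed indicator columns).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import HLAGenotypes, ValidationError
from .dynamics import HLAMatchRule

__all__ = [
    "TRSResult",
    "qc_cells",
    "cell_clones",
    "cell_vgene_usage",
    "residualize_on_protocol",
    "subset_association",
    "compute_trs",
    "match_cells",
    "trs_vs_matching",
    "trs_matching_analysis",
    "trs_clone_size_correlation",
]

CELL_CLONE_KEY = ["individual_id", "alpha1_cdr3", "alpha2_cdr3", "beta_cdr3"]


@dataclasses.dataclass
class TRSResult:
    stratum: str
    beta: float
    p: float
    n_cells: int
    note: str = ""


def qc_cells(
    cells: pd.DataFrame,
    min_transcripts: int = 300,
    max_mito: float = 0.20,
) -> pd.DataFrame:
    """Apply the cell inclusion filters (transcripts, mitochondrial fraction,
    then chain multiplicity 1a1b or 2a1b)."""
    keep = (
        (cells["total_transcripts"] >= min_transcripts)
        & (cells["mito_fraction"] <= max_mito)
    )
    out = cells[keep]
    keep_chain = out["n_alpha"].isin([1, 2]) & (out["n_beta"] == 1)
    return out[keep_chain].copy()


def cell_clones(cells: pd.DataFrame) -> pd.DataFrame:
    """Collapse cells to unique clones (distinct alpha+beta CDR3 combination
    per individual) with their cell counts."""
    grp = cells.groupby(CELL_CLONE_KEY, dropna=False)
    out = grp.agg(
        beta_v_gene=("beta_v_gene", "first"),
        alpha1_v_gene=("alpha1_v_gene", "first"),
        n_cells=("cell_id", "size"),
    ).reset_index()
    return out


def cell_vgene_usage(
    cells: pd.DataFrame, subset: str | None, chain: str = "beta"
) -> pd.DataFrame:
    """Per-individual unique-clone V-gene usage within one cell subset,
    normalised by the individual's total unique clones in that subset."""
    df = cells if subset is None else cells[cells["subset"] == subset]
    if df.empty:
        raise ValidationError(f"no cells in subset {subset!r}")
    clones = cell_clones(df)
    vcol = {"beta": "beta_v_gene", "alpha": "alpha1_v_gene"}[chain]
    counts = clones.groupby(["individual_id", vcol]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def residualize_on_protocol(pcs: pd.DataFrame, protocol: pd.Series) -> pd.DataFrame:
    """Regress the experimental protocol out of TCR PCs and return the
    residuals (the protocol is typically collinear with them)."""
    prot = protocol.reindex(pcs.index)
    levels = prot.unique()
    X = np.column_stack(
        [np.ones(len(prot))] + [(prot == lv).to_numpy(float) for lv in levels[1:]]
    )
    Y = pcs.to_numpy(float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return pd.DataFrame(Y - X @ coef, index=pcs.index, columns=pcs.columns)


def subset_association(
    usage: pd.DataFrame,
    predictor: pd.Series,
    covariates: pd.DataFrame,
    protocol: pd.Series,
    tcr_pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-subset V-gene usage association with protocol-residualised TCR PCs
    and protocol indicators among the covariates."""
    from .association import encode_covariates, fit_additive

    cov = covariates.copy()
    cov["protocol"] = protocol.reindex(cov.index)
    if tcr_pcs is not None:
        cov = cov.join(
            residualize_on_protocol(tcr_pcs, protocol).add_prefix("resid_")
        )
    enc = encode_covariates(cov)
    pred_enc = [c for c in enc.columns if c.startswith("protocol_")]
    common = predictor.reindex(enc.index)
    for c in pred_enc:
        if common.std() > 0 and abs(np.corrcoef(common.fillna(common.mean()),
                                                enc[c])[0, 1]) > 0.999:
            raise ValidationError("protocol confounded with the predictor")
    rows = []
    for feature in usage.columns:
        res = fit_additive(usage[feature], predictor, enc,
                           feature=str(feature), predictor=str(predictor.name))
        rows.append(res.to_row())
    return pd.DataFrame(rows)


def compute_trs(
    cells: pd.DataFrame,
    panel: Sequence[str],
    per_protocol: bool = False,
) -> pd.Series:
    """Tumour-reactivity score: standardised sum of the 20-gene panel.

    Expression is expected pre-normalised (depth-normalised, log-transformed,
    scaled per protocol upstream).  Standardisation is global by default,
    within protocol with ``per_protocol=True``.
    """
    missing = [g for g in panel if g not in cells.columns]
    if missing:
        raise ValidationError(f"panel gene(s) missing from cell table: {missing}")
    total = cells[list(panel)].sum(axis=1)

    def _scale(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=0)
        if sd == 0:
            raise ValidationError("panel sum has zero variance")
        return (s - s.mean()) / sd

    if per_protocol:
        return total.groupby(cells["protocol"]).transform(_scale).rename("trs")
    return _scale(total).rename("trs")


def match_cells(
    cells: pd.DataFrame,
    rules: Sequence[HLAMatchRule],
    hla: HLAGenotypes,
    use_alpha: bool = False,
) -> pd.Series:
    """0/1 HLA-matching status per cell: the cell's beta (optionally also
    alpha) V-gene pairs with a rule allele the individual carries."""
    status = np.zeros(len(cells), dtype=bool)
    for rule in rules:
        carriers = hla.dosage(rule.hla_allele) >= 1
        carrier_ids = set(carriers.index[carriers])
        in_carrier = cells["individual_id"].isin(carrier_ids).to_numpy()
        hit = (cells["beta_v_gene"].to_numpy() == rule.v_gene) & in_carrier
        if use_alpha:
            for col in ("alpha1_v_gene", "alpha2_v_gene"):
                hit |= (cells[col].to_numpy() == rule.v_gene) & in_carrier
        status |= hit
    return pd.Series(status.astype(int), index=cells.index, name="match_status")


def trs_vs_matching(
    trs: pd.Series,
    match_status: pd.Series,
    protocol: pd.Series,
    stratum: str = "all",
) -> TRSResult:
    """Nested-model F-test of TRS on HLA-matching status given protocol."""
    df = pd.DataFrame({"trs": trs, "status": match_status, "protocol": protocol})
    df = df.dropna()
    n = len(df)
    if df["status"].nunique() < 2:
        return TRSResult(stratum, np.nan, np.nan, n, note="untestable")
    levels = df["protocol"].unique()
    C = np.column_stack(
        [np.ones(n)] + [(df["protocol"] == lv).to_numpy(float) for lv in levels[1:]]
    )
    X = np.column_stack([C, df["status"].to_numpy(float)])
    if n <= X.shape[1]:
        return TRSResult(stratum, np.nan, np.nan, n, note="untestable")
    y = df["trs"].to_numpy(float)
    coef0, *_ = np.linalg.lstsq(C, y, rcond=None)
    rss0 = float(np.sum((y - C @ coef0) ** 2))
    coef1, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ coef1) ** 2))
    dof = n - X.shape[1]
    if rss1 == 0:
        return TRSResult(stratum, float(coef1[-1]), 1.0 if rss0 == rss1 else 0.0,
                         n, note="perfect_fit")
    F = (rss0 - rss1) / (rss1 / dof)
    p = float(stats.f.sf(F, 1, dof))
    return TRSResult(stratum, float(coef1[-1]), p, n)


def trs_matching_analysis(
    cells: pd.DataFrame,
    panel: Sequence[str],
    rules: Sequence[HLAMatchRule],
    hla: HLAGenotypes,
    per_protocol_trs: bool = False,
) -> pd.DataFrame:
    """TRS ~ matching-status model comparison across strata: all cells, each
    subset, singlets only, expanded-clone cells only."""
    cells = cells.reset_index(drop=True)
    trs = compute_trs(cells, panel, per_protocol_trs)
    status = match_cells(cells, rules, hla)
    protocol = cells["protocol"]
    clone_sizes = cells.groupby(CELL_CLONE_KEY, dropna=False)["cell_id"].transform(
        "size"
    )
    strata: dict[str, pd.Series] = {"all": pd.Series(True, index=cells.index)}
    for subset in sorted(cells["subset"].unique()):
        strata[subset] = cells["subset"] == subset
    strata["singlet"] = clone_sizes == 1
    strata["expanded"] = clone_sizes >= 2
    rows = []
    for name, mask in strata.items():
        res = trs_vs_matching(trs[mask], status[mask], protocol[mask], name)
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def trs_clone_size_correlation(trs: pd.Series, clone_sizes: pd.Series
                               ) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected p) of TRS with clone size."""
    df = pd.DataFrame({"trs": trs, "size": clone_sizes}).dropna()
    if len(df) < 3:
        raise ValidationError("need >= 3 cells")
    if df["size"].nunique() < 2 or df["trs"].nunique() < 2:
        return float("nan"), float("nan")
    r, p = stats.spearmanr(df["trs"], df["size"])
    return float(r), float(p)
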