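"""Longitudinal clone tracking and HLA-matched-clone analysis.

Clones (keyed by chain + V-gene + CDR3 amino acids) observed at paired
timepoints are partitioned per individual into *unstable* (pre only), *novel*
(post only) and *persistent* (both).  An *HLA-matched* clone pairs a V-gene
with a classical HLA allele the individual carries (dosage >= 1); the rules
are normally extracted from an association scan as the top classical allele
per significant V-gene.  Per-individual matched proportions are compared
between groups with paired Wilcoxon signed-rank tests (exact tail for small
samples).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import HLAGenotypes, ValidationError
from .phenotypes import CLONE_KEY

__all__ = [
    "HLAMatchRule",
    "classify_clones",
    "resampling_proportions",
    "hla_matched_proportion",
    "matched_proportion_table",
    "paired_wilcoxon",
    "top_allele_rules",
    "group_association_scan",
]

GROUPS = ("unstable", "novel", "persistent")


@dataclasses.dataclass(frozen=True)
class HLAMatchRule:
    """Pairing of a V-gene with a classical HLA allele (2- or 4-digit)."""

    v_gene: str
    hla_allele: str
    source: str = ""


def _clone_sets(df: pd.DataFrame) -> pd.DataFrame:
    return df[CLONE_KEY].drop_duplicates()


def classify_clones(c1: pd.DataFrame, c2: pd.DataFrame) -> pd.DataFrame:
    """Partition the union of pre (C1) and post (C2) clone sets per
    individual into unstable / novel / persistent."""
    merged = _clone_sets(c1).merge(
        _clone_sets(c2), on=CLONE_KEY, how="outer", indicator=True
    )
    merged["group"] = merged["_merge"].map(
        {"left_only": "unstable", "right_only": "novel", "both": "persistent"}
    ).astype(object)
    return merged.drop(columns="_merge")


def resampling_proportions(labels: pd.DataFrame, c4: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each individual's group redetected in the C4 clone set.

    Returns individuals x {unstable, novel, persistent}; groups with no
    clones are NaN.
    """
    c4_keys = _clone_sets(c4).assign(_in_c4=True)
    merged = labels.merge(c4_keys, on=CLONE_KEY, how="left")
    merged["_in_c4"] = merged["_in_c4"].notna()
    out = (
        merged.groupby(["individual_id", "group"])["_in_c4"]
        .mean()
        .unstack()
        .reindex(columns=list(GROUPS))
    )
    return out


def _matched_flags(clones: pd.DataFrame, rules: Sequence[HLAMatchRule],
                   hla: HLAGenotypes) -> np.ndarray:
    flags = np.zeros(len(clones), dtype=bool)
    for rule in rules:
        carriers = hla.dosage(rule.hla_allele) >= 1
        carrier_ids = set(carriers.index[carriers])
        flags |= (
            (clones["v_gene"].to_numpy() == rule.v_gene)
            & clones["individual_id"].isin(carrier_ids).to_numpy()
        )
    return flags


def hla_matched_proportion(
    clones: pd.DataFrame,
    rules: Sequence[HLAMatchRule],
    hla: HLAGenotypes,
    individual: str,
) -> float:
    """Proportion of one individual's (group-restricted, unique) clones that
    are HLA matched; NaN for an empty clone set."""
    mine = _clone_sets(clones[clones["individual_id"] == individual])
    if mine.empty:
        return float("nan")
    return float(_matched_flags(mine, rules, hla).mean())


def matched_proportion_table(
    labels: pd.DataFrame,
    rules: Sequence[HLAMatchRule],
    hla: HLAGenotypes,
    chain: str | None = None,
) -> pd.DataFrame:
    """Per-individual HLA-matched proportion within each clone group."""
    df = labels if chain is None else labels[labels["chain"] == chain]
    df = df.copy()
    df["_matched"] = _matched_flags(df, rules, hla)
    return (
        df.groupby(["individual_id", "group"])["_matched"]
        .mean()
        .unstack()
        .reindex(columns=list(GROUPS))
    )


def paired_wilcoxon(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are discarded; the exact distribution is used for <= 25
    informative untied pairs, the tie-corrected normal approximation above.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    d = x[ok] - y[ok]
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ties = len(np.unique(np.abs(d))) < len(d)
    if len(d) <= 25 and not ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)


def top_allele_rules(
    results: pd.DataFrame,
    v_genes: Sequence[str] | None = None,
    allele_filter=None,
) -> list[HLAMatchRule]:
    """Extract, per V-gene, the top classical HLA allele from an association
    results table (smallest p; ties broken by lexicographic allele name)."""
    df = results.dropna(subset=["p"])
    if v_genes is not None:
        df = df[df["feature"].isin(v_genes)]
    if allele_filter is not None:
        df = df[df["predictor"].map(allele_filter)]
    rules = []
    for v_gene, grp in df.groupby("feature"):
        grp = grp.sort_values(["p", "predictor"], kind="mergesort")
        rules.append(HLAMatchRule(str(v_gene), str(grp["predictor"].iloc[0]),
                                  source="top allele for this V-gene"))
    return rules


def group_association_scan(
    labels: pd.DataFrame,
    group: str,
    chain: str,
    predictors,
    covariates: pd.DataFrame,
    batch: pd.Series,
    individuals=None,
):
    """Re-run the V-gene usage association on one clone group's clones.

    Rebuilds the phenotype (counts -> TMM -> CPM -> batch -> INRT) from the
    group-restricted clone set and delegates to the association scan.
    """
    from .association import scan as assoc_scan
    from .phenotypes import vgene_phenotype_pipeline

    if group not in GROUPS:
        raise ValidationError(f"group must be one of {GROUPS}")
    sub = labels[labels["group"] == group].copy()
    sub["timepoint"] = "C1"
    sub["count"] = 1
    sub["productive"] = True
    ph, _ = vgene_phenotype_pipeline(sub, chain, batch, "C1", individuals)
    return assoc_scan(ph, predictors, covariates)
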