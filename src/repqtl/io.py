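"""Tabular I/O, schema validation and shared domain types.

The package analyses T cell receptor (TCR) repertoires as genetic
quantitative traits.  Everything moves through plain TSV tables:

* clone tables -- one row per observed productive rearrangement
  (AIRR-Rearrangement-style column names are accepted via a column map);
* a genotype dosage matrix (individuals x variants, additive 0-2 dosages)
  plus a variant metadata table;
* an imputed classical-HLA allele dosage table (2- and 4-digit names such
  as ``B*44`` / ``B*44:02``) plus an allele -> residue map per amino-acid
  position;
* covariate, single-cell and survival tables.

Row-level semantics are documented by small dataclasses (:class:`CloneRecord`,
:class:`SurvivalRecord`, ...); the bulk in-memory containers are pandas
DataFrames, which every analysis function accepts and returns.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CloneRecord",
    "GenotypeMatrix",
    "HLAGenotypes",
    "SurvivalRecord",
    "AIRR_COLUMN_MAP",
    "read_clone_table",
    "write_clone_table",
    "validate_clone_frame",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "read_hla_table",
    "write_hla_table",
    "read_residue_map",
    "read_covariates",
    "write_covariates",
    "read_survival",
    "write_survival",
    "read_cell_table",
    "write_cell_table",
    "intersect_individuals",
]

TIMEPOINTS = ("C1", "C2", "C4")
CHAINS = ("alpha", "beta")
#: IMGT nomenclature: TRAV* genes build alpha chains, TRBV* beta chains.
CHAIN_PREFIX = {"alpha": "TRAV", "beta": "TRBV"}
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CLONE_COLUMNS = [
    "individual_id",
    "timepoint",
    "chain",
    "v_gene",
    "cdr3_aa",
    "count",
    "productive",
]

#: AIRR Rearrangement dialect -> canonical column names.
AIRR_COLUMN_MAP = {
    "repertoire_id": "individual_id",
    "v_call": "v_gene",
    "junction_aa": "cdr3_aa",
    "duplicate_count": "count",
    "locus": "chain",
}

_AIRR_LOCUS = {"TRA": "alpha", "TRB": "beta"}


class ValidationError(ValueError):
    """A table violates its schema's invariants."""


# ---------------------------------------------------------------------------
# clone tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CloneRecord:
    """One productive rearrangement observation."""

    individual_id: str
    timepoint: str
    chain: str
    v_gene: str
    cdr3_aa: str
    count: int
    productive: bool = True

    @property
    def key(self) -> tuple[str, str, str]:
        """Clone identity key: (chain, V-gene, CDR3 amino acids)."""
        return (self.chain, self.v_gene, self.cdr3_aa)


def _bad_rows_message(kind: str, idx: Sequence, limit: int = 10) -> str:
    rows = list(idx)[:limit]
    suffix = "" if len(idx) <= limit else f" (+{len(idx) - limit} more)"
    return f"{kind}: rows {rows}{suffix}"


def validate_clone_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clone DataFrame, raising :class:`ValidationError` with the
    offending row labels on any invariant breach."""
    missing = [c for c in CLONE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clone table missing columns: {missing}")
    df = df.copy()
    problems = []
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[~(counts >= 1) | (counts != counts.round())]
    if len(bad):
        problems.append(_bad_rows_message("count must be a positive integer", bad))
    cdr3 = df["cdr3_aa"].astype(str)
    bad = df.index[cdr3.str.len() < 1]
    if len(bad):
        problems.append(_bad_rows_message("empty cdr3_aa", bad))
    bad = df.index[~df["timepoint"].isin(TIMEPOINTS)]
    if len(bad):
        problems.append(_bad_rows_message(f"timepoint not in {TIMEPOINTS}", bad))
    bad = df.index[~df["chain"].isin(CHAINS)]
    if len(bad):
        problems.append(_bad_rows_message(f"chain not in {CHAINS}", bad))
    else:
        expected = df["chain"].map(CHAIN_PREFIX)
        ok = [
            str(v).startswith(p)
            for v, p in zip(df["v_gene"], expected)
        ]
        bad = df.index[~np.asarray(ok)]
        if len(bad):
            problems.append(
                _bad_rows_message("v_gene prefix inconsistent with chain", bad)
            )
    if problems:
        raise ValidationError("invalid clone table: " + "; ".join(problems))
    df["count"] = counts.astype(int)
    df["productive"] = df["productive"].astype(bool)
    return df


def read_clone_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a clone table TSV.

    ``column_map`` maps file column names onto the canonical schema; the
    AIRR Rearrangement dialect (:data:`AIRR_COLUMN_MAP`) is recognised
    automatically when canonical columns are absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    airr = {k: v for k, v in AIRR_COLUMN_MAP.items()
            if k in df.columns and v not in df.columns}
    if airr:
        df = df.rename(columns=airr)
        if "chain" in df.columns:
            df["chain"] = df["chain"].replace(_AIRR_LOCUS)
    if "chain" not in df.columns and "v_gene" in df.columns:
        # infer chain from the IMGT gene-name prefix
        df["chain"] = np.where(
            df["v_gene"].astype(str).str.startswith("TRAV"), "alpha", "beta"
        )
    if "productive" not in df.columns:
        df["productive"] = True
    return validate_clone_frame(df[CLONE_COLUMNS])


def write_clone_table(df: pd.DataFrame, path) -> None:
    validate_clone_frame(df)[CLONE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GenotypeMatrix:
    """Additive dosage matrix (individuals x variants) with variant metadata.

    ``dosage`` holds values in [0, 2]; missing genotypes are NaN.  ``variants``
    is indexed by variant id with columns chrom / pos (1-based) / ref / alt.
    """

    dosage: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = self.dosage.astype(float)
        self.dosage.index.name = "individual_id"
        self.dosage.columns.name = None
        if self.dosage.columns.duplicated().any():
            dups = self.dosage.columns[self.dosage.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate variant ids: {dups[:5]}")
        vals = self.dosage.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 2)
        if np.nansum(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage out of [0, 2]: individual {self.dosage.index[i]!r}, "
                f"variant {self.dosage.columns[j]!r} = {vals[i, j]}"
            )
        self.variants = self.variants.reindex(self.dosage.columns)
        self.variants.index.name = "variant_id"

    @property
    def individuals(self) -> pd.Index:
        return self.dosage.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosage.columns

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    def subset(self, individuals=None, variants=None) -> "GenotypeMatrix":
        d = self.dosage
        if individuals is not None:
            d = d.loc[individuals]
        if variants is not None:
            d = d[list(variants)]
        return GenotypeMatrix(d, self.variants.loc[d.columns])


def read_dosage_matrix(path, variants_path=None) -> GenotypeMatrix:
    """Read a wide dosage TSV (first column ``individual_id``), optionally
    with a variant metadata TSV (columns variant_id/chrom/pos/ref/alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    df = df.set_index("individual_id")
    if variants_path is None:
        cand = Path(str(path) + ".variants.tsv")
        variants_path = cand if cand.exists() else None
    if variants_path is not None:
        meta = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
        meta = meta.set_index("variant_id")
    else:
        meta = pd.DataFrame(
            {"chrom": pd.NA, "pos": pd.NA, "ref": pd.NA, "alt": pd.NA},
            index=pd.Index(df.columns, name="variant_id"),
        )
    return GenotypeMatrix(df, meta)


def write_dosage_matrix(g: GenotypeMatrix, path, variants_path=None) -> None:
    g.dosage.to_csv(path, sep="\t")
    if variants_path is None:
        variants_path = Path(str(path) + ".variants.tsv")
    g.variants.to_csv(variants_path, sep="\t")


# ---------------------------------------------------------------------------
# HLA
# ---------------------------------------------------------------------------


def hla_gene(allele: str) -> str:
    """Gene name of a classical allele: ``B*44:02`` -> ``B``."""
    return allele.split("*")[0]


def hla_parent(allele: str) -> str:
    """2-digit parent of a 4-digit allele: ``B*44:02`` -> ``B*44``."""
    return allele.split(":")[0]


def is_four_digit(allele: str) -> bool:
    return ":" in allele


@dataclasses.dataclass
class HLAGenotypes:
    """Classical HLA allele dosages plus a per-position residue map.

    ``allele_dosage``: individuals x allele names (2- and 4-digit), values in
    {0, 1, 2}.  ``residue_map``: long table with columns
    gene / exon / position / allele (4-digit) / residue.
    """

    allele_dosage: pd.DataFrame
    residue_map: pd.DataFrame

    def __post_init__(self) -> None:
        ad = self.allele_dosage.astype(float)
        vals = ad.to_numpy()
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("HLA allele dosages must be in {0, 1, 2}")
        four = [a for a in ad.columns if is_four_digit(a)]
        two = [a for a in ad.columns if not is_four_digit(a)]
        # derive 2-digit columns from 4-digit children when absent
        for a in four:
            p = hla_parent(a)
            if p not in ad.columns and p not in two:
                kids = [c for c in four if hla_parent(c) == p]
                ad[p] = ad[kids].sum(axis=1)
                two.append(p)
        ad.index.name = "individual_id"
        ad.columns.name = None
        genes = sorted({hla_gene(a) for a in ad.columns})
        for gene in genes:
            cols = [a for a in two if hla_gene(a) == gene]
            sums = ad[cols].sum(axis=1)
            bad = sums.index[sums != 2]
            if len(bad):
                raise ValidationError(
                    f"2-digit HLA-{gene} dosages do not sum to 2 for "
                    f"individual(s) {list(bad[:5])}"
                )
        self.allele_dosage = ad

    @property
    def individuals(self) -> pd.Index:
        return self.allele_dosage.index

    def dosage(self, allele: str) -> pd.Series:
        """Dosage of a 2- or 4-digit allele (0/1/2 copies per individual)."""
        if allele in self.allele_dosage.columns:
            return self.allele_dosage[allele]
        kids = [
            a for a in self.allele_dosage.columns
            if is_four_digit(a) and hla_parent(a) == allele
        ]
        if not kids:
            raise KeyError(f"unknown HLA allele {allele!r}")
        return self.allele_dosage[kids].sum(axis=1).rename(allele)

    def positions(self) -> pd.DataFrame:
        """Distinct (gene, exon, position) rows of the residue map."""
        return (
            self.residue_map[["gene", "exon", "position"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def residue_dosages(self, gene: str, exon, position) -> pd.DataFrame:
        """Per-individual dosage of each residue at one amino-acid position.

        Dosage of residue r = sum of the individual's 4-digit allele dosages
        over alleles carrying r at that position; rows sum to 2 when the map
        covers every allele present.
        """
        rm = self.residue_map
        sel = rm[
            (rm["gene"] == gene) & (rm["exon"] == exon) & (rm["position"] == position)
        ]
        if sel.empty:
            raise KeyError(f"no residue map for {gene} exon {exon} pos {position}")
        out = {}
        for residue, grp in sel.groupby("residue"):
            alleles = [a for a in grp["allele"] if a in self.allele_dosage.columns]
            out[residue] = self.allele_dosage[alleles].sum(axis=1)
        return pd.DataFrame(out)


def read_hla_table(path, residue_map_path=None) -> HLAGenotypes:
    ad = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    ad = ad.set_index("individual_id")
    if residue_map_path is not None:
        rm = read_residue_map(residue_map_path)
    else:
        rm = pd.DataFrame(columns=["gene", "exon", "position", "allele", "residue"])
    return HLAGenotypes(ad, rm)


def read_residue_map(path) -> pd.DataFrame:
    rm = pd.read_csv(path, sep="\t")
    need = {"gene", "exon", "position", "allele", "residue"}
    if not need.issubset(rm.columns):
        raise ValidationError(f"residue map needs columns {sorted(need)}")
    return rm


def write_hla_table(hla: HLAGenotypes, path, residue_map_path=None) -> None:
    hla.allele_dosage.to_csv(path, sep="\t")
    if residue_map_path is not None:
        hla.residue_map.to_csv(residue_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# covariates / survival / cells
# ---------------------------------------------------------------------------

COVARIATE_COLUMNS = ["age", "sex", "cancer_type", "batch"]


def read_covariates(path, required: Iterable[str] = COVARIATE_COLUMNS) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    df = df.set_index("individual_id")
    if df.index.duplicated().any():
        raise ValidationError("duplicate individual_id in covariate table")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"covariate table missing columns: {missing}")
    cols = [c for c in required if c in df.columns]
    if df[cols].isna().any().any():
        bad = df.index[df[cols].isna().any(axis=1)]
        raise ValidationError(
            f"missing values in modeled covariates for {list(bad[:5])}"
        )
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    df.rename_axis("individual_id").to_csv(path, sep="\t")


@dataclasses.dataclass(frozen=True)
class SurvivalRecord:
    """One individual's overall-survival observation (time in days)."""

    individual_id: str
    os_time: float
    event: bool
    group: str | None = None


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if not {"individual_id", "os_time", "event"}.issubset(df.columns):
        raise ValidationError("survival table needs individual_id/os_time/event")
    if (df["os_time"] < 0).any():
        raise ValidationError("negative os_time")
    df["event"] = df["event"].astype(bool)
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


CELL_BASE_COLUMNS = [
    "cell_id",
    "individual_id",
    "subset",
    "protocol",
    "alpha1_v_gene",
    "alpha1_cdr3",
    "alpha2_v_gene",
    "alpha2_cdr3",
    "beta_v_gene",
    "beta_cdr3",
    "n_alpha",
    "n_beta",
    "total_transcripts",
    "mito_fraction",
]


def read_cell_table(path) -> pd.DataFrame:
    """Read a single-cell table; columns beyond the base schema are treated
    as (pre-normalised) gene-expression values."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    missing = [c for c in CELL_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cell table missing columns: {missing}")
    mito = df["mito_fraction"]
    if ((mito < 0) | (mito > 1)).any():
        raise ValidationError("mito_fraction outside [0, 1]")
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def intersect_individuals(**named: Iterable) -> list:
    """Intersect individual-id sets across tables, warning on differences."""
    sets = {name: set(ids) for name, ids in named.items()}
    common = set.intersection(*sets.values())
    for name, ids in sets.items():
        extra = ids - common
        if extra:
            warnings.warn(
                f"{len(extra)} individual(s) only in {name}; analysis set has "
                f"{len(common)}",
                stacklevel=2,
            )
    return sorted(common)
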