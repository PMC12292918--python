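"""Synthetic cohort generator.

Emulates a checkpoint-blockade study cohort end to end: germline genotypes,
classical HLA haplotypes, paired pre-/post-treatment (and optional C4) CD8+
TCR repertoires, covariates, a single-cell table with a 20-gene
tumour-reactivity panel, and overall-survival times.

The statistical structure is the one the downstream analysis assumes:

* V-gene clone counts are multinomial with log-linear weights
  ``base_g + sum(cis beta * SNP dosage) + sum(trans beta * HLA dosage) +
  batch offset + N(0, usage_noise_sd)``;
* CDR3s are random 20-letter amino-acid strings (chain-typical prefix and
  suffix, lengths 10-20 with most mass on 12-18); planted 7-mer motifs are
  inserted into clones of HLA-carrier individuals at a per-individual rate
  ``motif_base_rate * exp(beta * dosage + noise)``;
* clone persistence from C1 to C2 is Bernoulli per unique clone, with a
  multiplier for HLA-matched clones; C4 redetection is Bernoulli per clone
  group;
* HLA-matched cells carry a mean tumour-reactivity-panel shift, and carriers
  of HLA-matched clones have an exponential survival-hazard multiplier.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AA_ALPHABET,
    CLONE_COLUMNS,
    GenotypeMatrix,
    HLAGenotypes,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_survival",
    "make_ld_proxy",
    "DEFAULT_HLA_FREQS",
    "DEFAULT_RESIDUE_TABLE",
    "DEFAULT_TRS_PANEL",
]

# Allele catalogue (4-digit) with haplotype frequencies; two class I genes are
# enough to exercise 2-/4-digit resolution, the residue map and the omnibus
# test.  Frequencies are loosely European-ancestry-like and sum to 1 per gene.
DEFAULT_HLA_FREQS: dict[str, dict[str, float]] = {
    "A": {
        "A*01:01": 0.16,
        "A*02:01": 0.27,
        "A*02:05": 0.04,
        "A*03:01": 0.13,
        "A*11:01": 0.06,
        "A*24:02": 0.10,
        "A*26:01": 0.06,
        "A*68:01": 0.18,
    },
    "B": {
        "B*07:02": 0.14,
        "B*08:01": 0.12,
        "B*15:01": 0.07,
        "B*27:05": 0.04,
        "B*35:01": 0.10,
        "B*40:01": 0.08,
        "B*44:02": 0.24,
        "B*44:03": 0.11,
        "B*57:01": 0.10,
    },
}

# Hand-written allele -> residue map.  Positions are chosen so that the
# omnibus test sees both a multi-residue (k = 3) and a biallelic (k = 2)
# position per gene.
_RESIDUE_ROWS = [
    # gene, exon, position, allele, residue
    ("A", "exon2", 74, "A*01:01", "D"),
    ("A", "exon2", 74, "A*02:01", "H"),
    ("A", "exon2", 74, "A*02:05", "H"),
    ("A", "exon2", 74, "A*03:01", "D"),
    ("A", "exon2", 74, "A*11:01", "D"),
    ("A", "exon2", 74, "A*24:02", "N"),
    ("A", "exon2", 74, "A*26:01", "D"),
    ("A", "exon2", 74, "A*68:01", "N"),
    ("A", "exon2", 95, "A*01:01", "I"),
    ("A", "exon2", 95, "A*02:01", "V"),
    ("A", "exon2", 95, "A*02:05", "V"),
    ("A", "exon2", 95, "A*03:01", "I"),
    ("A", "exon2", 95, "A*11:01", "I"),
    ("A", "exon2", 95, "A*24:02", "I"),
    ("A", "exon2", 95, "A*26:01", "V"),
    ("A", "exon2", 95, "A*68:01", "I"),
    ("B", "exon2", 45, "B*07:02", "M"),
    ("B", "exon2", 45, "B*08:01", "K"),
    ("B", "exon2", 45, "B*15:01", "M"),
    ("B", "exon2", 45, "B*27:05", "E"),
    ("B", "exon2", 45, "B*35:01", "K"),
    ("B", "exon2", 45, "B*40:01", "K"),
    ("B", "exon2", 45, "B*44:02", "E"),
    ("B", "exon2", 45, "B*44:03", "E"),
    ("B", "exon2", 45, "B*57:01", "M"),
    ("B", "exon2", 116, "B*07:02", "Y"),
    ("B", "exon2", 116, "B*08:01", "Y"),
    ("B", "exon2", 116, "B*15:01", "Y"),
    ("B", "exon2", 116, "B*27:05", "Y"),
    ("B", "exon2", 116, "B*35:01", "Y"),
    ("B", "exon2", 116, "B*40:01", "Y"),
    ("B", "exon2", 116, "B*44:02", "Y"),
    ("B", "exon2", 116, "B*44:03", "Y"),
    ("B", "exon2", 116, "B*57:01", "S"),
]
DEFAULT_RESIDUE_TABLE = pd.DataFrame(
    _RESIDUE_ROWS, columns=["gene", "exon", "position", "allele", "residue"]
)

#: 20-gene tumour-reactivity panel shipped with the generator (exhaustion /
#: tissue-residency / tumour-reactivity markers commonly used for CD8 scoring).
DEFAULT_TRS_PANEL = (
    "ENTPD1", "ITGAE", "PDCD1", "CTLA4", "HAVCR2", "LAG3", "TIGIT", "TOX",
    "CXCL13", "TNFRSF9", "TNFRSF18", "GZMB", "PRF1", "IFNG", "FASLG", "CD27",
    "ICOS", "BATF", "RBPJ", "KIR2DL4",
)

_CDR3_PREFIX = {"alpha": "CAV", "beta": "CASS"}
_CDR3_SUFFIX = {"alpha": "KLF", "beta": "EQYF"}
_CDR3_LENGTHS = np.arange(10, 21)
# most mass on 12-18, as in real CDR3 length distributions
_CDR3_LENGTH_W = np.array([1, 2, 6, 8, 10, 10, 10, 8, 6, 2, 1], float)
_CDR3_LENGTH_P = _CDR3_LENGTH_W / _CDR3_LENGTH_W.sum()


@dataclasses.dataclass
class SimConfig:
    """Study conditions for :func:`simulate_cohort`.

    Effect tuples: ``cis_effects`` = (variant_id, v_gene, beta) on the
    multinomial log-weight scale; ``trans_effects`` = (hla_allele, v_gene,
    beta); ``kmer_effects`` = (hla_allele, 7-residue motif, beta).
    ``hla_match_rules`` (v_gene, allele) pairs define which clones count as
    HLA matched for persistence, single-cell TRS shifts and survival; they
    default to the pairs in ``trans_effects``.
    """

    n_individuals: int = 250
    n_variants: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_vgenes_alpha: int = 42
    n_vgenes_beta: int = 47
    clones_per_sample: int = 2000
    clone_count_geom_p: float = 0.35
    cis_effects: Sequence[tuple[str, str, float]] = ()
    trans_effects: Sequence[tuple[str, str, float]] = ()
    kmer_effects: Sequence[tuple[str, str, float]] = ()
    hla_match_rules: Sequence[tuple[str, str]] | None = None
    persistence_baseline: float = 0.10
    persistence_hla_multiplier: float = 0.5
    c4_redetect: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"unstable": 0.0664, "novel": 0.0793,
                                 "persistent": 0.651}
    )
    timepoints: tuple[str, ...] = ("C1", "C2", "C4")
    usage_noise_sd: float = 1.0
    batch_effect_sd: float = 0.25
    n_batches: int = 2
    motif_base_rate: float = 0.03
    missing_rate: float = 0.0
    maf_overrides: Mapping[str, float] = dataclasses.field(default_factory=dict)
    hla_freqs: Mapping[str, Mapping[str, float]] | None = None
    residue_table: pd.DataFrame | None = None
    cancer_type_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"melanoma": 0.924, "renal": 0.068,
                                 "colorectal": 0.008}
    )
    n_cells: int = 5000
    n_sc_individuals: int = 59
    trs_shift: float = 0.3
    trs_panel: tuple[str, ...] = DEFAULT_TRS_PANEL
    cell_qc_fail_rate: float = 0.02
    subset_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"CD8_TEM": 0.35, "CD8_TEMRA": 0.25,
                                 "CD8_naive": 0.25, "CD4": 0.15}
    )
    survival_hazard_ratio: float = 0.5
    survival_scale_days: float = 365.0
    censor_tmax: float = 1095.0
    individual_ids: Sequence[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ValidationError("n_individuals must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie in (0, 0.5]")
        for _, motif, _ in self.kmer_effects:
            if len(motif) != 7 or any(c not in AA_ALPHABET for c in motif):
                raise ValidationError(
                    f"planted motif {motif!r} must be 7 residues over the "
                    "20-letter alphabet"
                )
        for eff in (*self.cis_effects, *self.trans_effects, *self.kmer_effects):
            if not math.isfinite(eff[2]):
                raise ValidationError(f"non-finite effect size in {eff}")
        for p in (self.persistence_baseline, self.persistence_hla_multiplier
                  * self.persistence_baseline, *self.c4_redetect.values()):
            if not 0 <= p <= 1:
                raise ValidationError("persistence probabilities must be in [0, 1]")
        if self.survival_hazard_ratio <= 0:
            raise ValidationError("survival_hazard_ratio must be > 0")
        if self.individual_ids is not None:
            ids = list(self.individual_ids)
            if len(ids) != len(set(ids)):
                raise ValidationError("duplicate individual identifiers")
            if len(ids) != self.n_individuals:
                raise ValidationError("individual_ids length != n_individuals")
        if len(self.trs_panel) != 20:
            raise ValidationError("trs_panel must name exactly 20 genes")

    @property
    def match_rules(self) -> list[tuple[str, str]]:
        if self.hla_match_rules is not None:
            return list(self.hla_match_rules)
        return [(vg, allele) for allele, vg, _ in self.trans_effects]


@dataclasses.dataclass
class SyntheticCohort:
    """Bundle of all simulated tables plus the generating truth."""

    genotypes: GenotypeMatrix
    hla: HLAGenotypes
    clones: pd.DataFrame
    covariates: pd.DataFrame
    cells: pd.DataFrame
    survival: pd.DataFrame
    truth: SimConfig


# ---------------------------------------------------------------------------
# low-level samplers
# ---------------------------------------------------------------------------

_LETTER_CODES = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)


def _random_cdr3s(rng: np.random.Generator, n: int, chain: str) -> np.ndarray:
    """n random CDR3 amino-acid strings for one chain (vectorised)."""
    pre = np.frombuffer(_CDR3_PREFIX[chain].encode(), dtype=np.uint8)
    suf = np.frombuffer(_CDR3_SUFFIX[chain].encode(), dtype=np.uint8)
    lengths = rng.choice(_CDR3_LENGTHS, size=n, p=_CDR3_LENGTH_P)
    raw = _LETTER_CODES[rng.integers(0, 20, size=(n, int(_CDR3_LENGTHS.max())))]
    out = np.empty(n, dtype=object)
    for L in np.unique(lengths):
        idx = np.nonzero(lengths == L)[0]
        block = raw[idx, :L].copy()
        block[:, : len(pre)] = pre
        block[:, L - len(suf):] = suf
        strings = np.ascontiguousarray(block).view(f"S{L}").ravel().astype(str)
        out[idx] = strings
    return out


def _sample_hla(rng, ids, freqs) -> pd.DataFrame:
    cols = {}
    for gene, table in freqs.items():
        alleles = list(table)
        p = np.asarray([table[a] for a in alleles], float)
        p = p / p.sum()
        hap = rng.choice(len(alleles), size=(len(ids), 2), p=p)
        dosage = np.zeros((len(ids), len(alleles)))
        for c in range(2):
            np.add.at(dosage, (np.arange(len(ids)), hap[:, c]), 1.0)
        for j, a in enumerate(alleles):
            cols[a] = dosage[:, j]
    return pd.DataFrame(cols, index=ids)


def _vgene_names(chain: str, n: int) -> list[str]:
    prefix = {"alpha": "TRAV", "beta": "TRBV"}[chain]
    return [f"{prefix}{i + 1}" for i in range(n)]


def _matched_mask(clones: pd.DataFrame, rules, hla: HLAGenotypes) -> np.ndarray:
    """HLA-matched flag per clone row: some rule's V-gene equals the clone's
    and the clone's individual carries >= 1 copy of that rule's allele."""
    if not rules:
        return np.zeros(len(clones), dtype=bool)
    mask = np.zeros(len(clones), dtype=bool)
    for v_gene, allele in rules:
        carriers = hla.dosage(allele) >= 1
        carrier_ids = set(carriers.index[carriers])
        mask |= (
            (clones["v_gene"].to_numpy() == v_gene)
            & clones["individual_id"].isin(carrier_ids).to_numpy()
        )
    return mask


def make_ld_proxy(
    g: GenotypeMatrix, variant: str, proxy_id: str, flip_prob: float, seed: int
) -> GenotypeMatrix:
    """Append a near-perfect LD proxy of ``variant``: each of the two allele
    copies is resampled from the population frequency with ``flip_prob``."""
    rng = np.random.default_rng(seed)
    d = g.dosage[variant].to_numpy()
    maf = np.nanmean(d) / 2
    n = len(d)
    keep = rng.random((n, 2)) >= flip_prob
    hap = np.repeat((d / 2)[:, None], 2, axis=1)  # allele-copy expectation
    orig = (rng.random((n, 2)) < hap).astype(float)
    # reconstruct haplotypes consistent with the dosage where possible
    orig[d == 2] = 1.0
    orig[d == 0] = 0.0
    het = d == 1
    orig[het, 0], orig[het, 1] = 1.0, 0.0
    rand = (rng.random((n, 2)) < maf).astype(float)
    proxy = np.where(keep, orig, rand).sum(axis=1)
    dosage = g.dosage.copy()
    dosage[proxy_id] = proxy
    meta = g.variants.copy()
    meta.loc[proxy_id] = meta.loc[variant]
    return GenotypeMatrix(dosage, meta)


# ---------------------------------------------------------------------------
# repertoire generation
# ---------------------------------------------------------------------------


def _clone_frame(rng, ids, chain, counts_matrix, vgenes, geom_p) -> pd.DataFrame:
    """Expand per-individual V-gene multinomial counts into a clone table.

    Random CDR3s over a 20-letter alphabet make clone-key collisions
    vanishingly rare, so no dedup pass is needed here (all downstream
    counting is unique-clone based anyway).
    """
    n_ind, n_genes = counts_matrix.shape
    per_ind = counts_matrix.sum(axis=1)
    individual = np.repeat(np.asarray(ids, dtype=object), per_ind)
    v_idx = np.repeat(
        np.tile(np.arange(n_genes), n_ind), counts_matrix.ravel()
    )
    total = len(individual)
    return pd.DataFrame(
        {
            "individual_id": individual,
            "chain": chain,
            "v_gene": np.asarray(vgenes, dtype=object)[v_idx],
            "cdr3_aa": _random_cdr3s(rng, total, chain),
            "count": rng.geometric(geom_p, size=total),
        }
    )


def _plant_motifs(rng, clones: pd.DataFrame, config: SimConfig,
                  hla: HLAGenotypes, motif_noise: dict) -> pd.DataFrame:
    """Overwrite a 7-residue window with each planted motif in beta-chain
    clones of carrier individuals, at rate base * exp(beta * dosage + noise)."""
    if not config.kmer_effects:
        return clones
    cdr3 = clones["cdr3_aa"].to_numpy(dtype=object)
    lens = clones["cdr3_aa"].str.len().to_numpy()
    eligible = (clones["chain"].to_numpy() == "beta") & (lens >= 12) & (lens <= 18)
    ind_codes, ind_ids = pd.factorize(clones["individual_id"])
    for allele, motif, beta in config.kmer_effects:
        dosage = hla.dosage(allele).reindex(ind_ids).to_numpy()
        eps = motif_noise[(allele, motif)]
        rate = np.clip(
            config.motif_base_rate * np.exp(beta * dosage + eps), 0.0, 0.5
        )
        u = rng.random(len(clones))
        hit = eligible & (u < rate[ind_codes])
        idx = np.nonzero(hit)[0]
        starts = rng.integers(0, lens[idx] - 6)
        for i, s in zip(idx, starts):
            seq = cdr3[i]
            cdr3[i] = seq[:s] + motif + seq[s + 7:]
    out = clones.copy()
    out["cdr3_aa"] = cdr3
    return out


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic study; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = (
        list(config.individual_ids)
        if config.individual_ids is not None
        else [f"P{i:04d}" for i in range(n)]
    )

    # --- genotypes -------------------------------------------------------
    mafs = rng.uniform(*config.maf_range, size=config.n_variants)
    var_ids = [f"var{j:05d}" for j in range(config.n_variants)]
    for vid, maf in config.maf_overrides.items():
        mafs[var_ids.index(vid)] = maf
    dosage = rng.binomial(2, mafs, size=(n, config.n_variants)).astype(float)
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = np.nan
    chroms = np.resize(np.arange(1, 23), config.n_variants)
    variants = pd.DataFrame(
        {
            "chrom": chroms.astype(str),
            "pos": np.arange(1, config.n_variants + 1) * 1000,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(var_ids, name="variant_id"),
    )
    genotypes = GenotypeMatrix(pd.DataFrame(dosage, index=ids, columns=var_ids),
                               variants)

    # --- HLA -------------------------------------------------------------
    freqs = config.hla_freqs or DEFAULT_HLA_FREQS
    residues = (config.residue_table if config.residue_table is not None
                else DEFAULT_RESIDUE_TABLE)
    hla = HLAGenotypes(_sample_hla(rng, ids, freqs), residues)

    # --- covariates ------------------------------------------------------
    cancers = list(config.cancer_type_probs)
    cancer_p = np.asarray(list(config.cancer_type_probs.values()), float)
    covariates = pd.DataFrame(
        {
            "age": np.clip(rng.normal(65, 10, n).round(), 30, 90),
            "sex": rng.choice(["F", "M"], size=n),
            "cancer_type": rng.choice(cancers, size=n, p=cancer_p / cancer_p.sum()),
            "batch": [f"B{b + 1}" for b in rng.integers(0, config.n_batches, n)],
        },
        index=pd.Index(ids, name="individual_id"),
    )
    batch_idx = covariates["batch"].str.slice(1).astype(int).to_numpy() - 1

    # --- V-gene propensities (stable per individual across timepoints) ----
    weights = {}
    for chain, n_genes in (("alpha", config.n_vgenes_alpha),
                           ("beta", config.n_vgenes_beta)):
        genes = _vgene_names(chain, n_genes)
        base = rng.normal(0.0, 0.5, n_genes)
        batch_off = rng.normal(0.0, config.batch_effect_sd,
                               (config.n_batches, n_genes))
        W = base + rng.normal(0.0, config.usage_noise_sd, (n, n_genes))
        W += batch_off[batch_idx]
        for vid, v_gene, beta in config.cis_effects:
            if v_gene in genes:
                d = np.nan_to_num(genotypes.dosage[vid].to_numpy(),
                                  nan=float(np.nanmean(dosage)))
                W[:, genes.index(v_gene)] += beta * d
        for allele, v_gene, beta in config.trans_effects:
            if v_gene in genes:
                W[:, genes.index(v_gene)] += beta * hla.dosage(allele).to_numpy()
        weights[chain] = (genes, W)

    motif_noise = {
        (allele, motif): rng.normal(0.0, config.usage_noise_sd, n)
        for allele, motif, _ in config.kmer_effects
    }

    def sample_pool(chain: str, sizes: np.ndarray) -> pd.DataFrame:
        genes, W = weights[chain]
        p = np.exp(W - W.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        counts = np.vstack([
            rng.multinomial(int(sizes[i]), p[i]) for i in range(n)
        ])
        pool = _clone_frame(rng, ids, chain, counts, genes,
                            config.clone_count_geom_p)
        return _plant_motifs(rng, pool, config, hla, motif_noise)

    full = np.full(n, config.clones_per_sample)
    rules = config.match_rules
    frames = []
    for chain in ("alpha", "beta"):
        c1 = sample_pool(chain, full)
        c1["timepoint"] = "C1"
        frames.append(c1)
        if "C2" not in config.timepoints:
            continue
        # persistence: Bernoulli per unique clone, HLA-matched multiplier
        matched = _matched_mask(c1, rules, hla)
        p_persist = np.where(
            matched,
            min(1.0, config.persistence_baseline * config.persistence_hla_multiplier),
            config.persistence_baseline,
        )
        persist_draw = rng.random(len(c1)) < p_persist
        persisted = c1[persist_draw].copy()
        n_pers = persisted.groupby("individual_id").size().reindex(ids, fill_value=0)
        novel_sizes = np.maximum(full - n_pers.to_numpy(), 0)
        novel = sample_pool(chain, novel_sizes)
        c2 = pd.concat([persisted, novel], ignore_index=True)
        c2["timepoint"] = "C2"
        frames.append(c2)
        if "C4" not in config.timepoints:
            continue
        # C4 redetection per clone group (emulates the later-cycle resampling);
        # groups are known from the persistence draw, no join needed
        key = ["individual_id", "chain", "v_gene", "cdr3_aa"]
        pool = pd.concat(
            [c1[key], novel[key]], ignore_index=True
        )
        group = np.concatenate([
            np.where(persist_draw, "persistent", "unstable"),
            np.full(len(novel), "novel"),
        ])
        q = pd.Series(group).map(config.c4_redetect).to_numpy(float)
        c4 = pool.loc[rng.random(len(pool)) < q].copy()
        c4["count"] = 1
        c4["timepoint"] = "C4"
        frames.append(c4)

    clones = pd.concat(frames, ignore_index=True)
    clones["productive"] = True
    clones = clones[CLONE_COLUMNS]

    # --- single cells ------------------------------------------------------
    cells = _simulate_cells(rng, config, ids, clones, hla, covariates)

    # --- survival ----------------------------------------------------------
    carrier_tp = [t for t in ("C1", "C2") if t in config.timepoints]
    at_tp = clones[clones["timepoint"].isin(carrier_tp)]
    carrier_ids = set(
        at_tp.loc[_matched_mask(at_tp, rules, hla), "individual_id"]
    )
    carrier = pd.Series([i in carrier_ids for i in ids], index=ids, name="carrier")
    survival = simulate_survival(
        carrier,
        config.survival_hazard_ratio,
        seed=int(rng.integers(0, 2**31 - 1)),
        scale_days=config.survival_scale_days,
        censor_tmax=config.censor_tmax,
    )

    return SyntheticCohort(genotypes, hla, clones, covariates, cells, survival,
                           config)


def _simulate_cells(rng, config: SimConfig, ids, clones, hla, covariates
                    ) -> pd.DataFrame:
    if config.n_cells <= 0:
        return pd.DataFrame(columns=["cell_id", "individual_id"])
    sc_ids = list(ids[: min(config.n_sc_individuals, len(ids))])
    beta = clones[(clones["timepoint"] == "C1") & (clones["chain"] == "beta")
                  & (clones["individual_id"].isin(sc_ids))]
    alpha = clones[(clones["timepoint"] == "C1") & (clones["chain"] == "alpha")
                   & (clones["individual_id"].isin(sc_ids))]
    rules = config.match_rules

    # allocate cells across individuals, then sample each cell's beta clone
    # weighted by bulk clone count (so some clones expand, others stay singlets)
    alloc = rng.multinomial(config.n_cells, np.full(len(sc_ids), 1 / len(sc_ids)))
    rows = []
    for ind, n_cells_i in zip(sc_ids, alloc):
        if n_cells_i == 0:
            continue
        b = beta[beta["individual_id"] == ind]
        a = alpha[alpha["individual_id"] == ind]
        if b.empty or a.empty:
            continue
        w = b["count"].to_numpy(float)
        pick = rng.choice(len(b), size=n_cells_i, p=w / w.sum())
        # a clone (same TRA+TRB CDR3) keeps one alpha partner across its cells
        partners = rng.integers(0, len(a), size=len(b))
        second = rng.random(len(b)) < 0.10  # ~10 % of clones carry two alphas
        partners2 = rng.integers(0, len(a), size=len(b))
        for c in pick:
            rows.append((
                ind,
                b["v_gene"].iat[c], b["cdr3_aa"].iat[c],
                a["v_gene"].iat[partners[c]], a["cdr3_aa"].iat[partners[c]],
                a["v_gene"].iat[partners2[c]] if second[c] else "",
                a["cdr3_aa"].iat[partners2[c]] if second[c] else "",
            ))
    cells = pd.DataFrame(rows, columns=[
        "individual_id", "beta_v_gene", "beta_cdr3",
        "alpha1_v_gene", "alpha1_cdr3", "alpha2_v_gene", "alpha2_cdr3",
    ])
    m = len(cells)
    cells.insert(0, "cell_id", [f"cell{i:06d}" for i in range(m)])
    subsets = list(config.subset_probs)
    sp = np.asarray(list(config.subset_probs.values()), float)
    cells["subset"] = rng.choice(subsets, size=m, p=sp / sp.sum())
    # protocol is an individual-level technical variable (two platforms)
    proto_of = {i: f"proto{1 + (k % 2)}" for k, i in enumerate(sc_ids)}
    cells["protocol"] = cells["individual_id"].map(proto_of)
    cells["n_alpha"] = np.where(cells["alpha2_cdr3"] == "", 1, 2)
    cells["n_beta"] = 1
    # a small slice of cells violates QC rules on purpose
    fail = rng.random(m) < config.cell_qc_fail_rate
    transcripts = rng.poisson(3000, m)
    transcripts[fail] = rng.integers(50, 299, int(fail.sum()))
    mito = rng.beta(2, 38, m)
    mito[fail & (rng.random(m) < 0.5)] = rng.uniform(0.21, 0.6)
    cells["total_transcripts"] = transcripts
    cells["mito_fraction"] = np.round(mito, 5)
    multi_beta = rng.random(m) < 0.01
    cells.loc[multi_beta, "n_beta"] = 2

    # matched status via the clone's beta chain
    tmp = cells.rename(columns={"beta_v_gene": "v_gene"})
    matched = _matched_mask(tmp.assign(chain="beta"), rules, hla)

    # tumour-reactivity panel: per-gene baseline + protocol offset + noise,
    # with the planted matched-cell shift split evenly over the 20 genes
    panel = list(config.trs_panel)
    gene_sd = 0.8
    mu = rng.uniform(2.0, 4.0, len(panel))
    proto_levels = sorted(set(proto_of.values()))
    proto_off = rng.normal(0.0, 0.1, (len(proto_levels), len(panel)))
    proto_idx = cells["protocol"].map({p: i for i, p in enumerate(proto_levels)})
    sigma_sum = gene_sd * math.sqrt(len(panel))
    delta = config.trs_shift * sigma_sum / len(panel)
    expr = (
        mu
        + proto_off[proto_idx.to_numpy()]
        + rng.normal(0.0, gene_sd, (m, len(panel)))
        + delta * matched[:, None]
    )
    expr = np.clip(expr, 0.0, None)
    for j, g in enumerate(panel):
        cells[g] = np.round(expr[:, j], 6)
    return cells


def simulate_survival(
    carrier_status: pd.Series,
    hazard_ratio: float,
    seed: int,
    scale_days: float = 365.0,
    censor_tmax: float = 1095.0,
) -> pd.DataFrame:
    """Exponential survival times with a hazard multiplier for carriers and
    independent uniform right-censoring on [0, censor_tmax]."""
    if len(carrier_status) == 0:
        raise ValidationError("empty cohort")
    if hazard_ratio <= 0:
        raise ValidationError("hazard_ratio must be > 0")
    if censor_tmax <= 0:
        raise ValidationError("censoring window must have positive length")
    rng = np.random.default_rng(seed)
    carrier = carrier_status.astype(bool).to_numpy()
    hazard = (1.0 / scale_days) * np.where(carrier, hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, censor_tmax, len(carrier))
    return pd.DataFrame(
        {
            "individual_id": carrier_status.index,
            "os_time": np.minimum(event_time, censor_time).round(2),
            "event": event_time <= censor_time,
            "group": np.where(carrier, "carrier", "non-carrier"),
        }
    )
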