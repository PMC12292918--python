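"""Phenotype construction: unique-clone counting, 7-mer windows, TMM,
batch correction, INRT and TCR PCs against independent oracles."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri
from scipy.stats import rankdata, skew

from repqtl.io import ValidationError
from repqtl.phenotypes import (
    PhenotypeMatrix,
    count_kmers,
    count_vgene_usage,
    inrt,
    normalize_counts,
    remove_batch,
    tcr_pcs,
    tmm_factors,
)


# ---------------------------------------------------------------------------
# unique-clone counting
# ---------------------------------------------------------------------------


def test_vgene_usage_counts_unique_clones(clone_frame):
    pm = count_vgene_usage(clone_frame, "beta", "C1")
    # I1: {TRBV28 x CASSA, TRBV28 x CASSB, TRBV19 x CASSC}
    assert pm.values.loc["I1", "TRBV28"] == 2
    assert pm.values.loc["I1", "TRBV19"] == 1
    # I2 has duplicate rows of (TRBV19, CASSC) with counts 4 and 6 -> 1 clone
    assert pm.values.loc["I2", "TRBV19"] == 1
    assert pm.stage == "raw_counts"


def test_vgene_usage_ignores_nonproductive_and_other_timepoints(clone_frame):
    df = clone_frame.copy()
    df.loc[0, "productive"] = False
    df.loc[1, "timepoint"] = "C2"
    pm = count_vgene_usage(df, "beta", "C1")
    assert pm.values.loc["I1", "TRBV28"] == 0  # both TRBV28 clones excluded


def test_vgene_usage_matches_set_oracle(small_cohort):
    clones = small_cohort.clones
    pm = count_vgene_usage(clones, "beta", "C1")
    sub = clones[
        (clones["chain"] == "beta") & (clones["timepoint"] == "C1")
        & clones["productive"]
    ]
    for ind in pm.values.index[:10]:
        mine = sub[sub["individual_id"] == ind]
        for vg in pm.values.columns:
            oracle = len({
                (r.chain, r.v_gene, r.cdr3_aa)
                for r in mine.itertuples() if r.v_gene == vg
            })
            assert pm.values.loc[ind, vg] == oracle


def test_empty_individual_warns_and_gets_zero_row(clone_frame):
    with pytest.warns(UserWarning, match="no beta clones"):
        pm = count_vgene_usage(clone_frame, "beta", "C1",
                               individuals=["I1", "I2", "I3"])
    assert pm.values.loc["I3"].sum() == 0


# ---------------------------------------------------------------------------
# k-mers
# ---------------------------------------------------------------------------


def _kmer_oracle(cdr3s_by_ind, k=7, min_len=12, max_len=18):
    """Naive O(L*k) substring scan, counting clone presence."""
    out = {}
    for ind, seqs in cdr3s_by_ind.items():
        for seq in seqs:
            if not (min_len <= len(seq) <= max_len):
                continue
            for m in {seq[i: i + k] for i in range(len(seq) - k + 1)}:
                out[(ind, m)] = out.get((ind, m), 0) + 1
    return out


def test_kmer_window_count_is_length_minus_six():
    df = pd.DataFrame(
        {
            "individual_id": ["I1"],
            "timepoint": ["C1"],
            "chain": ["beta"],
            "v_gene": ["TRBV1"],
            "cdr3_aa": ["ACDEFGHIKLMN"],  # length 12
            "count": [1],
            "productive": [True],
        }
    )
    pm = count_kmers(df, "beta", "C1")
    assert pm.values.shape == (1, 6)  # L - 6 windows
    assert set(pm.values.columns) == {
        "ACDEFGH", "CDEFGHI", "DEFGHIK", "EFGHIKL", "FGHIKLM", "GHIKLMN"
    }


def test_kmer_length_filter_excludes_short_and_long():
    df = pd.DataFrame(
        {
            "individual_id": ["I1", "I1"],
            "timepoint": ["C1", "C1"],
            "chain": ["beta", "beta"],
            "v_gene": ["TRBV1", "TRBV1"],
            "cdr3_aa": ["ACDEFGHIKLM", "ACDEFGHIKLMNPQRSTVWYA"],  # 11 and 21
            "count": [1, 1],
            "productive": [True, True],
        }
    )
    pm = count_kmers(df, "beta", "C1")
    assert pm.values.shape[1] == 0


def test_kmer_motif_counted_once_per_clone():
    # AAAAAAAA (L=12 padded) contains AAAAAAA twice but the clone counts once
    df = pd.DataFrame(
        {
            "individual_id": ["I1"],
            "timepoint": ["C1"],
            "chain": ["beta"],
            "v_gene": ["TRBV1"],
            "cdr3_aa": ["AAAAAAAAWYFG"],
            "count": [9],
            "productive": [True],
        }
    )
    pm = count_kmers(df, "beta", "C1")
    assert pm.values.loc["I1", "AAAAAAA"] == 1


def test_kmers_match_bruteforce_oracle(small_cohort):
    clones = small_cohort.clones
    sub = clones[(clones["chain"] == "beta") & (clones["timepoint"] == "C1")]
    sub = sub[sub["individual_id"].isin(sub["individual_id"].unique()[:6])]
    pm = count_kmers(sub, "beta", "C1")
    uniq = sub.drop_duplicates(["individual_id", "chain", "v_gene", "cdr3_aa"])
    oracle = _kmer_oracle(
        {i: g["cdr3_aa"].tolist() for i, g in uniq.groupby("individual_id")}
    )
    dense = {
        (i, m): int(pm.values.loc[i, m])
        for i in pm.values.index for m in pm.values.columns
        if pm.values.loc[i, m]
    }
    assert dense == oracle


def test_kmer_warns_on_nonstandard_k(clone_frame):
    with pytest.warns(UserWarning, match="k=5"):
        count_kmers(clone_frame, "beta", "C1", k=5, min_len=5, max_len=18)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _pm(arr, ids=None) -> PhenotypeMatrix:
    arr = np.asarray(arr, float)
    ids = ids or [f"S{i}" for i in range(arr.shape[0])]
    cols = [f"F{j}" for j in range(arr.shape[1])]
    return PhenotypeMatrix(pd.DataFrame(arr, index=ids, columns=cols),
                           "raw_counts")


def test_tmm_identical_samples_all_one():
    pm = _pm(np.tile([5, 9, 14, 3], (4, 1)))
    assert np.allclose(tmm_factors(pm), 1.0)


def test_tmm_pure_library_scaling_absorbed():
    base = np.array([10.0, 40, 25, 5, 20])
    pm = _pm(np.vstack([base, 3 * base]))
    assert np.allclose(tmm_factors(pm), 1.0)


def test_tmm_matches_edger_frozen_fixture():
    """Fixture with one inflated feature block; expected factors were
    computed independently with Bioconductor edgeR calcNormFactors."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(50, size=(6, 12)).astype(float)
    counts[0, :4] *= 8
    counts[3] *= 3
    expected = np.array([
        0.608283972565, 1.107848433149, 1.098494823985,
        1.133709658963, 1.077817861044, 1.105523657816,
    ])
    got = tmm_factors(_pm(counts)).to_numpy()
    assert np.allclose(got, expected, atol=1e-10)


def test_tmm_matches_edger_live(tmp_path):
    rng = np.random.default_rng(123)
    counts = rng.poisson(80, size=(5, 30)).astype(float)
    counts[2, :6] *= 5
    df = _pm(counts).values
    path = tmp_path / "counts.tsv"
    df.T.to_csv(path, sep="\t")
    script = textwrap.dedent(f"""
        suppressMessages(library(edgeR))
        x <- as.matrix(read.delim("{path}", row.names=1))
        cat(sprintf("%.12f", calcNormFactors(x, method="TMM")), sep="\\n")
    """)
    res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    expected = np.array([float(v) for v in res.stdout.split()])
    assert np.allclose(tmm_factors(_pm(counts)).to_numpy(), expected, atol=1e-8)


def test_tmm_geometric_mean_is_one(rng):
    counts = rng.poisson(30, size=(8, 25)).astype(float) + 1
    f = tmm_factors(_pm(counts))
    assert abs(np.log(f).sum()) < 1e-10


# ---------------------------------------------------------------------------
# normalisation / batch / INRT
# ---------------------------------------------------------------------------


def test_normalize_counts_closed_form(rng):
    counts = rng.poisson(30, size=(5, 10)).astype(float) + 1
    pm = _pm(counts)
    f = tmm_factors(pm)
    norm = normalize_counts(pm, f)
    lib = counts.sum(axis=1)
    expected = counts / (lib * f.to_numpy())[:, None] * 1e6
    assert np.allclose(norm.values.to_numpy(), expected)
    assert norm.stage == "normalized"


def test_normalize_scale_invariance():
    counts = np.array([[10.0, 20, 30], [1, 2, 3]])
    pm = _pm(counts)
    f = tmm_factors(pm)
    norm = normalize_counts(pm, f)
    assert np.allclose(norm.values.iloc[0], norm.values.iloc[1])


def test_remove_batch_removes_planted_offset(rng):
    y = rng.normal(0, 1, size=(30, 4))
    batch = pd.Series(["A"] * 15 + ["B"] * 15,
                      index=[f"S{i}" for i in range(30)])
    y[15:] += 0.7  # planted offset on batch B
    pm = PhenotypeMatrix(pd.DataFrame(y, index=batch.index,
                                      columns=list("wxyz")), "normalized")
    out = remove_batch(pm, batch)
    means = out.values.groupby(batch).mean()
    assert np.allclose(means.loc["A"], means.loc["B"], atol=1e-10)
    assert out.stage == "batch_corrected"


def test_remove_batch_single_batch_identity(rng):
    y = rng.normal(size=(6, 3))
    batch = pd.Series(["A"] * 6, index=[f"S{i}" for i in range(6)])
    pm = PhenotypeMatrix(pd.DataFrame(y, index=batch.index), "normalized")
    out = remove_batch(pm, batch)
    assert np.allclose(out.values.to_numpy(), y)


def test_remove_batch_singleton_batch_refused(rng):
    y = rng.normal(size=(5, 2))
    batch = pd.Series(["A", "A", "A", "A", "B"],
                      index=[f"S{i}" for i in range(5)])
    pm = PhenotypeMatrix(pd.DataFrame(y, index=batch.index), "normalized")
    with pytest.raises(ValidationError, match="single individual"):
        remove_batch(pm, batch)


def test_inrt_small_example_against_quantile_oracle():
    pm = PhenotypeMatrix(pd.DataFrame({"f": [3.0, 1.0, 2.0]},
                                      index=list("abc")), "batch_corrected")
    out = inrt(pm).values["f"].to_numpy()
    z = ndtri((np.array([3, 1, 2]) - 0.375) / 3.25)
    assert np.allclose(out, z)
    assert out[0] == pytest.approx(-out[1])  # antisymmetric about 0
    assert out[2] == pytest.approx(0.0)


@given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=40, unique=True))
@settings(max_examples=50, deadline=None)
def test_inrt_invariant_to_monotone_transform(xs):
    x = np.array(xs, float)
    pm1 = PhenotypeMatrix(pd.DataFrame({"f": x}), "batch_corrected")
    pm2 = PhenotypeMatrix(pd.DataFrame({"f": x**3 + 5 * x}),  # strictly monotone
                          "batch_corrected")
    assert np.allclose(inrt(pm1).values["f"], inrt(pm2).values["f"])


def test_inrt_tie_handling_and_constant_column(rng):
    x = np.array([1.0, 5.0, 5.0, 2.0])
    pm = PhenotypeMatrix(pd.DataFrame({"f": x, "const": np.ones(4)}),
                         "batch_corrected")
    with pytest.warns(UserWarning, match="constant"):
        out = inrt(pm).values
    assert out["f"].iloc[1] == out["f"].iloc[2]  # tied maxima equal
    assert (out["const"] == 0).all()


def test_inrt_output_shape_is_normal_without_ties(rng):
    x = rng.normal(size=(200, 3)) ** 3  # heavily skewed input
    pm = PhenotypeMatrix(pd.DataFrame(x), "batch_corrected")
    out = inrt(pm).values.to_numpy()
    assert np.abs(out.mean(axis=0)).max() < 1e-8
    assert np.abs(skew(out, axis=0)).max() < 1e-8


def test_stage_order_enforced(rng):
    raw = _pm(rng.poisson(20, size=(5, 4)).astype(float) + 1)
    batch = pd.Series(["A", "A", "B", "B", "B"], index=raw.values.index)
    with pytest.raises(ValidationError, match="normalized"):
        remove_batch(raw, batch)  # skipping TMM+CPM
    with pytest.raises(ValidationError, match="batch_corrected"):
        inrt(raw)  # skipping everything
    norm = normalize_counts(raw, tmm_factors(raw))
    with pytest.raises(ValidationError, match="raw_counts"):
        tmm_factors(norm)  # TMM twice


# ---------------------------------------------------------------------------
# TCR PCs
# ---------------------------------------------------------------------------


def test_tcr_pcs_rank_one_structure(rng):
    u = rng.normal(size=(30, 1))
    v = rng.normal(size=(1, 8))
    pm = PhenotypeMatrix(pd.DataFrame(u @ v + 1e-6 * rng.normal(size=(30, 8))),
                         "batch_corrected")
    scores = tcr_pcs(pm, 2)
    var = scores.var(ddof=0)
    assert var.iloc[0] / var.sum() > 0.999
    # orthogonality
    assert abs(scores.iloc[:, 0] @ scores.iloc[:, 1]) < 1e-6 * var.iloc[0]
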