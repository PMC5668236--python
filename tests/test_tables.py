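"""Container, I/O and transform tests for feature/taxonomy/phenotype tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from microtrait import (Lineage, OtuTable, PhenotypeTable, TaxonomyMap,
                        ValidationError, ParseError, derive_lipid_indices,
                        fb_ratio, read_feature_table, read_phenotypes,
                        read_taxonomy, write_feature_table)


# ---------------------------------------------------------------------------
# construction and I/O


def test_duplicate_ids_rejected():
    frame = pd.DataFrame([[1, 2], [3, 4]], index=["a", "a"], columns=["s1", "s2"])
    with pytest.raises(ValidationError, match="duplicate feature"):
        OtuTable(frame)
    frame = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"], columns=["s", "s"])
    with pytest.raises(ValidationError, match="duplicate sample"):
        OtuTable(frame)


def test_negative_values_rejected():
    frame = pd.DataFrame([[1, -2]], index=["a"], columns=["s1", "s2"])
    with pytest.raises(ValidationError, match="negative"):
        OtuTable(frame)


def test_read_feature_table_roundtrip(tmp_path, toy_table):
    path = tmp_path / "table.tsv"
    write_feature_table(toy_table, path)
    back = read_feature_table(path)
    assert back.feature_ids == toy_table.feature_ids
    assert back.sample_ids == toy_table.sample_ids
    np.testing.assert_array_equal(back.values, toy_table.values)


def test_read_feature_table_biom_dialect_with_taxonomy(tmp_path):
    path = tmp_path / "biom.tsv"
    path.write_text(
        "#OTU ID\ts1\ts2\ttaxonomy\n"
        "otu1\t3\t4\tk__Bacteria;p__Firmicutes;g__Blautia\n"
        "otu2\t1\t0\tk__Bacteria;p__Bacteroidetes;g__Prevotella\n"
    )
    table = read_feature_table(path)
    assert table.n_features == 2
    assert table.taxonomy is not None
    assert table.taxonomy.label("otu2", "phylum") == "Bacteroidetes"


def test_read_feature_table_errors(tmp_path):
    bad_cell = tmp_path / "bad.tsv"
    bad_cell.write_text("#OTU ID\ts1\ts2\notu1\t3\tx7\n")
    with pytest.raises(ParseError, match="malformed numeric"):
        read_feature_table(bad_cell)
    empty_cell = tmp_path / "empty.tsv"
    empty_cell.write_text("#OTU ID\ts1\ts2\notu1\t3\t\n")
    with pytest.raises(ParseError, match="empty cell"):
        read_feature_table(empty_cell)
    dup = tmp_path / "dup.tsv"
    dup.write_text("#OTU ID\ts1\ts1\notu1\t3\t4\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_feature_table(dup)


def test_orientation_samples_in_rows(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("sample\totu1\totu2\ns1\t1\t2\ns2\t3\t4\n")
    table = read_feature_table(path, orientation="samples")
    assert table.feature_ids == ["otu1", "otu2"]
    assert table.data.loc["otu2", "s1"] == 2


# ---------------------------------------------------------------------------
# taxonomy


def test_lineage_parse_and_roundtrip():
    s = "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Lachnospiraceae; g__"
    lin = Lineage.from_string(s)
    assert lin.to_string() == s.replace(" ", "")
    assert lin.get("family") == "Lachnospiraceae"
    assert lin.get("genus") == "unassigned"
    assert lin.get("species") == "unassigned"


def test_lineage_rejects_unprefixed_token():
    with pytest.raises(ValidationError):
        Lineage.from_string("Bacteria;Firmicutes")


def test_taxonomy_tsv_roundtrip(tmp_path):
    tax = TaxonomyMap.from_strings({
        "otu1": "k__Bacteria;p__Firmicutes;g__Blautia",
        "otu2": "k__Bacteria;p__Bacteroidetes;g__",
    })
    path = tmp_path / "tax.tsv"
    tax.write_tsv(path)
    back = read_taxonomy(path)
    assert back["otu1"] == tax["otu1"]
    assert back.label("otu2", "genus") == "unassigned"


# ---------------------------------------------------------------------------
# rarefaction


def test_rarefy_forced_and_identity_cases():
    data = pd.DataFrame({"s1": [50, 0], "s2": [30, 20]}, index=["a", "b"])
    table = OtuTable(data)
    out = table.rarefy(10, seed=0)
    # single nonzero feature: forced outcome
    assert out.data.loc["a", "s1"] == 10
    # depth equal to column sum would leave s2 unchanged
    out2 = OtuTable(data[["s2"]]).rarefy(50, seed=0)
    np.testing.assert_array_equal(out2.data["s2"], [30, 20])


def test_rarefy_columns_sum_to_depth_every_seed(small_cohort):
    _, table, _, _ = small_cohort
    for seed in (0, 1, 99):
        out = table.rarefy(5000, seed=seed)
        assert (out.values.sum(axis=0) == 5000).all()


def test_rarefy_shallow_samples_error_or_drop():
    data = pd.DataFrame({"deep": [80, 40], "shallow": [3, 2]}, index=["a", "b"])
    table = OtuTable(data)
    with pytest.raises(ValidationError, match="shallow"):
        table.rarefy(10)
    with pytest.warns(UserWarning, match="shallow"):
        out = table.rarefy(10, drop_low=True, seed=0)
    assert out.sample_ids == ["deep"]


def test_rarefy_matches_hypergeometric_moments():
    """Mean subsampled count agrees with the multivariate hypergeometric
    expectation within Monte-Carlo error."""
    data = pd.DataFrame({"s": [9000, 1000]}, index=["a", "b"])
    table = OtuTable(data)
    depth, reps = 1000, 2000
    draws = np.array([
        table.rarefy(depth, seed=seed).data.loc["a", "s"] for seed in range(reps)
    ])
    expected = depth * 0.9
    var = (depth * 0.9 * 0.1) * (10000 - depth) / (10000 - 1)
    se = np.sqrt(var / reps)
    assert abs(draws.mean() - expected) < 3 * se


# ---------------------------------------------------------------------------
# relative abundance + filtering


def test_relative_abundance_basic_and_idempotent(toy_table):
    rel = toy_table.relative_abundance()
    np.testing.assert_allclose(rel.values.sum(axis=0), 1.0, atol=1e-12)
    np.testing.assert_allclose(rel.values[:, 0], [0.5, 0.25, 0.25])
    again = rel.relative_abundance()
    np.testing.assert_array_equal(rel.values, again.values)


def test_relative_abundance_zero_column_errors():
    table = OtuTable(pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["a", "b"]))
    with pytest.raises(ValidationError, match="all-zero"):
        table.relative_abundance()


def test_filter_features_boundaries():
    # prevalence 1/10 at threshold 0.2 -> dropped; exact abundance threshold kept
    rng = np.random.default_rng(1)
    data = rng.integers(1, 100, size=(3, 10)).astype(float)
    data[0, 1:] = 0.0  # feature a: present in 1 of 10
    table = OtuTable(pd.DataFrame(data, index=list("abc"),
                                  columns=[f"s{i}" for i in range(10)]))
    kept, report = table.filter_features(0.0, 0.2)
    assert "a" not in kept.feature_ids
    # inclusive >= on the abundance threshold
    rel = table.relative_abundance()
    thr = rel.values.mean(axis=1)[1]
    kept2, _ = table.filter_features(thr, 0.0)
    assert "b" in kept2.feature_ids


def test_filter_features_matches_brute_force(small_cohort):
    _, table, _, _ = small_cohort
    kept, report = table.filter_features(5e-4, 0.2)
    rel = table.values / table.values.sum(axis=0)
    expected = []
    for i, fid in enumerate(table.feature_ids):
        mean_ab = rel[i].mean()
        prev = (table.values[i] > 0).mean()
        if mean_ab >= 5e-4 and prev >= 0.2:
            expected.append(fid)
    assert kept.feature_ids == expected
    assert report["kept"].sum() == len(expected)


def test_filter_features_bad_threshold():
    table = OtuTable(pd.DataFrame({"s1": [1]}, index=["a"]))
    with pytest.raises(ValidationError, match="min_prevalence"):
        table.filter_features(0.1, 1.5)


@settings(deadline=None, max_examples=20)
@given(st.randoms(use_true_random=False))
def test_filter_features_order_independent(rnd):
    rng = np.random.default_rng(rnd.randint(0, 2**31))
    data = rng.integers(0, 50, size=(12, 8)).astype(float)
    data[:, data.sum(axis=0) == 0] = 1.0
    ids = [f"f{i}" for i in range(12)]
    table = OtuTable(pd.DataFrame(data, index=ids,
                                  columns=[f"s{j}" for j in range(8)]))
    kept, _ = table.filter_features(0.02, 0.3)
    perm = rng.permutation(12)
    shuffled = OtuTable(table.data.iloc[perm])
    kept_shuffled, _ = shuffled.filter_features(0.02, 0.3)
    assert set(kept.feature_ids) == set(kept_shuffled.feature_ids)


# ---------------------------------------------------------------------------
# taxonomy aggregation and F/B ratio


@pytest.fixture
def phylum_toy():
    table = OtuTable(pd.DataFrame(
        {"s1": [0.1, 0.2, 0.3, 0.4], "s2": [0.25, 0.25, 0.25, 0.25]},
        index=["o1", "o2", "o3", "o4"]), kind="relative_abundance")
    tax = TaxonomyMap.from_strings({
        "o1": "k__Bacteria;p__Firmicutes;g__Blautia",
        "o2": "k__Bacteria;p__Firmicutes;g__Roseburia",
        "o3": "k__Bacteria;p__Bacteroidetes;g__Prevotella",
        "o4": "k__Bacteria;p__;g__",
    })
    return table, tax


def test_aggregate_taxa_hand_worked(phylum_toy):
    table, tax = phylum_toy
    agg = table.aggregate_taxa(tax, "phylum")
    assert agg.data.loc["Firmicutes", "s1"] == pytest.approx(0.3)
    assert agg.data.loc["Bacteroidetes", "s1"] == pytest.approx(0.3)
    assert agg.data.loc["unassigned", "s1"] == pytest.approx(0.4)
    # conservation of per-sample totals
    np.testing.assert_allclose(agg.values.sum(axis=0),
                               table.values.sum(axis=0), atol=1e-12)


def test_aggregate_taxa_genus_additivity(phylum_toy):
    table, tax = phylum_toy
    agg = table.aggregate_taxa(tax, "genus")
    assert agg.data.loc["Blautia", "s2"] == pytest.approx(0.25)
    with pytest.raises(ValidationError, match="rank"):
        table.aggregate_taxa(tax, "kingdom")


def test_fb_ratio_hand_worked(phylum_toy):
    table, tax = phylum_toy
    ratio = fb_ratio(table, tax)
    assert ratio["s1"] == pytest.approx(0.3 / 0.3)
    assert ratio["s2"] == pytest.approx(0.5 / 0.25)


def test_fb_ratio_zero_bacteroidetes_is_missing():
    table = OtuTable(pd.DataFrame({"s1": [1.0]}, index=["o1"]),
                     kind="relative_abundance")
    tax = TaxonomyMap.from_strings({"o1": "k__Bacteria;p__Firmicutes"})
    with pytest.warns(UserWarning, match="zero Bacteroidetes"):
        ratio = fb_ratio(table, tax)
    assert np.isnan(ratio["s1"])


# ---------------------------------------------------------------------------
# phenotypes and lipid indices


def test_derive_lipid_indices_identities(toy_pheno):
    derived = derive_lipid_indices(toy_pheno)
    d = derived.data
    np.testing.assert_array_equal(
        d["AI"].to_numpy(), ((d["TCHOL"] - d["HDL"]) / d["HDL"]).to_numpy())
    np.testing.assert_array_equal(
        d["LDL_HDL"].to_numpy(), (d["LDL"] / d["HDL"]).to_numpy())
    # original columns untouched
    pd.testing.assert_frame_equal(d[toy_pheno.data.columns], toy_pheno.data)


def test_derive_lipid_indices_simple_values():
    frame = pd.DataFrame({
        "sample_id": ["x", "y"], "sex": ["gilt", "gilt"], "batch": ["b", "b"],
        "GLU": [3, 3], "TCHOL": [2.0, 1.0], "TG": [0.2, 0.2],
        "HDL": [1.0, 1.0], "LDL": [1.5, 0.5],
    })
    out = PhenotypeTable(frame).derive_lipid_indices().data
    assert out.loc["x", "AI"] == pytest.approx(1.0)
    assert out.loc["y", "AI"] == pytest.approx(0.0)
    assert out.loc["x", "LDL_HDL"] == pytest.approx(1.5)


def test_derive_lipid_indices_nonpositive_hdl_warns():
    frame = pd.DataFrame({
        "sample_id": ["x"], "sex": ["gilt"], "batch": ["b"], "GLU": [3],
        "TCHOL": [2.0], "TG": [0.2], "HDL": [0.0], "LDL": [1.5],
    })
    with pytest.warns(UserWarning, match="HDL"):
        out = PhenotypeTable(frame).derive_lipid_indices().data
    assert np.isnan(out.loc["x", "AI"])


def test_read_phenotypes_csv(tmp_path, toy_pheno):
    path = tmp_path / "pheno.csv"
    toy_pheno.write(path)
    back = read_phenotypes(path)
    pd.testing.assert_frame_equal(back.data, toy_pheno.data)


def test_missing_batch_defaults_single_level():
    frame = pd.DataFrame({"sample_id": ["a", "b"], "sex": ["gilt", "gilt"],
                          "GLU": [1.0, 2.0]})
    with pytest.warns(UserWarning, match="batch"):
        pheno = PhenotypeTable(frame)
    assert (pheno.data["batch"] == "batch1").all()
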