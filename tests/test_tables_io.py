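import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from microstage.tables_io import (
    AsvTable,
    SampleMetadata,
    TableValidationError,
    aggregate_taxa,
    expand_lineages,
    prevalence_filter,
    read_asv_table,
    relative_abundance,
    write_asv_table,
)


def _write_tsv(path, frame):
    frame.to_csv(path, sep="\t", index_label="id")


class TestReadWrite:
    def test_round_trip_is_bit_exact(self, toy_table, tmp_path):
        path = tmp_path / "t.tsv"
        write_asv_table(toy_table, path)
        back = read_asv_table(path, orientation="sample_rows", site="feces")
        pd.testing.assert_frame_equal(back.counts, toy_table.counts)

    def test_asv_rows_orientation_matches_transpose(self, toy_table, tmp_path):
        path = tmp_path / "t.tsv"
        _write_tsv(path, toy_table.counts.T)
        back = read_asv_table(path, orientation="asv_rows")
        assert np.array_equal(back.counts.to_numpy(), toy_table.counts.to_numpy())
        assert back.sample_ids == toy_table.sample_ids

    def test_taxonomy_column_dropped(self, toy_table, tmp_path):
        path = tmp_path / "t.tsv"
        aug = toy_table.counts.copy()
        aug["taxonomy"] = "Bacteria;Firmicutes"
        _write_tsv(path, aug)
        back = read_asv_table(path)
        assert back.asv_ids == toy_table.asv_ids

    @pytest.mark.parametrize("bad_value,match", [
        (-1, "negative"),
        ("oops", "malformed numeric cell"),
    ])
    def test_bad_cells_rejected(self, toy_table, tmp_path, bad_value, match):
        path = tmp_path / "t.tsv"
        broken = toy_table.counts.astype(object).copy()
        broken.iloc[1, 2] = bad_value
        _write_tsv(path, broken)
        with pytest.raises((TableValidationError, ValueError), match=match):
            read_asv_table(path)

    def test_duplicate_identifiers_rejected(self, toy_table):
        dup = toy_table.counts.copy()
        dup.columns = ["a1", "a1", "a3", "a4"]
        with pytest.raises(TableValidationError, match="duplicate"):
            AsvTable(dup)

    def test_zero_total_sample_rejected(self):
        counts = pd.DataFrame([[1, 2], [0, 0]], index=["s1", "s2"], columns=["a", "b"])
        with pytest.raises(TableValidationError, match="zero total"):
            AsvTable(counts)


class TestRelativeAbundance:
    def test_hand_values(self):
        counts = pd.DataFrame([[2, 2], [0, 5]], index=["s1", "s2"], columns=["a", "b"])
        props = relative_abundance(AsvTable(counts))
        assert props.loc["s1"].tolist() == [0.5, 0.5]
        assert props.loc["s2"].tolist() == [0.0, 1.0]

    @settings(max_examples=25, deadline=None)
    @given(arrays(np.int64, (10, 20), elements=st.integers(0, 1000)))
    def test_rows_sum_to_one(self, counts):
        counts[:, 0] += 1  # guarantee positive totals
        table = AsvTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(10)],
            columns=[f"a{j}" for j in range(20)]))
        sums = relative_abundance(table).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestPrevalenceFilter:
    @pytest.mark.parametrize("n_present,kept", [(30, True), (29, False)])
    def test_one_third_boundary(self, n_present, kept):
        n = 90
        counts = pd.DataFrame(
            {"always": np.ones(n, dtype=int),
             "tested": [1] * n_present + [0] * (n - n_present)},
            index=[f"s{i}" for i in range(n)])
        out = prevalence_filter(AsvTable(counts), 1 / 3)
        assert ("tested" in out.asv_ids) == kept

    def test_idempotent(self, small_cohort):
        once = prevalence_filter(small_cohort["feces"], 1 / 3)
        twice = prevalence_filter(once, 1 / 3)
        assert once.asv_ids == twice.asv_ids

    def test_sample_set_unchanged_and_empty_result_allowed(self, toy_table):
        out = prevalence_filter(toy_table, 1.0)
        assert out.sample_ids == toy_table.sample_ids
        all_filtered = prevalence_filter(
            AsvTable(pd.DataFrame(np.eye(3, dtype=int),
                                  index=list("xyz"), columns=list("abc"))),
            1.0)
        assert all_filtered.n_asvs == 0

    def test_per_group_mode(self, toy_table, toy_metadata):
        pooled = prevalence_filter(toy_table, 1.0, metadata=toy_metadata, mode="pooled")
        per_group = prevalence_filter(
            toy_table, 1.0, metadata=toy_metadata, mode="per_group")
        # a4 is present in every sample, so both modes keep it; a2 is absent in
        # s1 (pooled fails at fraction 1.0) but fully present within group NM
        assert "a2" not in pooled.asv_ids
        assert "a2" in per_group.asv_ids


class TestAggregateTaxa:
    @pytest.fixture
    def taxonomy(self, toy_table):
        return expand_lineages(pd.Series({
            "a1": "Bacteria;P1;C;O;F;G1;sp1",
            "a2": "Bacteria;P1;C;O;F;G1;sp2",
            "a3": "Bacteria;P2;C;O;F;G2;sp3",
            "a4": "Bacteria;P2",  # missing ranks -> unclassified_<parent>
        }))

    def test_shared_genus_sums(self, toy_table, taxonomy):
        agg = aggregate_taxa(toy_table, taxonomy, "genus", top_k=10)
        props = relative_abundance(toy_table)
        assert np.allclose(agg["G1"], props["a1"] + props["a2"])

    def test_missing_ranks_propagate_unclassified(self, taxonomy):
        assert taxonomy.loc["a4", "genus"].startswith("unclassified_")

    def test_no_others_when_topk_large(self, toy_table, taxonomy):
        agg = aggregate_taxa(toy_table, taxonomy, "genus", top_k=10)
        assert "Others" not in agg.columns

    def test_others_bucket_and_row_sums(self, toy_table, taxonomy):
        agg = aggregate_taxa(toy_table, taxonomy, "genus", top_k=1)
        assert "Others" in agg.columns
        assert np.allclose(agg.sum(axis=1), 1.0, atol=1e-12)

    def test_invariant_to_asv_column_order(self, toy_table, taxonomy, rng):
        perm = rng.permutation(toy_table.asv_ids)
        shuffled = AsvTable(toy_table.counts[perm], site=toy_table.site)
        a = aggregate_taxa(toy_table, taxonomy, "genus", top_k=2)
        b = aggregate_taxa(shuffled, taxonomy, "genus", top_k=2)
        pd.testing.assert_frame_equal(a, b[a.columns])


class TestMetadata:
    def test_missing_column_rejected(self):
        with pytest.raises(TableValidationError, match="missing columns"):
            SampleMetadata(pd.DataFrame({"sample_id": ["s1"]}))

    def test_unknown_group_rejected(self, toy_metadata):
        bad = toy_metadata.frame.copy()
        bad.loc[0, "group"] = "XX"
        with pytest.raises(TableValidationError, match="unknown groups"):
            SampleMetadata(bad)

    def test_groups_for_missing_sample(self, toy_metadata):
        with pytest.raises(TableValidationError, match="without metadata"):
            toy_metadata.groups_for(["s1", "nope"])
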