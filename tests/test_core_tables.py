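import numpy as np
import pandas as pd
import pytest

from mycobloom import (DataError, SampleFilterPolicy, filter_samples,
                       read_table, subset_fraction, write_table)
from mycobloom.core_tables import SIZE_FRACTIONS

from conftest import make_table, random_table

COUNTS_TSV = """asv_id\tS1\tS2
A1\t5\t10
A2\t10\t20
A3\t5\t10
"""
TAXONOMY_TSV = (
    "asv_id\tdomain\tsupergroup\tdivision\tclass\torder\tfamily\tgenus\tspecies\tis_fungal\n"
    "A1\tEukaryota\tOpisthokonta\tFungi\tAscomycota\tunassigned\tunassigned\tunassigned\tunassigned\ttrue\n"
    "A2\tEukaryota\tunassigned\tDinoflagellata\tunassigned\tunassigned\tunassigned\tunassigned\tunassigned\tfalse\n"
    "A3\tEukaryota\tOpisthokonta\tFungi\tChytridiomycota\tunassigned\tunassigned\tunassigned\tunassigned\ttrue\n"
)
METADATA_CSV = """sample_id,date,size_fraction,station
S1,2015-03-01,gt3um,SOLA
S2,2015-03-15,0.2-3um,SOLA
"""


@pytest.fixture
def fixture_paths(tmp_path):
    paths = {}
    for name, text in [("counts.tsv", COUNTS_TSV), ("taxonomy.tsv", TAXONOMY_TSV),
                       ("metadata.csv", METADATA_CSV)]:
        p = tmp_path / name
        p.write_text(text)
        paths[name.split(".")[0]] = p
    return paths


class TestReadWrite:
    def test_dense_fixture_column_sums(self, fixture_paths):
        table = read_table(fixture_paths["counts"], fixture_paths["taxonomy"],
                           fixture_paths["metadata"])
        assert table.total_reads().tolist() == [20, 40]
        assert list(table.fungal_ids()) == ["A1", "A3"]

    def test_sparse_triplet_equals_dense(self, fixture_paths, tmp_path):
        dense = read_table(fixture_paths["counts"], fixture_paths["taxonomy"],
                           fixture_paths["metadata"])
        trip = tmp_path / "triplet.tsv"
        write_table(dense, trip, tmp_path / "t.tsv", tmp_path / "m.csv", sparse=True)
        again = read_table(trip, fixture_paths["taxonomy"], fixture_paths["metadata"])
        pd.testing.assert_frame_equal(
            dense.counts.sort_index(), again.counts.sort_index(), check_names=False
        )

    @pytest.mark.parametrize("sparse", [False, True])
    def test_write_read_round_trip(self, tmp_path, sparse):
        rng = np.random.default_rng(0)
        table = random_table(rng)
        paths = [tmp_path / "c.tsv", tmp_path / "t.tsv", tmp_path / "m.csv"]
        write_table(table, *paths, sparse=sparse)
        back = read_table(*paths)
        # triplet files carry no column order; compare on a canonical one
        cols = sorted(table.sample_ids)
        pd.testing.assert_frame_equal(table.counts[cols].sort_index(),
                                      back.counts[cols].sort_index(),
                                      check_names=False)
        assert (back.samples.loc[cols, "date"]
                == table.samples.loc[cols, "date"]).all()
        assert back.taxonomy["is_fungal"].sort_index().equals(
            table.taxonomy["is_fungal"].sort_index())

    def test_negative_count_names_cell(self, fixture_paths, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(COUNTS_TSV.replace("10\t20", "-3\t20"))
        with pytest.raises(DataError, match="A2.*S1"):
            read_table(bad, fixture_paths["taxonomy"], fixture_paths["metadata"])

    def test_missing_taxonomy_is_hard_error(self, fixture_paths, tmp_path):
        trimmed = tmp_path / "tax.tsv"
        trimmed.write_text("\n".join(TAXONOMY_TSV.splitlines()[:-1]) + "\n")
        with pytest.raises(DataError, match="A3"):
            read_table(fixture_paths["counts"], trimmed, fixture_paths["metadata"])

    def test_unparseable_date_names_row(self, fixture_paths, tmp_path):
        meta = tmp_path / "meta.csv"
        meta.write_text(METADATA_CSV.replace("2015-03-15", "yesterday"))
        with pytest.raises(DataError, match="S2"):
            read_table(fixture_paths["counts"], fixture_paths["taxonomy"], meta)

    def test_duplicate_sample_id_rejected(self, fixture_paths, tmp_path):
        meta = tmp_path / "meta.csv"
        meta.write_text(METADATA_CSV + "S2,2015-04-01,gt3um,SOLA\n")
        with pytest.raises(DataError, match="duplicate"):
            read_table(fixture_paths["counts"], fixture_paths["taxonomy"], meta)


class TestFilterSamples:
    def test_threshold_boundary_inclusive(self):
        table = make_table({"A": [999, 1000, 5000]}, fungal=set())
        kept = filter_samples(table, SampleFilterPolicy(min_total_reads=1000))
        assert kept.n_samples == 2
        assert "S1" not in kept.sample_ids

    def test_zero_threshold_is_identity(self):
        table = make_table({"A": [5, 7]}, fungal=set())
        kept = filter_samples(table, SampleFilterPolicy(min_total_reads=0))
        assert list(kept.sample_ids) == list(table.sample_ids)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, max_count=300)
        policy = SampleFilterPolicy(min_total_reads=2000)
        once = filter_samples(table, policy)
        twice = filter_samples(once, policy)
        assert list(once.sample_ids) == list(twice.sample_ids)

    def test_all_removed_errors(self):
        table = make_table({"A": [10, 20]}, fungal=set())
        with pytest.raises(DataError, match="below"):
            filter_samples(table, SampleFilterPolicy(min_total_reads=10_000))

    def test_low_read_synthetic_sample_absent_downstream(self, sim_small):
        table, _ = sim_small
        victim = table.sample_ids[3]
        counts = table.counts.copy()
        col = counts[victim].to_numpy()
        # scale the column down to a 500-read sample
        scaled = np.floor(col * (500 / col.sum())).astype(np.int64)
        counts[victim] = scaled
        from mycobloom import AsvTable
        hacked = AsvTable(counts=counts, taxonomy=table.taxonomy.copy(),
                          samples=table.samples.copy())
        kept = filter_samples(hacked, SampleFilterPolicy(min_total_reads=1000))
        assert victim not in kept.sample_ids
        assert kept.n_samples == table.n_samples - 1


class TestSubsetFraction:
    def test_partition_over_labels(self, sim_small):
        table, _ = sim_small
        parts = [subset_fraction(table, f).sample_ids for f in SIZE_FRACTIONS]
        union = set().union(*[set(p) for p in parts])
        assert union == set(table.sample_ids)
        assert sum(len(p) for p in parts) == table.n_samples

    def test_unknown_label_lists_valid(self):
        table = make_table({"A": [5, 7]}, fungal=set())
        with pytest.raises(DataError, match="gt3um"):
            subset_fraction(table, "10um")

    def test_empty_fraction_errors(self):
        table = make_table({"A": [5, 7]}, fungal=set())  # all gt3um
        with pytest.raises(DataError, match="no samples"):
            subset_fraction(table, "0.2-3um")

    def test_all_zero_rows_retained(self):
        table = make_table({"A": [5, 0], "B": [0, 7]}, fungal=set(),
                           fractions=["gt3um", "0.2-3um"])
        sub = subset_fraction(table, "gt3um")
        assert list(sub.asv_ids) == ["A", "B"]
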