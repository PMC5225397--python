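import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqdup.impact import (
    PipelineConfig,
    aggregate,
    group_differences,
    pair_differences,
    duplicates_mean_differences,
    redundancy_reduction,
    run_pipeline,
)
from seqdup.records import DuplicatePair, MergedGroup, NucleotideRecord
from seqdup.seqprops import SequenceProperties
from seqdup.synthetic import GeneratorConfig


def props_of(gc):
    # synthetic property bundle where every property equals gc, so arithmetic
    # can be checked by hand on one number
    return SequenceProperties(gc_percent=gc, tm_basic=gc, tm_salt=gc,
                              tm_advanced=gc)


def test_group_difference_symmetric_members_cancel():
    group = MergedGroup("g1", "E", ("A", "B"), "X x")
    props = {"E": props_of(50.0), "A": props_of(40.0), "B": props_of(60.0)}
    assert group_differences(group, props)["gc"] == pytest.approx(0.0)


def test_group_difference_single_member():
    group = MergedGroup("g1", "E", ("A",), "X x")
    props = {"E": props_of(50.0), "A": props_of(40.0)}
    d = group_differences(group, props)
    assert d["gc"] == pytest.approx(5.0)  # mean(50, 40) = 45


def test_pair_difference_is_absolute():
    ex = NucleotideRecord("E", "ACGTACGT")
    du = NucleotideRecord("D", "ACGTACGT")
    pair = DuplicatePair(exemplar=ex, duplicate=du, group_id="g1", organism="X x")
    props = {"E": props_of(50.0), "D": props_of(40.0)}
    assert pair_differences(pair, props)["gc"] == pytest.approx(10.0)


def test_duplicates_mean_excludes_exemplar():
    group = MergedGroup("g1", "E", ("A", "B"), "X x")
    props = {"E": props_of(50.0), "A": props_of(40.0), "B": props_of(60.0)}
    assert duplicates_mean_differences(group, props)["gc"] == pytest.approx(0.0)
    props["B"] = props_of(40.0)
    assert duplicates_mean_differences(group, props)["gc"] == pytest.approx(10.0)


def test_missing_property_names_accession():
    group = MergedGroup("g1", "E", ("A",), "X x")
    with pytest.raises(KeyError, match="A"):
        group_differences(group, {"E": props_of(50.0)})


def test_aggregate_mean_and_sample_std():
    diffs = [{p: d for p in ("gc", "tm_basic", "tm_salt", "tm_advanced")}
             for d in (0.0, 10.0)]
    out = aggregate(diffs, ["EF", "EF"], ["X x", "X x"], setting="pair")
    row = out[out["category"] == "EF"].iloc[0]
    assert row["size"] == 2
    assert row["mdiff_gc"] == pytest.approx(5.0)
    assert row["std_gc"] == pytest.approx(np.std([0, 10], ddof=1))  # ~7.071
    all_row = out[out["category"] == "ALL"].iloc[0]
    assert all_row["size"] == 2


def test_aggregate_single_unit_std_is_zero():
    diffs = [{p: 3.0 for p in ("gc", "tm_basic", "tm_salt", "tm_advanced")}]
    out = aggregate(diffs, ["SS"], ["X x"], setting="pair")
    row = out[out["category"] == "SS"].iloc[0]
    assert row["mdiff_gc"] == pytest.approx(3.0)
    assert row["std_gc"] == 0.0


def test_aggregate_empty_input_gives_empty_table():
    assert aggregate([], [], [], setting="pair").empty


def test_aggregate_all_row_counts_each_unit_once():
    diffs = [{p: float(i) for p in ("gc", "tm_basic", "tm_salt", "tm_advanced")}
             for i in range(5)]
    labels = ["ES", "ES", "EF", "SF", "LI"]
    out = aggregate(diffs, labels, ["X x"] * 5, setting="group")
    all_row = out[out["category"] == "ALL"].iloc[0]
    assert all_row["size"] == 5
    per_cat = out[out["category"] != "ALL"]["size"].sum()
    assert per_cat == 5


def test_redundancy_reduction_arithmetic():
    groups = [
        MergedGroup("g1", "E1", ("A",), "X x"),
        MergedGroup("g2", "E2", ("B", "C"), "X x"),
        MergedGroup("g3", "E3", ("D", "F", "G"), "X x"),
    ]
    # 3 groups, 9 records
    assert redundancy_reduction(groups) == pytest.approx(100 * (1 - 3 / 9))


def test_redundancy_reduction_minimal_groups_exactly_fifty():
    groups = [MergedGroup(f"g{i}", f"E{i}", (f"D{i}",), "X x") for i in range(10)]
    assert redundancy_reduction(groups) == pytest.approx(50.0)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=1, max_value=8), min_size=1, max_size=40))
def test_redundancy_reduction_structurally_at_least_fifty(member_counts):
    groups = [
        MergedGroup(f"g{i}", f"E{i}", tuple(f"D{i}_{j}" for j in range(k)), "X x")
        for i, k in enumerate(member_counts)
    ]
    assert redundancy_reduction(groups) >= 50.0


def test_pipeline_config_requires_exactly_one_source(tmp_path):
    with pytest.raises(ValueError):
        PipelineConfig()
    with pytest.raises(ValueError):
        PipelineConfig(fasta="x.fasta", groups="g.tsv",
                       synthetic=GeneratorConfig(seed=0, n_groups=1))


def test_run_pipeline_deterministic_reports(tmp_path):
    cfg = PipelineConfig(
        synthetic=GeneratorConfig(seed=3, n_groups=30, length_range=(150, 600))
    )
    out1 = tmp_path / "run1"
    out2 = tmp_path / "run2"
    run_pipeline(cfg, out1)
    run_pipeline(cfg, out2)
    for name in ("pairs.tsv", "pair_categories.tsv", "table2_counts.tsv",
                 "table3_group_impact.tsv", "table4_pair_impact.tsv"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


def test_run_pipeline_from_files_matches_group_bookkeeping(tmp_path):
    from seqdup.synthetic import generate_benchmark, write_benchmark

    bench = generate_benchmark(
        GeneratorConfig(seed=5, n_groups=12, length_range=(150, 500))
    )
    write_benchmark(bench, tmp_path)
    cfg = PipelineConfig(
        fasta=str(tmp_path / "records.fasta"),
        groups=str(tmp_path / "groups.tsv"),
    )
    result = run_pipeline(cfg, tmp_path / "out")
    assert len(result.pair_table) == len(bench.pairs)
    assert result.redundancy_reduction == pytest.approx(
        redundancy_reduction(bench.groups)
    )
    # report rows: per organism, categories present + ALL
    for organism, sub in result.pair_impact.groupby("organism"):
        cats = set(
            result.pair_table.loc[
                result.pair_table["organism"] == organism, "seq_category"
            ]
        )
        assert set(sub["category"]) == cats | {"ALL"}
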