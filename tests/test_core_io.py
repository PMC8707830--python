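import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from germscreen.core_io import (
    InputError,
    read_metabolome,
    read_network,
    read_phenotype,
    validate_phenotype,
    write_metabolome,
    write_network,
)

from conftest import build_matrix


def tiny_matrix():
    return build_matrix(
        [[1.0, 2.5], [3.0, 4.0]],
        varieties=("fast",),
        timepoints=(0, 3),
        n_replicates=1,
        met_ids=["metA", "metB"],
    )


@pytest.mark.parametrize("layout", ["wide", "long"])
def test_metabolome_round_trip(tmp_path, layout):
    m = tiny_matrix()
    path = tmp_path / "m.csv"
    write_metabolome(m, path, layout=layout)
    back = read_metabolome(path, layout=layout)
    assert back == m
    assert back.values.isna().sum().sum() == 0


def test_wide_and_long_reads_agree(tmp_path):
    m = tiny_matrix()
    write_metabolome(m, tmp_path / "w.csv", layout="wide")
    write_metabolome(m, tmp_path / "l.csv", layout="long")
    assert read_metabolome(tmp_path / "w.csv", "wide") == read_metabolome(
        tmp_path / "l.csv", "long"
    )


def test_tab_delimiter_autodetected(tmp_path):
    m = tiny_matrix()
    write_metabolome(m, tmp_path / "m.tsv", layout="wide", sep="\t")
    assert read_metabolome(tmp_path / "m.tsv", "wide") == m


def test_negative_intensity_names_the_cell(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "sample_id,variety,timepoint_hai,replicate,metA\ns1,fast,0,1,-1.0\n"
    )
    with pytest.raises(InputError, match="metA"):
        read_metabolome(path, "wide")


def test_duplicate_sample_triple_rejected(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text(
        "sample_id,variety,timepoint_hai,replicate,metA\n"
        "s1,fast,0,1,1.0\ns2,fast,0,1,2.0\n"
    )
    with pytest.raises(InputError, match="duplicate sample triple"):
        read_metabolome(path, "wide")


def test_duplicate_long_cell_rejected(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text(
        "sample_id,variety,timepoint_hai,replicate,metabolite_id,intensity\n"
        "s1,fast,0,1,metA,1.0\ns1,fast,0,1,metA,2.0\n"
    )
    with pytest.raises(InputError, match="duplicate cell"):
        read_metabolome(path, "long")


def test_empty_cell_becomes_missing(tmp_path):
    path = tmp_path / "gap.csv"
    path.write_text(
        "sample_id,variety,timepoint_hai,replicate,metA,metB\ns1,fast,0,1,,2.0\n"
    )
    m = read_metabolome(path, "wide")
    assert np.isnan(m.values.loc["s1", "metA"])
    assert m.values.loc["s1", "metB"] == 2.0


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    n_samples=st.integers(1, 4),
    n_mets=st.integers(1, 5),
    data=st.data(),
)
def test_fuzzed_well_formed_tables_round_trip(tmp_path_factory, n_samples, n_mets, data):
    """Any well-formed non-negative table is accepted and survives a round trip."""
    vals = np.array(
        data.draw(
            st.lists(
                st.lists(
                    st.floats(0, 1e6, allow_nan=False, width=32),
                    min_size=n_mets,
                    max_size=n_mets,
                ),
                min_size=n_samples,
                max_size=n_samples,
            )
        )
    )
    m = build_matrix(
        vals,
        varieties=("fast",),
        timepoints=range(n_samples),
        n_replicates=1,
        met_ids=[f"m{i}" for i in range(n_mets)],
    )
    path = tmp_path_factory.mktemp("fuzz") / "m.csv"
    write_metabolome(m, path)
    assert read_metabolome(path) == m


# -- network export ---------------------------------------------------------


def _edges(n, r=0.9):
    return pd.DataFrame(
        {
            "metabolite_id": [f"met{i:04d}" for i in range(n)],
            "variety": ["fast"] * n,
            "r": [r] * n,
            "p": [0.01] * n,
        }
    )


def test_empty_network_still_writes_valid_tables(tmp_path):
    out = write_network(_edges(0), None, tmp_path / "net")
    back = read_network(tmp_path / "net")
    assert len(back) == 0
    assert list(back.columns)[:2] == ["source", "target"]


def test_single_edge_weight_and_sign(tmp_path):
    write_network(_edges(1, r=0.9), None, tmp_path / "net")
    back = read_network(tmp_path / "net")
    assert len(back) == 1
    assert back.loc[0, "weight"] == 0.9
    assert back.loc[0, "sign"] == "pos"
    assert back.loc[0, "target"] == "germination_rate[fast]"


def test_edge_table_row_count_contract(tmp_path):
    """An n-edge network produces exactly n data rows (checked at n=184)."""
    write_network(_edges(184), None, tmp_path / "net")
    assert len(read_network(tmp_path / "net")) == 184
    sif = (tmp_path / "net.sif").read_text().strip().splitlines()
    assert len(sif) == 184


def test_graphml_mirror_loads(tmp_path):
    import networkx as nx

    write_network(_edges(5), None, tmp_path / "net")
    g = nx.read_graphml(tmp_path / "net.graphml")
    assert g.number_of_edges() == 5


# -- phenotype --------------------------------------------------------------


def test_phenotype_fraction_range_enforced():
    df = pd.DataFrame(
        {"variety": ["fast"], "timepoint_hai": [0], "germination_fraction": [1.2]}
    )
    with pytest.raises(InputError, match="outside"):
        validate_phenotype(df)


def test_phenotype_nonmonotone_series_warns_not_fails():
    df = pd.DataFrame(
        {
            "variety": ["fast", "fast"],
            "timepoint_hai": [0, 12],
            "germination_fraction": [0.5, 0.2],
        }
    )
    with pytest.warns(UserWarning, match="decreases"):
        out = validate_phenotype(df)
    assert len(out) == 2


def test_phenotype_round_trip(tmp_path, default_dataset):
    from germscreen.core_io import write_phenotype

    _, phen, _ = default_dataset
    write_phenotype(phen, tmp_path / "p.csv")
    back = read_phenotype(tmp_path / "p.csv")
    pd.testing.assert_frame_equal(
        back.reset_index(drop=True), phen.reset_index(drop=True), check_dtype=False
    )
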