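"""Rule grammar, model file round-trips, and edge export."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hillnet import (
    RuleParseError,
    build_cardiacdevnet,
    build_examplenet,
    export_edges,
    load_model,
    parse_rule,
    render_rule,
    validate_model,
    write_model,
)
from hillnet.fixtures import data_dir
from hillnet.model_io import ModelIOError


# ---------------------------------------------------------------------------
# Rule grammar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text, expected_regs, expected_product",
    [
        ("=> GATA6", [], "GATA6"),
        ("'=> GATA6", [], "GATA6"),  # spreadsheet text-guard apostrophe
        ("!NKX25 => ISL1", [("NKX25", "inhibitor")], "ISL1"),
        ("C & !D => E", [("C", "activator"), ("D", "inhibitor")], "E"),
        ("  A   =>   C  ", [("A", "activator")], "C"),
        ("!a & !b & c => d", [("a", "inhibitor"), ("b", "inhibitor"), ("c", "activator")], "d"),
    ],
)
def test_parse_rule(text, expected_regs, expected_product):
    regulators, product = parse_rule(text)
    assert [(r.species_id, r.sign) for r in regulators] == expected_regs
    assert product == expected_product


@pytest.mark.parametrize(
    "text",
    [
        "A =>",  # empty product
        "A -> B",  # missing separator
        "A => B => C",  # two separators
        "A & => B",  # empty regulator between '&'s
        "! => B",  # '!' with no token
        "A | B => C",  # OR is structural, not in-rule
        "",
        "A => B C",  # product is not one token
    ],
)
def test_parse_rule_rejects_malformed(text):
    with pytest.raises(RuleParseError):
        parse_rule(text)


token = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), max_codepoint=127),
    min_size=1,
    max_size=6,
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    regs=st.lists(st.tuples(token, st.sampled_from(["activator", "inhibitor"])), max_size=4),
    product=token,
)
def test_render_parse_round_trip(regs, product):
    """parse(render(...)) is the identity on canonical rule strings."""
    from hillnet.model import Regulator

    regulators = [Regulator(s, sign) for s, sign in regs]
    text = render_rule(regulators, product)
    parsed_regs, parsed_product = parse_rule(text)
    assert parsed_regs == regulators
    assert parsed_product == product
    assert render_rule(parsed_regs, parsed_product) == text  # canonical fixpoint


# ---------------------------------------------------------------------------
# File round-trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("builder", [build_examplenet, build_cardiacdevnet])
@pytest.mark.parametrize("dialect, suffix", [("workbook", "model.xlsx"), ("csv", "model_dir")])
def test_write_load_round_trip(tmp_path, builder, dialect, suffix):
    model = builder()
    target = tmp_path / suffix
    write_model(model, target, dialect=dialect)
    loaded = load_model(target, dialect=dialect)
    assert loaded.species == model.species
    assert loaded.reactions == model.reactions
    assert validate_model(loaded) == []


def test_shipped_fixture_files_match_builders():
    for name, builder in [
        ("examplenet", build_examplenet),
        ("cardiacdevnet", build_cardiacdevnet),
    ]:
        loaded = load_model(data_dir() / name)
        built = builder()
        assert loaded.species == built.species
        assert loaded.reactions == built.reactions


def test_loaded_counts(tmp_path):
    ex = load_model(data_dir() / "examplenet")
    assert (len(ex.species), len(ex.reactions)) == (5, 6)
    cd = load_model(data_dir() / "cardiacdevnet")
    assert (len(cd.species), len(cd.reactions)) == (5, 7)
    assert cd.get_species("ISL1").yinit == 1.0


def test_blank_cells_fill_defaults(tmp_path):
    (tmp_path / "species.csv").write_text(
        "ID,name,Yinit,Ymax,tau\nA,Species A,,,\nB,Species B,0.5,2,3\n"
    )
    (tmp_path / "reactions.csv").write_text(
        "module,ID,Rule,Weight,n,EC50\nm,r1,=> A,1,,\nm,r2,A => B,0.5,2,0.3\n"
    )
    model = load_model(tmp_path)
    a = model.get_species("A")
    assert (a.yinit, a.ymax, a.tau) == (0.0, 1.0, 1.0)
    r1 = model.get_reaction("r1")
    assert (r1.n, r1.ec50) == (1.4, 0.5)
    assert model.get_reaction("r2").n == 2.0


def test_blank_weight_is_an_error(tmp_path):
    (tmp_path / "species.csv").write_text("ID,name\nA,Species A\n")
    (tmp_path / "reactions.csv").write_text("module,ID,Rule,Weight\nm,r1,=> A,\n")
    with pytest.raises(ModelIOError, match="Weight"):
        load_model(tmp_path)


def test_headers_match_case_insensitively(tmp_path):
    (tmp_path / "species.csv").write_text("id,NAME,yinit,YMAX,Tau\nA,Species A,0,1,1\n")
    (tmp_path / "reactions.csv").write_text("MODULE,id,rule,weight,N,ec50\nm,r1,=> A,1,1.4,0.5\n")
    model = load_model(tmp_path)
    assert model.species_ids() == ["A"]
    assert model.get_reaction("r1").weight == 1.0


def test_workbook_sheet_names_match_case_insensitively(tmp_path, examplenet):
    path = tmp_path / "model.xlsx"
    from hillnet.model_io import _reactions_frame, _species_frame

    with pd.ExcelWriter(path) as writer:
        _species_frame(examplenet).to_excel(writer, sheet_name="Species", index=False)
        _reactions_frame(examplenet).to_excel(writer, sheet_name="REACTIONS", index=False)
    assert len(load_model(path).species) == 5


def test_unknown_columns_survive_round_trip(tmp_path):
    (tmp_path / "species.csv").write_text(
        "ID,name,Yinit,Ymax,tau,citation\nA,Species A,0,1,1,PMID:123\n"
    )
    (tmp_path / "reactions.csv").write_text(
        "module,ID,Rule,Weight,n,EC50,note\nm,r1,=> A,1,1.4,0.5,seed stimulus\n"
    )
    model = load_model(tmp_path)
    assert model.metadata["species_columns"]["citation"]["A"] == "PMID:123"
    out = tmp_path / "copy"
    write_model(model, out, dialect="csv")
    again = load_model(out)
    assert again.metadata == model.metadata


def test_missing_table_errors_name_the_sheet(tmp_path, examplenet):
    path = tmp_path / "model.xlsx"
    from hillnet.model_io import _species_frame

    with pd.ExcelWriter(path) as writer:
        _species_frame(examplenet).to_excel(writer, sheet_name="species", index=False)
    with pytest.raises(ModelIOError, match="reactions"):
        load_model(path)


def test_empty_species_sheet_is_an_error(tmp_path):
    (tmp_path / "species.csv").write_text("ID,name,Yinit,Ymax,tau\n")
    (tmp_path / "reactions.csv").write_text("module,ID,Rule,Weight,n,EC50\n")
    with pytest.raises(ModelIOError, match="species"):
        load_model(tmp_path)


def test_load_reports_rule_errors_with_coordinates(tmp_path):
    (tmp_path / "species.csv").write_text("ID,name\nA,Species A\n")
    (tmp_path / "reactions.csv").write_text("module,ID,Rule,Weight\nm,r1,A =>,1\n")
    with pytest.raises(ModelIOError, match=r"row 2"):
        load_model(tmp_path)


def test_missing_file_raises_file_error(tmp_path):
    with pytest.raises(FileNotFoundError):
        load_model(tmp_path / "nope.xlsx")


# ---------------------------------------------------------------------------
# Edge export
# ---------------------------------------------------------------------------

def test_examplenet_edge_table(examplenet):
    lines = export_edges(examplenet, format="sif").strip().split("\n")
    # 2 input reactions + 5 (reaction, regulator) pairs
    assert len(lines) == 7
    assert lines[0] == "INPUT_A\tinput\tA"
    assert "C\tactivates\tE" in lines
    assert "D\tinhibits\tE" in lines


def test_cardiacdevnet_edge_table(cardiacdevnet):
    lines = export_edges(cardiacdevnet, format="sif").strip().split("\n")
    assert len(lines) == 7  # 1 input + 6 regulator edges
    assert "NKX25\tinhibits\tISL1" in lines


def test_edge_count_identity(examplenet, cardiacdevnet):
    for model in (examplenet, cardiacdevnet):
        expected = sum(len(r.regulators) or 1 for r in model.reactions)
        lines = export_edges(model, format="sif").strip().split("\n")
        assert len(lines) == expected


def test_tsv_export_has_header_and_provenance(examplenet):
    lines = export_edges(examplenet, format="tsv").strip().split("\n")
    assert lines[0] == "source\tinteraction\ttarget\treaction_id"
    assert lines[1].endswith("\tr1")
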