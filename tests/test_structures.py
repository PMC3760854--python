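import numpy as np
import pytest

from pepbind.errors import ChainNotFoundError, FormatError
from pepbind.structures import (
    Atom,
    SequenceRecord,
    StructureModel,
    compute_search_box,
    format_box_config,
    parse_pdb,
    read_box_config,
    read_fasta,
    strip_chain,
    write_fasta,
    write_pdb,
)
from pepbind.synthetic import gen_toy_pdb


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def test_read_fasta_parses_normalises_and_preserves_order(tmp_path):
    path = tmp_path / "in.fasta"
    path.write_text(">p\nACDEF\n>q lowercase\nacd ef\n")
    records = read_fasta(path)
    assert [(r.id, r.seq) for r in records] == [("p", "ACDEF"), ("q", "ACDEF")]


def test_read_fasta_rejects_empty_sequence_and_bad_letters(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text(">p\n\n>q\nACDEF\n")
    with pytest.raises(FormatError, match="p"):
        read_fasta(path)
    path.write_text(">z\nAC1EF\n")
    with pytest.raises(FormatError, match="z"):
        read_fasta(path)


def test_fasta_round_trip(tmp_path):
    records = [SequenceRecord("a", "ACDEFGHIKL"), SequenceRecord("b", "MNPQRSTVWYX")]
    path = tmp_path / "out.fasta"
    write_fasta(records, path)
    assert read_fasta(path) == records


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def test_parse_toy_pdb_builds_chain_index(toy_pdb_path):
    model = parse_pdb(toy_pdb_path)
    assert model.chains == ["A", "B"]
    assert len(model.chain_atoms("B")) == 3
    assert all(np.isfinite(a.coord).all() for a in model.atoms)


def test_parse_pdb_empty_file_errors(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(FormatError):
        parse_pdb(path)


def test_parse_pdb_reports_bad_coordinate_with_line_number(tmp_path):
    good = gen_toy_pdb(seed=0)
    lines = good.splitlines()
    idx = next(i for i, l in enumerate(lines) if l.startswith("ATOM"))
    lines[idx] = lines[idx][:30] + "  badnum" + lines[idx][38:]
    path = tmp_path / "bad.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(FormatError, match=f":{idx + 1}:"):
        parse_pdb(path)


def test_parse_pdb_hetatm_only_gives_empty_chain_index(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(
        "HETATM    1  O   HOH W   1       1.000   2.000   3.000  1.00  0.00           O\n"
        "END\n"
    )
    model = parse_pdb(path)
    assert model.chains == []
    assert len(model) == 1 and model.atoms[0].hetero


# ---------------------------------------------------------------------------
# Search box
# ---------------------------------------------------------------------------

def _cube_model():
    # peptide chain B spanning [0, 10] on every axis
    atoms = [Atom("A", 1, "GLY", "CA", 20.0, 20.0, 20.0)]
    corners = [(0, 0, 0), (10, 10, 10), (0, 10, 0), (10, 0, 10)]
    atoms += [
        Atom("B", i + 1, "ALA", "CA", float(x), float(y), float(z))
        for i, (x, y, z) in enumerate(corners)
    ]
    return StructureModel(atoms=atoms)


def test_search_box_is_padded_bounding_box():
    box = compute_search_box(_cube_model(), "B", padding=4.0)
    assert box.centre == (5.0, 5.0, 5.0)
    assert box.dims == (18.0, 18.0, 18.0)


def test_search_box_single_atom_degenerates_to_padding():
    model = StructureModel(atoms=[Atom("B", 1, "ALA", "CA", 1.0, 2.0, 3.0)])
    box = compute_search_box(model, "B", padding=4.0)
    assert box.centre == (1.0, 2.0, 3.0)
    assert box.dims == (8.0, 8.0, 8.0)


def test_search_box_clamps_oversized_edges_with_warning():
    atoms = [Atom("B", 1, "ALA", "CA", 0.0, 0.0, 0.0), Atom("B", 2, "ALA", "CA", 40.0, 1.0, 1.0)]
    with pytest.warns(UserWarning, match="clamped"):
        box = compute_search_box(StructureModel(atoms=atoms), "B", padding=5.0, max_edge=30.0)
    assert box.dims[0] == 30.0
    assert box.dims[1] == 11.0


def test_search_box_missing_or_empty_chain_errors():
    with pytest.raises(ChainNotFoundError):
        compute_search_box(_cube_model(), "Z")


def test_unclamped_box_contains_every_peptide_atom(rng):
    # containment property over random structures
    for trial in range(20):
        coords = rng.uniform(-30, 30, size=(rng.integers(1, 12), 3))
        atoms = [
            Atom("B", i + 1, "ALA", "CA", *map(float, c)) for i, c in enumerate(coords)
        ]
        box = compute_search_box(
            StructureModel(atoms=atoms), "B", padding=3.0, max_edge=1e9
        )
        assert all(box.contains(c) for c in coords)


# ---------------------------------------------------------------------------
# Chain stripping
# ---------------------------------------------------------------------------

def test_strip_chain_removes_exactly_that_chain(toy_pdb_path):
    model = parse_pdb(toy_pdb_path)
    stripped = strip_chain(model, "B")
    assert stripped.chains == ["A"]
    assert len(stripped) + len(model.chain_atoms("B", include_hetero=True)) == len(model)
    with pytest.raises(ChainNotFoundError):
        strip_chain(stripped, "B")  # idempotence: the chain is gone


def test_strip_last_chain_warns_and_returns_empty():
    model = StructureModel(atoms=[Atom("A", 1, "GLY", "CA", 0.0, 0.0, 0.0)])
    with pytest.warns(UserWarning, match="empty"):
        out = strip_chain(model, "A")
    assert len(out) == 0


def test_pdb_write_parse_round_trip(tmp_path, toy_pdb_path):
    model = parse_pdb(toy_pdb_path)
    stripped = strip_chain(model, "B")
    out = tmp_path / "receptor.pdb"
    write_pdb(stripped, out)
    reparsed = parse_pdb(out)
    original = [(a.chain, a.res_seq, a.name) + tuple(np.round(a.coord, 3)) for a in stripped.atoms]
    recovered = [(a.chain, a.res_seq, a.name) + tuple(np.round(a.coord, 3)) for a in reparsed.atoms]
    assert recovered == original


# ---------------------------------------------------------------------------
# Box config block
# ---------------------------------------------------------------------------

def test_box_config_round_trip(tmp_path):
    box = compute_search_box(_cube_model(), "B", padding=4.0)
    text = format_box_config(box)
    assert "center_x = 5.000" in text and "size_z = 18.000" in text
    path = tmp_path / "box.cfg"
    path.write_text(text)
    recovered = read_box_config(path)
    assert recovered.centre == box.centre
    assert recovered.dims == box.dims
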