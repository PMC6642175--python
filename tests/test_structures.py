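"""Interface geometry: parsing, SEQRES validation and the 5 A contact rule."""

import math

import numpy as np
import pytest

from edgotype.structures import (
    Atom,
    ChainStructure,
    Residue,
    compute_interface,
    parse_chain,
    read_interfaces_tsv,
    residue_min_distance,
    write_interfaces_tsv,
)
from edgotype.synthetic import generate_toy_dimer, write_pdb

from conftest import brute_force_interface


def _res(pos, aa, *coords):
    return Residue(pos, aa, tuple(Atom("CA", *c) for c in coords))


class TestResidueMinDistance:
    def test_single_atoms_345_triangle(self):
        a = _res(1, "A", (0, 0, 0))
        b = _res(2, "G", (3, 4, 0))
        assert residue_min_distance(a, b) == pytest.approx(5.0)

    def test_minimum_over_atom_pairs(self):
        a = _res(1, "A", (0, 0, 0), (10, 0, 0))
        b = _res(2, "G", (0, 0, 2))
        assert residue_min_distance(a, b) == pytest.approx(2.0)

    def test_symmetric_and_matches_double_loop(self):
        rng = np.random.default_rng(3)
        a = Residue(1, "A", tuple(Atom("CA", *xyz) for xyz in rng.normal(size=(10, 3))))
        b = Residue(2, "G", tuple(Atom("CA", *xyz) for xyz in rng.normal(size=(10, 3))))
        expected = min(
            math.dist((p.x, p.y, p.z), (q.x, q.y, q.z))
            for p in a.atoms
            for q in b.atoms
        )
        assert residue_min_distance(a, b) == pytest.approx(expected)
        assert residue_min_distance(b, a) == pytest.approx(expected)

    def test_empty_atoms_rejected(self):
        with pytest.raises(ValueError):
            Residue(1, "A", ())


class TestParseChain:
    def _write(self, tmp_path, text):
        path = tmp_path / "toy.pdb"
        path.write_text(text)
        return path

    def test_parse_roundtrip_of_generated_dimer(self, tmp_path):
        chain_a, chain_b = generate_toy_dimer(5, 4, 2, seed=0)
        path = tmp_path / "dimer.pdb"
        write_pdb([chain_a, chain_b], path)
        parsed = parse_chain(path, "TOY0", "A", chain_a.seqres)
        assert [r.seqres_position for r in parsed.residues] == [1, 2, 3, 4, 5]
        assert parsed.n_discarded == 0
        got = parsed.residues[0].atoms[0]
        want = chain_a.residues[0].atoms[0]
        assert got.coord == pytest.approx(want.coord, abs=1e-3)

    def test_first_model_rule(self, tmp_path):
        lines = ["MODEL     1"]
        lines.append(
            "ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C"
        )
        lines += ["ENDMDL", "MODEL     2"]
        lines.append(
            "ATOM      2  CA  ALA A   1      99.000   0.000   0.000  1.00  0.00           C"
        )
        lines += ["ENDMDL", "END"]
        path = self._write(tmp_path, "\n".join(lines) + "\n")
        chain = parse_chain(path, "X", "A", "A")
        assert chain.residues[0].atoms[0].x == pytest.approx(1.0)

    def test_seqres_mismatch_dropped(self, tmp_path):
        # residue 2 claims LYS where the backbone says ARG
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  LYS A   2       4.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = self._write(tmp_path, text)
        chain = parse_chain(path, "X", "A", "AR")
        assert [r.seqres_position for r in chain.residues] == [1]
        assert chain.n_discarded == 1

    def test_missing_chain_is_lookup_error(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = self._write(tmp_path, text)
        with pytest.raises(KeyError):
            parse_chain(path, "X", "B", "A")

    def test_mixed_valid_and_mismatched_residues(self, tmp_path):
        chain_a, _ = generate_toy_dimer(6, 4, 0, seed=5)
        path = tmp_path / "d.pdb"
        write_pdb([chain_a], path)
        # corrupt the last residue's name in-place
        lines = path.read_text().splitlines()
        target = chain_a.seqres[5]
        bad = "GLY" if target != "G" else "ALA"
        out = []
        for ln in lines:
            if ln.startswith("ATOM") and int(ln[22:26]) == 6:
                ln = ln[:17] + bad + ln[20:]
            out.append(ln)
        path.write_text("\n".join(out) + "\n")
        chain = parse_chain(path, "TOY0", "A", chain_a.seqres)
        assert len(chain.residues) == 5
        assert chain.n_discarded == 1


class TestComputeInterface:
    def test_counts_match_construction(self):
        chain_a, chain_b = generate_toy_dimer(10, 8, 3, seed=7)
        pair = compute_interface(chain_a, chain_b)
        assert len(pair.interface_a) == 3
        assert len(pair.interface_b) == 3

    def test_disjoint_chains(self):
        chain_a, chain_b = generate_toy_dimer(6, 6, 0, seed=2)
        pair = compute_interface(chain_a, chain_b)
        assert pair.interface_a == frozenset() and pair.interface_b == frozenset()

    def test_translated_copy_has_no_interface(self):
        chain_a, _ = generate_toy_dimer(8, 8, 0, seed=4)
        far = ChainStructure(
            chain_a.structure_id,
            "B",
            chain_a.seqres,
            [
                Residue(
                    r.seqres_position,
                    r.amino_acid,
                    tuple(Atom(a.name, a.x + 100.0, a.y, a.z) for a in r.atoms),
                )
                for r in chain_a.residues
            ],
        )
        pair = compute_interface(chain_a, far)
        assert not pair.interface_a and not pair.interface_b

    @pytest.mark.parametrize("cutoff", [4.0, 5.0, 6.0])
    def test_matches_brute_force_oracle(self, cutoff):
        chain_a, chain_b = generate_toy_dimer(30, 25, 6, seed=13)
        pair = compute_interface(chain_a, chain_b, cutoff=cutoff)
        oracle_a, oracle_b = brute_force_interface(chain_a, chain_b, cutoff)
        assert set(pair.interface_a) == oracle_a
        assert set(pair.interface_b) == oracle_b

    def test_inclusive_at_exact_cutoff(self):
        a = ChainStructure("X", "A", "A", [_res(1, "A", (0, 0, 0))])
        b = ChainStructure("X", "B", "G", [_res(1, "G", (5.0, 0, 0))])
        pair = compute_interface(a, b, cutoff=5.0)
        assert pair.interface_a == frozenset({1})

    def test_monotone_in_cutoff(self):
        chain_a, chain_b = generate_toy_dimer(20, 20, 5, seed=9)
        small = compute_interface(chain_a, chain_b, cutoff=4.0)
        large = compute_interface(chain_a, chain_b, cutoff=6.0)
        assert small.interface_a <= large.interface_a
        assert small.interface_b <= large.interface_b

    def test_symmetry(self):
        chain_a, chain_b = generate_toy_dimer(15, 12, 4, seed=21)
        ab = compute_interface(chain_a, chain_b)
        ba = compute_interface(chain_b, chain_a)
        assert ab.interface_a == ba.interface_b
        assert ab.interface_b == ba.interface_a

    def test_heavy_only_drops_hydrogen_contacts(self):
        a = ChainStructure(
            "X", "A", "A",
            [Residue(1, "A", (Atom("CA", 0, 0, 0), Atom("H1", 7.0, 0, 0)))],
        )
        b = ChainStructure("X", "B", "G", [_res(1, "G", (10.0, 0, 0))])
        assert compute_interface(a, b).interface_a == frozenset({1})
        assert compute_interface(a, b, heavy_only=True).interface_a == frozenset()


def test_interface_tsv_roundtrip(tmp_path):
    chain_a, chain_b = generate_toy_dimer(10, 10, 3, seed=1)
    pair = compute_interface(chain_a, chain_b)
    path = tmp_path / "ifaces.tsv"
    write_interfaces_tsv([pair], path)
    catalog = read_interfaces_tsv(path)
    assert catalog[("TOY0", "A", "B")] == (pair.interface_a, pair.interface_b)
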