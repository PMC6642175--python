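"""Chain coordinates, SEQRES validation and binding-interface geometry.

Two residues are considered in contact when the minimum Euclidean distance
over all pairs of their atoms is within a cutoff (default 5 Angstrom,
inclusive).  A residue of one chain is an interface residue for a chain pair
when it is in contact with at least one residue of the partner chain.
Residue positions are 1-based indices into the chain's declared backbone
(SEQRES) sequence throughout; insertion codes are not part of the dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "Residue",
    "ChainStructure",
    "InterfacePair",
    "parse_chain",
    "residue_min_distance",
    "compute_interface",
    "write_interfaces_tsv",
    "read_interfaces_tsv",
]


@dataclass(frozen=True)
class Atom:
    name: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Residue:
    seqres_position: int  # 1-based index into the SEQRES sequence
    amino_acid: str  # one-letter code
    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(
                f"residue {self.seqres_position} must carry at least one atom"
            )

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


@dataclass
class ChainStructure:
    """One chain's backbone sequence plus per-residue atom coordinates."""

    structure_id: str
    chain_id: str
    seqres: str
    residues: list[Residue] = field(default_factory=list)
    n_discarded: int = 0  # residues dropped at parse time for SEQRES mismatch

    def __post_init__(self) -> None:
        last = 0
        for res in self.residues:
            if not 1 <= res.seqres_position <= len(self.seqres):
                raise ValueError(
                    f"residue position {res.seqres_position} outside SEQRES "
                    f"of length {len(self.seqres)}"
                )
            if self.seqres[res.seqres_position - 1] != res.amino_acid:
                raise ValueError(
                    f"residue {res.seqres_position} is {res.amino_acid!r} but "
                    f"SEQRES says {self.seqres[res.seqres_position - 1]!r}"
                )
            if res.seqres_position <= last:
                raise ValueError("residue positions must be strictly increasing")
            if not res.atoms:
                raise ValueError(f"residue {res.seqres_position} has no atoms")
            last = res.seqres_position

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure_id, self.chain_id)


@dataclass
class InterfacePair:
    """Interface residue positions for one chain pair of one structure."""

    chain_a: ChainStructure
    chain_b: ChainStructure
    interface_a: frozenset[int]
    interface_b: frozenset[int]


def parse_chain(
    coordinate_file: str | Path,
    structure_id: str,
    chain_id: str,
    seqres: str,
) -> ChainStructure:
    """Load one chain from a minimal PDB-dialect file and validate it.

    Only the first model is read.  Residues whose residue name disagrees with
    the SEQRES letter at their (1-based) position are discarded and counted in
    ``n_discarded``; residues numbered outside the SEQRES range are discarded
    the same way.

    Raises
    ------
    KeyError
        If the requested chain is absent from the file.
    ValueError
        If the file cannot be parsed as PDB ATOM records.
    """
    path = Path(coordinate_file)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(structure_id, str(path))
    except Exception as exc:  # Bio.PDB raises bare exceptions on bad records
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    model = next(iter(structure))  # first-model rule
    if chain_id not in [c.id for c in model]:
        raise KeyError(f"chain {chain_id!r} not found in {path}")
    chain = model[chain_id]

    residues: list[Residue] = []
    n_discarded = 0
    for res in chain:
        if res.id[0] != " ":  # skip HETATM / waters
            continue
        pos = res.id[1]
        aa = seq1(res.get_resname().capitalize())
        atoms = tuple(
            Atom(a.get_name(), *(float(v) for v in a.coord)) for a in res
        )
        if not 1 <= pos <= len(seqres) or seqres[pos - 1] != aa:
            n_discarded += 1
            continue
        residues.append(Residue(pos, aa, atoms))
    residues.sort(key=lambda r: r.seqres_position)
    return ChainStructure(structure_id, chain_id, seqres, residues, n_discarded)


def residue_min_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum Euclidean distance over all atom pairs of two residues."""
    if not res_a.atoms or not res_b.atoms:
        raise ValueError("residues must carry at least one atom")
    ca = res_a.coords()
    cb = res_b.coords()
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def compute_interface(
    chain_a: ChainStructure,
    chain_b: ChainStructure,
    cutoff: float = 5.0,
    heavy_only: bool = False,
) -> InterfacePair:
    """Interface residues of two chains under the minimum-atom-distance rule.

    A position enters ``interface_a`` iff some residue of ``chain_b`` lies
    within ``cutoff`` (inclusive) of it, and symmetrically for ``interface_b``.
    All atoms present in the record are used by default; ``heavy_only=True``
    drops hydrogens first.
    """
    if chain_a.structure_id != chain_b.structure_id:
        warnings.warn(
            "computing an interface across different structures "
            f"({chain_a.structure_id} vs {chain_b.structure_id})",
            stacklevel=2,
        )
    res_a = _usable_residues(chain_a, heavy_only)
    res_b = _usable_residues(chain_b, heavy_only)
    if not res_a or not res_b:
        warnings.warn("empty chain: interfaces are empty", stacklevel=2)
        return InterfacePair(chain_a, chain_b, frozenset(), frozenset())

    coords_a, idx_a = _stack_atoms(res_a)
    coords_b, idx_b = _stack_atoms(res_b)
    # all-atom cross distances, reduced to per-residue-pair minima
    d2 = ((coords_a[:, None, :] - coords_b[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= cutoff * cutoff
    iface_a = {res_a[i].seqres_position for i in idx_a[within.any(axis=1)]}
    iface_b = {res_b[j].seqres_position for j in idx_b[within.any(axis=0)]}
    return InterfacePair(chain_a, chain_b, frozenset(iface_a), frozenset(iface_b))


def _usable_residues(chain: ChainStructure, heavy_only: bool) -> list[Residue]:
    if not heavy_only:
        return list(chain.residues)
    out = []
    for res in chain.residues:
        atoms = tuple(a for a in res.atoms if not a.name.startswith("H"))
        if atoms:
            out.append(Residue(res.seqres_position, res.amino_acid, atoms))
    return out


def _stack_atoms(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    coords = np.concatenate([r.coords() for r in residues])
    idx = np.concatenate(
        [np.full(len(r.atoms), i) for i, r in enumerate(residues)]
    )
    return coords, idx


def write_interfaces_tsv(pairs: list[InterfacePair], path: str | Path) -> None:
    """One row per interface residue: structure, chains, side, position."""
    with open(path, "w") as fh:
        fh.write("structure_id\tchain_a\tchain_b\tside\tposition\n")
        for p in pairs:
            sid = p.chain_a.structure_id
            ca, cb = p.chain_a.chain_id, p.chain_b.chain_id
            for pos in sorted(p.interface_a):
                fh.write(f"{sid}\t{ca}\t{cb}\ta\t{pos}\n")
            for pos in sorted(p.interface_b):
                fh.write(f"{sid}\t{ca}\t{cb}\tb\t{pos}\n")


def read_interfaces_tsv(
    path: str | Path,
) -> dict[tuple[str, str, str], tuple[frozenset[int], frozenset[int]]]:
    """Inverse of :func:`write_interfaces_tsv`, keyed by (structure, chain_a, chain_b)."""
    table: dict[tuple[str, str, str], tuple[set[int], set[int]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["structure_id", "chain_a", "chain_b", "side", "position"]:
            raise ValueError(f"unexpected interface TSV header in {path}")
        for line in fh:
            sid, ca, cb, side, pos = line.rstrip("\n").split("\t")
            sides = table.setdefault((sid, ca, cb), (set(), set()))
            sides[0 if side == "a" else 1].add(int(pos))
    return {
        key: (frozenset(a), frozenset(b)) for key, (a, b) in table.items()
    }
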