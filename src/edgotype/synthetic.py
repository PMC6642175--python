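"""Synthetic study inputs with known ground truth.

Generates a complete, internally consistent set of inputs — chain
coordinates realizing declared interfaces under the 5 Å rule, identity
alignments, a reference interactome, curated mutation tables, per-(mutation,
PPI) binding free-energy changes, and GO/expression side tables — from a
handful of ground-truth parameters: the class-wise probabilities for a
mutation to fall on an interface (``true_pEgivenN``, ``true_pEgivenM``) and
the class-wise probabilities for an interfacial mutation to disrupt its PPI
(``gamma_N``, ``gamma_M``).  Defaults mirror the rates measured on the
Y2H-derived structural interactome: interfacial placement 5.1% / 18.6% and
disruption 60% / 66% for non-disease / disease mutations, with 376 and 145
mutations respectively.

Geometry is a jittered lattice of Cα-plus-dummy-side-chain atoms: chains
run along parallel lines 30 Å apart, and each declared contact pair is
realized by relocating the partner residue to ~4.2 Å while every other
inter-chain residue distance stays above a 6 Å guard band.  Only inter-atom
distances matter to interface detection, so no attempt at stereochemistry
is made.

ΔΔG values are drawn from class-truncated Gaussians: with probability gamma
the value comes from the destabilizing component truncated above the
0.5 kcal/mol disruption threshold, otherwise from the neutral component
truncated below it — so the exceedance probability equals gamma exactly.

A single integer seed drives per-stage substreams (sequences, topology,
structures, mutations, ΔΔG, side tables), so e.g. requesting more mutations
does not perturb structure generation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.special import ndtr, ndtri

from .edgotypes import DDGRecord, write_ddg_tsv
from .interactome import AlignmentHit, write_edges_tsv, write_hits_tsv
from .mutations import Curation, MutationRecord, write_mutations_tsv
from .structures import Atom, ChainStructure, Residue
from .qc import ExpressionMatrix, GoAnnotationSet

import pandas as pd

__all__ = [
    "ConfigurationError",
    "GenerationError",
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "generate_world",
    "generate_toy_dimer",
    "go_annotation_set",
    "expression_matrix",
    "write_pdb",
    "write_world",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CHAIN_SPACING = 10.0  # Å between consecutive residues along a chain
CHAIN_SEPARATION = 30.0  # Å between non-contacting chains
CONTACT_DISTANCE = 4.2  # Å target Cα-Cα distance for a declared contact
JITTER = 0.2  # Å max coordinate jitter


class ConfigurationError(ValueError):
    """A configuration field violates its invariant."""


class GenerationError(RuntimeError):
    """The requested world or geometry cannot be realized."""


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Ground-truth parameters of a synthetic world.

    Probabilities are in [0, 1]; counts are >= 1; ΔΔG means must straddle
    the 0.5 kcal/mol disruption threshold so the threshold rule is
    exercisable.
    """

    n_proteins: int = 573
    n_ppis: int = 486
    mean_protein_length: int = 150
    interface_width: int = 10  # contact residues per chain side
    true_pEgivenN: float = 0.051
    true_pEgivenM: float = 0.186
    gamma_N: float = 0.60
    gamma_M: float = 0.66
    ddg_disrupt_mean: float = 1.5  # kcal/mol
    ddg_neutral_mean: float = -0.2  # kcal/mol
    ddg_sd: float = 0.8  # kcal/mol
    n_disease_mut: int = 145
    n_nondisease_mut: int = 376
    n_decoy_hits: int = 0  # sub-threshold alignment hits, to exercise filters
    n_tissues: int = 16
    seed: int = 0

    def validate(self) -> None:
        for name in ("true_pEgivenN", "true_pEgivenM", "gamma_N", "gamma_M"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        for name in (
            "n_proteins",
            "n_ppis",
            "mean_protein_length",
            "interface_width",
            "n_disease_mut",
            "n_nondisease_mut",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not self.ddg_disrupt_mean > 0.5 > self.ddg_neutral_mean:
            raise ConfigurationError(
                "ddg_disrupt_mean must exceed 0.5 kcal/mol and "
                "ddg_neutral_mean must fall below it"
            )
        if self.ddg_sd <= 0:
            raise ConfigurationError("ddg_sd must be positive")
        if self.n_ppis > self.n_proteins * (self.n_proteins - 1) // 2:
            raise ConfigurationError("n_ppis exceeds the number of protein pairs")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticWorldConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    protein_sequences: dict[str, str]
    structures: list[tuple[ChainStructure, ChainStructure]]
    alignments: list[AlignmentHit]
    interactome: list[tuple[str, str]]
    mutations: list[MutationRecord]
    ddg_table: list[DDGRecord]
    go_dag: dict[str, frozenset[str]]
    go_annotations: dict[str, frozenset[str]]
    expression: pd.DataFrame  # protein x tissue
    #: ground-truth interface positions per PPI (protein_a side, protein_b side)
    declared_interfaces: dict[tuple[str, str], tuple[frozenset[int], frozenset[int]]]
    #: per-mutation ground truth: interfacial flag, covering PPIs, PPIs
    #: whose ΔΔG exceeds the disruption threshold
    truth: dict[str, dict]


def _jittered(rng: np.random.Generator, base: np.ndarray) -> np.ndarray:
    return base + rng.uniform(-JITTER, JITTER, size=3)


def _build_chain(
    structure_id: str,
    chain_id: str,
    seqres: str,
    positions: dict[int, np.ndarray],
    rng: np.random.Generator,
) -> ChainStructure:
    residues = []
    for pos in sorted(positions):
        base = positions[pos]
        ca = _jittered(rng, base)
        cb = _jittered(rng, base + np.array([0.5, 0.5, 0.3]))
        residues.append(
            Residue(
                pos,
                seqres[pos - 1],
                (Atom("CA", *ca), Atom("CB", *cb)),
            )
        )
    return ChainStructure(structure_id, chain_id, seqres, residues)


def _build_dimer(
    structure_id: str,
    seq_a: str,
    seq_b: str,
    contacts_a: list[int],
    contacts_b: list[int],
    rng: np.random.Generator,
) -> tuple[ChainStructure, ChainStructure]:
    """Two lattice chains where exactly the k-th contact positions of each
    chain sit within the 5 Å rule of each other."""
    if len(contacts_a) != len(contacts_b):
        raise GenerationError("contact lists must pair up one-to-one")
    pos_a = {
        i: np.array([CHAIN_SPACING * (i - 1), 0.0, 0.0]) for i in range(1, len(seq_a) + 1)
    }
    pos_b = {
        j: np.array([CHAIN_SPACING * (j - 1), 3.0, CHAIN_SEPARATION])
        for j in range(1, len(seq_b) + 1)
    }
    for a, b in zip(contacts_a, contacts_b):
        # partner residue relocated under the contact residue of chain A
        pos_b[b] = np.array([CHAIN_SPACING * (a - 1), 0.0, CONTACT_DISTANCE])
    chain_a = _build_chain(structure_id, "A", seq_a, pos_a, rng)
    chain_b = _build_chain(structure_id, "B", seq_b, pos_b, rng)
    return chain_a, chain_b


def generate_toy_dimer(
    n_res_a: int, n_res_b: int, n_contact: int, seed: int
) -> tuple[ChainStructure, ChainStructure]:
    """A two-chain fixture with exactly ``n_contact`` interface residues per
    chain under the 5 Å rule and a > 6 Å guard band everywhere else."""
    if n_contact > min(n_res_a, n_res_b):
        raise GenerationError(
            f"cannot place {n_contact} contacts on chains of "
            f"{n_res_a} and {n_res_b} residues"
        )
    rng = np.random.default_rng(seed)
    seq_a = "".join(rng.choice(list(AMINO_ACIDS), size=n_res_a))
    seq_b = "".join(rng.choice(list(AMINO_ACIDS), size=n_res_b))
    contacts_a = sorted(rng.choice(np.arange(1, n_res_a + 1), size=n_contact, replace=False))
    contacts_b = sorted(rng.choice(np.arange(1, n_res_b + 1), size=n_contact, replace=False))
    return _build_dimer("TOY0", seq_a, seq_b, list(map(int, contacts_a)), list(map(int, contacts_b)), rng)


def _truncated_ddg(
    rng: np.random.Generator, disrupt: bool, cfg: SyntheticWorldConfig
) -> float:
    """Class-conditional ΔΔG draw truncated at the disruption threshold
    (inverse-CDF sampling of a one-sided truncated Gaussian)."""
    u = rng.random()
    if disrupt:
        alpha = ndtr((0.5 - cfg.ddg_disrupt_mean) / cfg.ddg_sd)
        q = alpha + u * (1.0 - alpha)  # mass above the threshold
        return cfg.ddg_disrupt_mean + cfg.ddg_sd * float(ndtri(q))
    beta = ndtr((0.5 - cfg.ddg_neutral_mean) / cfg.ddg_sd)
    return cfg.ddg_neutral_mean + cfg.ddg_sd * float(ndtri(u * beta))


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a complete synthetic world; deterministic for a fixed seed."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_seq, rng_topo, rng_struct, rng_mut, rng_ddg, rng_side = (
        np.random.default_rng(s) for s in streams
    )

    # --- proteins ---------------------------------------------------------
    n = config.n_proteins
    ids = [f"P{i:04d}" for i in range(1, n + 1)]
    min_len = max(30, 2 * config.interface_width + 10)
    lengths = rng_seq.integers(
        max(min_len, int(0.8 * config.mean_protein_length)),
        int(1.2 * config.mean_protein_length) + 1,
        size=n,
    )
    sequences = {
        pid: "".join(rng_seq.choice(list(AMINO_ACIDS), size=int(L)))
        for pid, L in zip(ids, lengths)
    }

    # --- interactome topology --------------------------------------------
    all_pairs_needed = config.n_ppis
    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    while len(edges) < all_pairs_needed:
        i, j = rng_topo.integers(0, n, size=2)
        if i == j:
            continue
        key = frozenset((ids[i], ids[j]))
        if key in seen:
            continue
        seen.add(key)
        pa, pb = sorted((ids[i], ids[j]))
        edges.append((pa, pb))

    # --- structures realizing declared interfaces -------------------------
    structures: list[tuple[ChainStructure, ChainStructure]] = []
    alignments: list[AlignmentHit] = []
    interfaces: dict[tuple[str, str], tuple[frozenset[int], frozenset[int]]] = {}
    for idx, (pa, pb) in enumerate(edges):
        sid = f"S{idx:04d}"
        seq_a, seq_b = sequences[pa], sequences[pb]
        w = config.interface_width
        ca = sorted(
            int(x) for x in rng_struct.choice(np.arange(1, len(seq_a) + 1), size=w, replace=False)
        )
        cb = sorted(
            int(x) for x in rng_struct.choice(np.arange(1, len(seq_b) + 1), size=w, replace=False)
        )
        chain_a, chain_b = _build_dimer(sid, seq_a, seq_b, ca, cb, rng_struct)
        structures.append((chain_a, chain_b))
        interfaces[(pa, pb)] = (frozenset(ca), frozenset(cb))
        for pid, cid, L in ((pa, "A", len(seq_a)), (pb, "B", len(seq_b))):
            alignments.append(
                AlignmentHit(
                    pid, sid, cid, 1e-50, tuple((k, k) for k in range(1, L + 1))
                )
            )
    for d in range(config.n_decoy_hits):
        # sub-threshold hits that the E-value filter must remove
        pid = ids[int(rng_struct.integers(0, n))]
        sid = f"S{int(rng_struct.integers(0, len(edges))):04d}"
        alignments.append(
            AlignmentHit(pid, sid, "A", 1e-5, ((1, 1), (2, 2), (3, 3)))
        )

    # --- mutation placement -----------------------------------------------
    iface_by_protein: dict[str, dict[int, list[tuple[str, str]]]] = {}
    for (pa, pb), (ia, ib) in interfaces.items():
        for pid, side in ((pa, ia), (pb, ib)):
            slots = iface_by_protein.setdefault(pid, {})
            for pos in side:
                slots.setdefault(pos, []).append((pa, pb))

    iface_pool: list[tuple[str, int]] = [
        (pid, pos) for pid, slots in sorted(iface_by_protein.items()) for pos in sorted(slots)
    ]
    network_proteins = sorted({p for e in edges for p in e})
    noniface_pool: list[tuple[str, int]] = [
        (pid, pos)
        for pid in network_proteins
        for pos in range(1, len(sequences[pid]) + 1)
        if pos not in iface_by_protein.get(pid, {})
    ]
    rng_mut.shuffle(iface_pool)
    rng_mut.shuffle(noniface_pool)

    mutations: list[MutationRecord] = []
    truth: dict[str, dict] = {}

    def _place(mutation_id: str, mutation_class: str, p_iface: float) -> None:
        interfacial = rng_mut.random() < p_iface
        pool = iface_pool if interfacial else noniface_pool
        if not pool:
            raise GenerationError(
                "ran out of distinct positions; reduce mutation counts or "
                "enlarge proteins/interfaces"
            )
        pid, pos = pool.pop()
        wt = sequences[pid][pos - 1]
        mut = str(rng_mut.choice([a for a in AMINO_ACIDS if a != wt]))
        if mutation_class == "disease":
            curation = Curation(
                clinical_significance=frozenset({"pathogenic"}),
                review_stars=int(rng_mut.integers(1, 5)),
                conflicting=False,
            )
        else:
            curation = Curation(
                validated=True,
                withdrawn=False,
                maf=float(rng_mut.uniform(0.05, 0.5)),
            )
        mutations.append(
            MutationRecord(
                mutation_id, pid, sequences[pid], pos, wt, mut, mutation_class, curation
            )
        )
        covering = iface_by_protein.get(pid, {}).get(pos, []) if interfacial else []
        truth[mutation_id] = {
            "interfacial": interfacial,
            "protein_id": pid,
            "position": pos,
            "ppis": [list(k) for k in covering],
            "physics_disrupted": [],
        }

    for i in range(config.n_disease_mut):
        _place(f"D{i + 1:05d}", "disease", config.true_pEgivenM)
    for i in range(config.n_nondisease_mut):
        _place(f"N{i + 1:05d}", "non_disease", config.true_pEgivenN)

    # --- ΔΔG for interfacial (mutation, PPI) pairs -------------------------
    ddg_table: list[DDGRecord] = []
    for m in mutations:
        info = truth[m.mutation_id]
        if not info["interfacial"]:
            continue
        gamma = config.gamma_M if m.mutation_class == "disease" else config.gamma_N
        for pa, pb in info["ppis"]:
            disrupt = bool(rng_ddg.random() < gamma)
            value = _truncated_ddg(rng_ddg, disrupt, config)
            ddg_table.append(DDGRecord(m.mutation_id, pa, pb, value))
            if disrupt:
                info["physics_disrupted"].append([pa, pb])

    # --- GO and expression side tables -------------------------------------
    root = "T:root"
    go_dag: dict[str, frozenset[str]] = {root: frozenset()}
    go_annotations: dict[str, set[str]] = {pid: set() for pid in network_proteins}
    for idx, (pa, pb) in enumerate(edges):
        term = f"T:ppi{idx:04d}"
        go_dag[term] = frozenset({root})
        go_annotations[pa].add(term)
        go_annotations[pb].add(term)
    for pid in network_proteins:
        term = f"T:{pid}"
        go_dag[term] = frozenset({root})
        go_annotations[pid].add(term)

    tissues = [f"tissue{t:02d}" for t in range(1, config.n_tissues + 1)]
    factors = {
        idx: rng_side.normal(size=config.n_tissues) for idx in range(len(edges))
    }
    ppis_of: dict[str, list[int]] = {}
    for idx, (pa, pb) in enumerate(edges):
        ppis_of.setdefault(pa, []).append(idx)
        ppis_of.setdefault(pb, []).append(idx)
    profiles = {}
    for pid in network_proteins:
        shared = sum((factors[i] for i in ppis_of.get(pid, [])), np.zeros(config.n_tissues))
        profiles[pid] = shared + 0.3 * rng_side.normal(size=config.n_tissues)
    expression = pd.DataFrame.from_dict(profiles, orient="index", columns=tissues)
    expression = expression.sort_index()

    world = SyntheticWorld(
        config=config,
        protein_sequences=sequences,
        structures=structures,
        alignments=alignments,
        interactome=edges,
        mutations=mutations,
        ddg_table=ddg_table,
        go_dag=go_dag,
        go_annotations={p: frozenset(ts) for p, ts in go_annotations.items()},
        expression=expression,
        declared_interfaces=interfaces,
        truth=truth,
    )
    return world


def go_annotation_set(world: SyntheticWorld) -> GoAnnotationSet:
    return GoAnnotationSet(world.go_dag, dict(world.go_annotations))


def expression_matrix(world: SyntheticWorld) -> ExpressionMatrix:
    return ExpressionMatrix(world.expression, source="rnaseq_log2")


# ---------------------------------------------------------------------------
# serialization


def _format_atom(serial: int, atom: Atom, resname: str, chain_id: str, resseq: int) -> str:
    name = f" {atom.name:<3}"[:4]
    return (
        f"ATOM  {serial:>5} {name}"
        f" {resname:>3} {chain_id}{resseq:>4}    "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {atom.name[0]:>2}\n"
    )


_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def write_pdb(chains: list[ChainStructure], path: str | Path) -> None:
    """Write chains as minimal PDB-dialect ATOM records (single model)."""
    serial = 1
    with open(path, "w") as fh:
        for chain in chains:
            for res in chain.residues:
                resname = _AA3[res.amino_acid]
                for atom in res.atoms:
                    fh.write(
                        _format_atom(serial, atom, resname, chain.chain_id, res.seqres_position)
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Serialize a world to plain-text files under ``outdir``.

    Layout: per-structure PDB files under structures/, proteins.fasta,
    alignments.tsv, interactome.tsv, mutations_disease.tsv,
    mutations_nondisease.tsv, ddg.tsv, go_dag.tsv, go_annotations.tsv,
    expression.tsv and a truth.json ground-truth sidecar.
    """
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    for chain_a, chain_b in world.structures:
        write_pdb([chain_a, chain_b], outdir / "structures" / f"{chain_a.structure_id}.pdb")

    with open(outdir / "proteins.fasta", "w") as fh:
        for pid in sorted(world.protein_sequences):
            fh.write(f">{pid}\n{world.protein_sequences[pid]}\n")

    write_hits_tsv(world.alignments, outdir / "alignments.tsv")
    write_edges_tsv(world.interactome, outdir / "interactome.tsv")
    write_mutations_tsv(
        [m for m in world.mutations if m.mutation_class == "disease"],
        outdir / "mutations_disease.tsv",
    )
    write_mutations_tsv(
        [m for m in world.mutations if m.mutation_class == "non_disease"],
        outdir / "mutations_nondisease.tsv",
    )
    write_ddg_tsv(world.ddg_table, outdir / "ddg.tsv")

    with open(outdir / "go_dag.tsv", "w") as fh:
        fh.write("term\tparent\n")
        for term in sorted(world.go_dag):
            parents = sorted(world.go_dag[term])
            if not parents:
                fh.write(f"{term}\t\n")
            for p in parents:
                fh.write(f"{term}\t{p}\n")
    with open(outdir / "go_annotations.tsv", "w") as fh:
        fh.write("protein_id\tterm\n")
        for pid in sorted(world.go_annotations):
            for term in sorted(world.go_annotations[pid]):
                fh.write(f"{pid}\t{term}\n")

    world.expression.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6f")

    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {"config": world.config.to_dict(), "mutations": world.truth},
            fh,
            indent=1,
            sort_keys=True,
        )
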