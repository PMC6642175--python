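"""Structural interactome construction.

Starting from a reference interactome edge list and protein-to-chain
alignment hits, each PPI is annotated with pairs of interacting chains from
one structure.  An annotation is kept when both proteins align to the two
chains with at least half of each chain's interface residues covered by the
alignment; up to five annotations with the smallest joint E-values are
retained per PPI and their mapped interfaces are merged.  PPIs with no
surviving annotation are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "AlignmentHit",
    "ChainPairAnnotation",
    "StructuralPPI",
    "filter_hits",
    "annotate_ppi",
    "build_structural_interactome",
    "read_edges_tsv",
    "write_edges_tsv",
    "read_hits_tsv",
    "write_hits_tsv",
    "write_structural_interactome_tsv",
    "read_structural_interactome_tsv",
]

logger = logging.getLogger(__name__)

EVALUE_CUTOFF = 1e-10
MIN_COVERAGE = 0.5
MAX_ANNOTATIONS = 5

InterfaceCatalog = dict[tuple[str, str, str], tuple[frozenset[int], frozenset[int]]]


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped-column alignment between a protein and a structure chain."""

    protein_id: str
    structure_id: str
    chain_id: str
    evalue: float
    pairs: tuple[tuple[int, int], ...]  # (protein_position, chain_seqres_position)

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")
        prev_p = prev_q = 0
        for p, q in self.pairs:
            if p <= prev_p or q <= prev_q:
                raise ValueError("aligned positions must be strictly increasing")
            prev_p, prev_q = p, q

    def chain_to_protein(self) -> dict[int, int]:
        return {q: p for p, q in self.pairs}


@dataclass
class ChainPairAnnotation:
    protein_a: str
    protein_b: str
    hit_a: AlignmentHit
    hit_b: AlignmentHit
    joint_evalue: float
    mapped_interface_a: frozenset[int]  # protein positions
    mapped_interface_b: frozenset[int]
    coverage_a: float
    coverage_b: float

    @property
    def structure_id(self) -> str:
        return self.hit_a.structure_id

    @property
    def sort_key(self) -> tuple:
        # smallest joint E-value first; deterministic lexicographic tie-break
        return (
            self.joint_evalue,
            self.structure_id,
            self.hit_a.chain_id,
            self.hit_b.chain_id,
        )


@dataclass
class StructuralPPI:
    """An interactome edge with residue-level interface annotation."""

    protein_a: str
    protein_b: str
    interface_a: frozenset[int]
    interface_b: frozenset[int]
    annotations: list[ChainPairAnnotation] = field(default_factory=list)

    def interface_of(self, protein_id: str) -> frozenset[int]:
        """Interface positions on the given protein's side (union for self-PPIs)."""
        if protein_id == self.protein_a == self.protein_b:
            return self.interface_a | self.interface_b
        if protein_id == self.protein_a:
            return self.interface_a
        if protein_id == self.protein_b:
            return self.interface_b
        raise KeyError(f"{protein_id} does not participate in this PPI")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


def filter_hits(
    hits: list[AlignmentHit], evalue_cutoff: float = EVALUE_CUTOFF
) -> list[AlignmentHit]:
    """Apply the E-value cutoff, then keep the best hit per (protein, chain).

    Ties on E-value are broken by the longer alignment, then lexicographically
    by chain identifier for cross-group stability.
    """
    kept: dict[tuple[str, str, str], AlignmentHit] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        key = (hit.protein_id, hit.structure_id, hit.chain_id)
        cur = kept.get(key)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            kept[key] = hit
    return sorted(
        kept.values(),
        key=lambda h: (h.protein_id, h.structure_id, h.chain_id),
    )


def _hit_rank(hit: AlignmentHit) -> tuple:
    return (hit.evalue, -len(hit.pairs), hit.chain_id)


def annotate_ppi(
    protein_a: str,
    protein_b: str,
    hits: list[AlignmentHit],
    interfaces: InterfaceCatalog,
    min_coverage: float = MIN_COVERAGE,
    max_annotations: int = MAX_ANNOTATIONS,
) -> StructuralPPI | None:
    """Annotate one PPI with chain pairs, or return None if none survives.

    ``interfaces`` maps (structure_id, chain_a, chain_b) to the chain-side
    interface position sets.  Coverage on each side is the fraction of that
    chain's interface residues that the alignment maps onto the protein.
    """
    by_chain: dict[tuple[str, str], dict[str, AlignmentHit]] = {}
    for hit in hits:
        by_chain.setdefault((hit.structure_id, hit.chain_id), {})[
            hit.protein_id
        ] = hit

    candidates: list[ChainPairAnnotation] = []
    for (sid, ca, cb), (iface_a, iface_b) in interfaces.items():
        if not iface_a or not iface_b:
            continue
        hits_a = by_chain.get((sid, ca), {})
        hits_b = by_chain.get((sid, cb), {})
        orientations = [(protein_a, protein_b)]
        if protein_a != protein_b:
            orientations.append((protein_b, protein_a))
        for first, second in orientations:
            if first not in hits_a or second not in hits_b:
                continue
            ann = _score_candidate(
                first, second, hits_a[first], hits_b[second], iface_a, iface_b
            )
            if ann.coverage_a >= min_coverage and ann.coverage_b >= min_coverage:
                candidates.append(ann)

    if not candidates:
        return None
    candidates.sort(key=lambda c: c.sort_key)
    retained = candidates[:max_annotations]

    iface_a: set[int] = set()
    iface_b: set[int] = set()
    for ann in retained:
        if protein_a == protein_b:
            # homodimer: both chains map onto the same protein
            iface_a.update(ann.mapped_interface_a | ann.mapped_interface_b)
            iface_b.update(ann.mapped_interface_a | ann.mapped_interface_b)
        elif ann.protein_a == protein_a:
            iface_a.update(ann.mapped_interface_a)
            iface_b.update(ann.mapped_interface_b)
        else:  # swapped orientation
            iface_a.update(ann.mapped_interface_b)
            iface_b.update(ann.mapped_interface_a)
    return StructuralPPI(
        protein_a, protein_b, frozenset(iface_a), frozenset(iface_b), retained
    )


def _score_candidate(
    prot_a: str,
    prot_b: str,
    hit_a: AlignmentHit,
    hit_b: AlignmentHit,
    iface_a: frozenset[int],
    iface_b: frozenset[int],
) -> ChainPairAnnotation:
    map_a = hit_a.chain_to_protein()
    map_b = hit_b.chain_to_protein()
    covered_a = frozenset(map_a[q] for q in iface_a if q in map_a)
    covered_b = frozenset(map_b[q] for q in iface_b if q in map_b)
    n_cov_a = sum(1 for q in iface_a if q in map_a)
    n_cov_b = sum(1 for q in iface_b if q in map_b)
    return ChainPairAnnotation(
        protein_a=prot_a,
        protein_b=prot_b,
        hit_a=hit_a,
        hit_b=hit_b,
        joint_evalue=hit_a.evalue * hit_b.evalue,
        mapped_interface_a=covered_a,
        mapped_interface_b=covered_b,
        coverage_a=n_cov_a / len(iface_a),
        coverage_b=n_cov_b / len(iface_b),
    )


def build_structural_interactome(
    edges: list[tuple[str, str]],
    hits: list[AlignmentHit],
    interfaces: InterfaceCatalog,
    evalue_cutoff: float = EVALUE_CUTOFF,
    min_coverage: float = MIN_COVERAGE,
    max_annotations: int = MAX_ANNOTATIONS,
) -> list[StructuralPPI]:
    """Resolve every annotatable edge of the reference interactome."""
    for edge in edges:
        if len(edge) != 2 or not all(isinstance(p, str) and p for p in edge):
            raise ValueError(f"malformed edge: {edge!r}")
    filtered = filter_hits(hits, evalue_cutoff)
    known_chains = {
        (sid, c) for (sid, ca, cb) in interfaces for c in (ca, cb)
    }
    for hit in filtered:
        if (hit.structure_id, hit.chain_id) not in known_chains:
            raise KeyError(
                f"hit references chain {hit.structure_id}:{hit.chain_id} "
                "absent from the interface catalog"
            )
    out = []
    for pa, pb in edges:
        ppi = annotate_ppi(pa, pb, filtered, interfaces, min_coverage, max_annotations)
        if ppi is not None:
            out.append(ppi)
    logger.info(
        "structural interactome: %d of %d edges structurally resolved",
        len(out),
        len(edges),
    )
    return out


# ---------------------------------------------------------------------------
# TSV round-trips


def read_edges_tsv(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein_a", "protein_b"]:
            raise ValueError(f"unexpected edge list header in {path}")
        for i, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{i}: malformed edge record")
            edges.append((fields[0], fields[1]))
    return edges


def write_edges_tsv(edges: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for pa, pb in edges:
            fh.write(f"{pa}\t{pb}\n")


def read_hits_tsv(path: str | Path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_id", "structure_id", "chain_id", "evalue", "pairs"]
        if header != expected:
            raise ValueError(f"unexpected alignment header in {path}")
        for i, line in enumerate(fh, start=2):
            pid, sid, cid, ev, pairs_s = line.rstrip("\n").split("\t")
            try:
                pairs = tuple(
                    tuple(int(x) for x in tok.split(":")) for tok in pairs_s.split(",")
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed pairs field") from exc
            hits.append(AlignmentHit(pid, sid, cid, float(ev), pairs))
    return hits


def write_hits_tsv(hits: list[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstructure_id\tchain_id\tevalue\tpairs\n")
        for h in hits:
            pairs = ",".join(f"{p}:{q}" for p, q in h.pairs)
            fh.write(f"{h.protein_id}\t{h.structure_id}\t{h.chain_id}\t{h.evalue:g}\t{pairs}\n")


def write_structural_interactome_tsv(
    ppis: list[StructuralPPI], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tinterface_a\tinterface_b\tn_annotations\n")
        for ppi in ppis:
            ia = ",".join(str(p) for p in sorted(ppi.interface_a))
            ib = ",".join(str(p) for p in sorted(ppi.interface_b))
            fh.write(f"{ppi.protein_a}\t{ppi.protein_b}\t{ia}\t{ib}\t{len(ppi.annotations)}\n")


def read_structural_interactome_tsv(path: str | Path) -> list[StructuralPPI]:
    ppis = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["protein_a", "protein_b", "interface_a", "interface_b", "n_annotations"]
        if header != expected:
            raise ValueError(f"unexpected structural interactome header in {path}")
        for line in fh:
            pa, pb, ia, ib, _ = line.rstrip("\n").split("\t")
            ppis.append(
                StructuralPPI(
                    pa,
                    pb,
                    frozenset(int(x) for x in ia.split(",") if x),
                    frozenset(int(x) for x in ib.split(",") if x),
                )
            )
    return ppis
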