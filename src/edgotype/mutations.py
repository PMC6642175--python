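"""Missense mutation curation filters and flank-verified protein mapping.

Disease records follow a ClinVar-like convention: a set of clinical
significance labels, a review star rating and a conflicting-interpretation
flag.  Non-disease records follow a dbSNP-like convention: validation and
withdrawal flags, free-form assertion labels and a minor allele frequency.
Mapping onto a protein sequence requires the mutation's flanking sequence
(up to 10 residues on each side of the mutated residue, taken from the
transcript) to occur in the protein at the same position the transcript
reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Curation",
    "MutationRecord",
    "MappedMutation",
    "DISEASE_ASSERTION_BLACKLIST",
    "filter_disease",
    "filter_nondisease",
    "flank_of",
    "map_mutation",
    "map_mutations",
    "read_mutations_tsv",
    "write_mutations_tsv",
    "write_mapped_tsv",
    "read_mapped_tsv",
]

logger = logging.getLogger(__name__)

FLANK_LEN = 10

# dbSNP-style labels that disqualify a variant from the non-disease set
DISEASE_ASSERTION_BLACKLIST = frozenset(
    {"pathogenic", "likely pathogenic", "drug-response", "uncertain significance", "other"}
)


@dataclass(frozen=True)
class Curation:
    clinical_significance: frozenset[str] = frozenset()
    review_stars: int = 0
    conflicting: bool = False
    validated: bool = False
    withdrawn: bool = False
    assertions: frozenset[str] = frozenset()
    maf: float | None = None


@dataclass(frozen=True)
class MutationRecord:
    mutation_id: str
    protein_id: str
    transcript_sequence: str
    transcript_position: int  # 1-based
    wt_aa: str
    mut_aa: str
    mutation_class: str  # "disease" | "non_disease"
    curation: Curation = field(default_factory=Curation)

    def __post_init__(self) -> None:
        if not 1 <= self.transcript_position <= len(self.transcript_sequence):
            raise ValueError("transcript position out of range")
        if self.transcript_sequence[self.transcript_position - 1] != self.wt_aa:
            raise ValueError(
                f"{self.mutation_id}: transcript has "
                f"{self.transcript_sequence[self.transcript_position - 1]!r} at "
                f"position {self.transcript_position}, not {self.wt_aa!r}"
            )
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"{self.mutation_id}: not a missense substitution")
        if self.mutation_class not in ("disease", "non_disease"):
            raise ValueError(f"unknown mutation class {self.mutation_class!r}")


@dataclass(frozen=True)
class MappedMutation:
    record: MutationRecord
    protein_position: int  # 1-based position on the protein sequence

    @property
    def protein_id(self) -> str:
        return self.record.protein_id

    @property
    def wt_aa(self) -> str:
        return self.record.wt_aa

    @property
    def mut_aa(self) -> str:
        return self.record.mut_aa

    @property
    def mutation_class(self) -> str:
        return self.record.mutation_class


def filter_disease(records: list[MutationRecord]) -> list[MutationRecord]:
    """Keep strictly-pathogenic, supported, non-conflicting disease records.

    A record survives when its significance label set is exactly
    ``{"pathogenic"}``, it has at least one review star, and it carries no
    conflicting interpretations.  Among records at the same
    (protein, position), only the one with the smallest mutation_id is kept.
    """
    kept = [
        r
        for r in records
        if r.mutation_class == "disease"
        and r.curation.clinical_significance == frozenset({"pathogenic"})
        and r.curation.review_stars >= 1
        and not r.curation.conflicting
    ]
    return _dedup_by_position(kept)


def filter_nondisease(
    records: list[MutationRecord],
    disease_positions: set[tuple[str, int]] | None = None,
    maf_threshold: float = 0.01,
    assertion_blacklist: frozenset[str] = DISEASE_ASSERTION_BLACKLIST,
) -> list[MutationRecord]:
    """Keep common, validated, assertion-free non-disease records.

    The minor-allele-frequency rule is strict (``maf > maf_threshold``), and
    records overlapping a (protein, position) in ``disease_positions`` — the
    mapped disease set — are discarded.
    """
    disease_positions = disease_positions or set()
    kept = [
        r
        for r in records
        if r.mutation_class == "non_disease"
        and r.curation.validated
        and not r.curation.withdrawn
        and not (r.curation.assertions & assertion_blacklist)
        and r.curation.maf is not None
        and r.curation.maf > maf_threshold
        and (r.protein_id, r.transcript_position) not in disease_positions
    ]
    return _dedup_by_position(kept)


def _dedup_by_position(records: list[MutationRecord]) -> list[MutationRecord]:
    best: dict[tuple[str, int], MutationRecord] = {}
    for r in sorted(records, key=lambda r: r.mutation_id):
        best.setdefault((r.protein_id, r.transcript_position), r)
    return sorted(best.values(), key=lambda r: r.mutation_id)


def flank_of(transcript_sequence: str, position: int, flank_len: int = FLANK_LEN) -> str:
    """Flanking sequence around a position: up to ``flank_len`` residues on
    each side (all available residues when fewer), wild-type residue included."""
    if not 1 <= position <= len(transcript_sequence):
        raise ValueError("position out of transcript range")
    lo = max(0, position - 1 - flank_len)
    hi = min(len(transcript_sequence), position + flank_len)
    return transcript_sequence[lo:hi]


def map_mutation(
    record: MutationRecord,
    protein_sequence: str,
    flank_len: int = FLANK_LEN,
    require_same_position: bool = True,
) -> MappedMutation | None:
    """Map a transcript-level mutation onto a protein sequence, or None.

    The transcript flank must occur in the protein with the mutated residue
    landing at the transcript-reported position.  With
    ``require_same_position=False`` any occurrence is accepted (the first,
    leftmost, is used) — an offset-tolerant mode for messier real data.
    """
    flank = flank_of(record.transcript_sequence, record.transcript_position, flank_len)
    left = min(flank_len, record.transcript_position - 1)
    start = 0
    while True:
        idx = protein_sequence.find(flank, start)
        if idx == -1:
            logger.debug("mutation %s unmappable", record.mutation_id)
            return None
        protein_position = idx + left + 1
        if not require_same_position or protein_position == record.transcript_position:
            return MappedMutation(record, protein_position)
        start = idx + 1


def map_mutations(
    records: list[MutationRecord],
    protein_sequences: dict[str, str],
    flank_len: int = FLANK_LEN,
) -> list[MappedMutation]:
    out = []
    for record in records:
        seq = protein_sequences.get(record.protein_id)
        if seq is None:
            logger.debug("no protein sequence for %s", record.protein_id)
            continue
        mapped = map_mutation(record, seq, flank_len)
        if mapped is not None:
            out.append(mapped)
    return out


# ---------------------------------------------------------------------------
# TSV round-trips

_MUT_HEADER = [
    "mutation_id",
    "protein_id",
    "transcript_sequence",
    "transcript_position",
    "wt_aa",
    "mut_aa",
    "mutation_class",
    "clinical_significance",
    "review_stars",
    "conflicting",
    "validated",
    "withdrawn",
    "assertions",
    "maf",
]


def write_mutations_tsv(records: list[MutationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_MUT_HEADER) + "\n")
        for r in records:
            c = r.curation
            fh.write(
                "\t".join(
                    [
                        r.mutation_id,
                        r.protein_id,
                        r.transcript_sequence,
                        str(r.transcript_position),
                        r.wt_aa,
                        r.mut_aa,
                        r.mutation_class,
                        ";".join(sorted(c.clinical_significance)),
                        str(c.review_stars),
                        str(int(c.conflicting)),
                        str(int(c.validated)),
                        str(int(c.withdrawn)),
                        ";".join(sorted(c.assertions)),
                        "" if c.maf is None else f"{c.maf:g}",
                    ]
                )
                + "\n"
            )


def read_mutations_tsv(path: str | Path) -> list[MutationRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MUT_HEADER:
            raise ValueError(f"unexpected mutation TSV header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            curation = Curation(
                clinical_significance=frozenset(x for x in f[7].split(";") if x),
                review_stars=int(f[8]),
                conflicting=bool(int(f[9])),
                validated=bool(int(f[10])),
                withdrawn=bool(int(f[11])),
                assertions=frozenset(x for x in f[12].split(";") if x),
                maf=float(f[13]) if f[13] else None,
            )
            records.append(
                MutationRecord(f[0], f[1], f[2], int(f[3]), f[4], f[5], f[6], curation)
            )
    return records


def write_mapped_tsv(mapped: list[MappedMutation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mutation_id\tprotein_id\tposition\twt\tmut\tclass\n")
        for m in mapped:
            fh.write(
                f"{m.record.mutation_id}\t{m.protein_id}\t{m.protein_position}"
                f"\t{m.wt_aa}\t{m.mut_aa}\t{m.mutation_class}\n"
            )


def read_mapped_tsv(
    path: str | Path, records_by_id: dict[str, MutationRecord] | None = None
) -> list[MappedMutation]:
    """Read a mapped-mutation table; reconstructs minimal records when the
    originating full records are not supplied."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["mutation_id", "protein_id", "position", "wt", "mut", "class"]:
            raise ValueError(f"unexpected mapped-mutation header in {path}")
        for line in fh:
            mid, pid, pos, wt, mut, cls = line.rstrip("\n").split("\t")
            pos = int(pos)
            if records_by_id and mid in records_by_id:
                record = records_by_id[mid]
            else:
                # minimal stand-in transcript: the wild-type residue at its position
                seq = "A" * (pos - 1) + wt
                record = MutationRecord(mid, pid, seq, pos, wt, mut, cls)
            out.append(MappedMutation(record, pos))
    return out
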