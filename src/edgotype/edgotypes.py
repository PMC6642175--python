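"""Mutation edgotype classification and the comparative statistics around it.

Geometry-based rule: a mutation edgetically disrupts a PPI iff its mapped
position lies on the interface mediating that PPI.  Physics-based rule: an
interfacial mutation disrupts a PPI iff the binding free-energy change
exceeds 0.5 kcal/mol (strictly); interfacial mutations with no ΔΔG record
for any of their PPIs are excluded from physics tallies, which is why the
physics denominators are smaller than the geometry ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from scipy import stats

from .interactome import StructuralPPI
from .mutations import MappedMutation

__all__ = [
    "DDG_THRESHOLD",
    "DDGRecord",
    "EdgotypeCall",
    "EdgeticCounts",
    "geometry_edgotype",
    "physics_edgotype",
    "call_edgotypes",
    "tally_counts",
    "estimate_gamma",
    "pam30_score",
    "compare_scores",
    "fisher_edgetic_comparison",
    "read_ddg_tsv",
    "write_ddg_tsv",
    "write_calls_tsv",
]

DDG_THRESHOLD = 0.5  # kcal/mol

_PAM30 = substitution_matrices.load("PAM30")
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DDGRecord:
    """Binding free-energy change of one PPI upon one mutation (kcal/mol,
    positive destabilizes binding)."""

    mutation_id: str
    protein_a: str
    protein_b: str
    ddg: float

    @property
    def ppi_key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass
class EdgotypeCall:
    mutation: MappedMutation
    method: str  # "geometry" | "physics"
    disrupted_ppis: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.method not in ("geometry", "physics"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def label(self) -> str:
        return "edgetic" if self.disrupted_ppis else "non_edgetic"

    @property
    def is_edgetic(self) -> bool:
        return bool(self.disrupted_ppis)

    @property
    def mono_edgetic(self) -> bool:
        return len(self.disrupted_ppis) == 1


@dataclass(frozen=True)
class EdgeticCounts:
    """Edgetic tallies: k_N of n_N non-disease, k_M of n_M disease mutations."""

    k_N: int
    n_N: int
    k_M: int
    n_M: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_N <= self.n_N and 0 <= self.k_M <= self.n_M):
            raise ValueError("counts must satisfy 0 <= k <= n")
        if self.n_N <= 0 or self.n_M <= 0:
            raise ValueError("denominators must be positive")

    @property
    def rate_N(self) -> float:
        return self.k_N / self.n_N

    @property
    def rate_M(self) -> float:
        return self.k_M / self.n_M

    def scaled(self, c: int) -> "EdgeticCounts":
        return EdgeticCounts(self.k_N * c, self.n_N * c, self.k_M * c, self.n_M * c)


def _ppis_of(protein_id: str, si: list[StructuralPPI]) -> list[StructuralPPI]:
    return [p for p in si if protein_id in (p.protein_a, p.protein_b)]


def geometry_edgotype(mutation: MappedMutation, si: list[StructuralPPI]) -> EdgotypeCall:
    """Geometry call: disrupted PPIs are those whose interface on the
    mutation's protein contains the mutated position."""
    disrupted = frozenset(
        ppi.key
        for ppi in _ppis_of(mutation.protein_id, si)
        if mutation.protein_position in ppi.interface_of(mutation.protein_id)
    )
    return EdgotypeCall(mutation, "geometry", disrupted)


def physics_edgotype(
    mutation: MappedMutation,
    si: list[StructuralPPI],
    ddg_table: list[DDGRecord],
    threshold: float = DDG_THRESHOLD,
) -> EdgotypeCall | None:
    """Physics call for an interfacial mutation; None when no ΔΔG is available.

    Raises a consistency error when a ΔΔG record exists for a PPI the
    mutation is not interfacial for.
    """
    interfacial = {
        ppi.key
        for ppi in _ppis_of(mutation.protein_id, si)
        if mutation.protein_position in ppi.interface_of(mutation.protein_id)
    }
    mine = [r for r in ddg_table if r.mutation_id == mutation.record.mutation_id]
    for r in mine:
        if r.ppi_key not in interfacial and (r.protein_b, r.protein_a) not in interfacial:
            raise ValueError(
                f"ΔΔG record for non-interfacial pair {r.ppi_key} of "
                f"mutation {r.mutation_id}"
            )
    if not mine:
        return None
    disrupted = frozenset(r.ppi_key for r in mine if r.ddg > threshold)
    return EdgotypeCall(mutation, "physics", disrupted)


def call_edgotypes(
    mutations: list[MappedMutation],
    si: list[StructuralPPI],
    method: str = "geometry",
    ddg_table: list[DDGRecord] | None = None,
    threshold: float = DDG_THRESHOLD,
) -> list[EdgotypeCall]:
    """Edgotype every mutation; physics skips mutations without usable ΔΔG.

    For the physics method, non-interfacial mutations are kept as non-edgetic
    calls (they need no ΔΔG), matching the convention that the physics rule
    only re-examines geometrically interfacial mutations.
    """
    if method == "geometry":
        return [geometry_edgotype(m, si) for m in mutations]
    if method != "physics":
        raise ValueError(f"unknown method {method!r}")
    ddg_table = ddg_table or []
    by_mut: dict[str, list[DDGRecord]] = {}
    for r in ddg_table:
        by_mut.setdefault(r.mutation_id, []).append(r)
    calls = []
    for m in mutations:
        geo = geometry_edgotype(m, si)
        if not geo.is_edgetic:
            calls.append(EdgotypeCall(m, "physics", frozenset()))
            continue
        call = physics_edgotype(m, si, by_mut.get(m.record.mutation_id, []), threshold)
        if call is not None:
            calls.append(call)
    return calls


def tally_counts(calls: list[EdgotypeCall], mono_only: bool = False) -> EdgeticCounts:
    """EdgeticCounts from a set of calls; ``mono_only`` tallies mono-edgetic
    mutations in the numerators instead."""
    k_N = n_N = k_M = n_M = 0
    for c in calls:
        hit = c.mono_edgetic if mono_only else c.is_edgetic
        if c.mutation.mutation_class == "disease":
            n_M += 1
            k_M += hit
        else:
            n_N += 1
            k_N += hit
    return EdgeticCounts(k_N, n_N, k_M, n_M)


def estimate_gamma(
    ddg_table: list[DDGRecord],
    mutations: list[MappedMutation],
    mutation_class: str,
    threshold: float = DDG_THRESHOLD,
) -> tuple[float, float]:
    """Disruption probability for interfacial mutations of one fitness class.

    Computed per (mutation, PPI) pair: the fraction of pairs whose ΔΔG
    exceeds the threshold, with the binomial standard error of the fraction.
    """
    class_ids = {
        m.record.mutation_id for m in mutations if m.mutation_class == mutation_class
    }
    pairs = [r for r in ddg_table if r.mutation_id in class_ids]
    if not pairs:
        raise ValueError(f"no ΔΔG pairs for class {mutation_class!r}")
    n = len(pairs)
    gamma = sum(1 for r in pairs if r.ddg > threshold) / n
    se = math.sqrt(gamma * (1.0 - gamma) / n)
    return gamma, se


# ---------------------------------------------------------------------------
# Comparative statistics


def pam30_score(wt_aa: str, mut_aa: str) -> int:
    """PAM30 substitution score between two standard residues."""
    if wt_aa not in _STANDARD_AA or mut_aa not in _STANDARD_AA:
        raise KeyError(f"non-standard residue code in ({wt_aa!r}, {mut_aa!r})")
    return int(_PAM30[wt_aa, mut_aa])


def compare_scores(
    disease_scores: list[float] | np.ndarray,
    nondisease_scores: list[float] | np.ndarray,
    n_resamples: int = 1_000_000,
    seed: int | None = None,
    chunk: int = 100_000,
) -> float:
    """Two-sided bootstrap test for a difference in mean substitution score.

    The statistic is the difference in group means.  Both groups are
    resampled with replacement; the resampled statistic is recentered at the
    observed difference and the p-value is the two-sided tail fraction, with
    the usual +1 continuity numerator so p is never exactly zero.
    """
    a = np.asarray(disease_scores, dtype=float)
    b = np.asarray(nondisease_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    rng = np.random.default_rng(seed)
    observed = a.mean() - b.mean()
    extreme = 0
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        ra = a[rng.integers(0, a.size, size=(m, a.size))].mean(axis=1)
        rb = b[rng.integers(0, b.size, size=(m, b.size))].mean(axis=1)
        extreme += int(np.count_nonzero(np.abs((ra - rb) - observed) >= abs(observed)))
        done += m
    return (extreme + 1) / (n_resamples + 1)


def fisher_edgetic_comparison(counts: EdgeticCounts) -> float:
    """Two-sided Fisher's exact test on the 2x2 edgetic-vs-class table."""
    table = [
        [counts.k_N, counts.n_N - counts.k_N],
        [counts.k_M, counts.n_M - counts.k_M],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# TSV round-trips

_DDG_HEADER = ["mutation_id", "protein_a", "protein_b", "ddg"]


def write_ddg_tsv(records: list[DDGRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_DDG_HEADER) + "\n")
        for r in records:
            fh.write(f"{r.mutation_id}\t{r.protein_a}\t{r.protein_b}\t{r.ddg:.6g}\n")


def read_ddg_tsv(path: str | Path) -> list[DDGRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _DDG_HEADER:
            raise ValueError(f"unexpected ΔΔG header in {path}")
        for line in fh:
            mid, pa, pb, ddg = line.rstrip("\n").split("\t")
            records.append(DDGRecord(mid, pa, pb, float(ddg)))
    return records


def write_calls_tsv(calls: list[EdgotypeCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mutation_id\tmethod\tlabel\tn_disrupted\tmono_edgetic\n")
        for c in calls:
            fh.write(
                f"{c.mutation.record.mutation_id}\t{c.method}\t{c.label}"
                f"\t{len(c.disrupted_ppis)}\t{int(c.mono_edgetic)}\n"
            )
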