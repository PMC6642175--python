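"""Quality-control metrics for a structural interactome.

Interacting protein pairs should, on average, be more functionally similar
(SimGIC over ancestor-closed GO annotation sets) and more tissue
co-expressed (Pearson correlation across shared tissues) than random
protein pairs.  The information-content corpus is the supplied annotated
protein set, which keeps the metric self-contained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GoAnnotationSet",
    "ExpressionMatrix",
    "simgic",
    "coexpression",
    "qc_report",
    "read_go_dag_tsv",
    "read_annotations_tsv",
]

logger = logging.getLogger(__name__)

EXPRESSION_SOURCES = ("rnaseq_log2", "normalized_rnaseq", "categorical_0_3", "cage_tpm")


@dataclass
class GoAnnotationSet:
    """Ontology DAG (term -> parent set) plus per-protein direct annotations."""

    parents: dict[str, frozenset[str]]
    annotations: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)  # term -> root category
    _closure_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _ic_cache: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._check_acyclic()
        for prot, terms in self.annotations.items():
            for t in terms:
                if t not in self.parents:
                    raise KeyError(f"protein {prot} annotated with unknown term {t}")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(term: str, stack: list[str]) -> None:
            if state.get(term) == 1:
                return
            if state.get(term) == 0:
                raise ValueError(f"ontology cycle through {term}")
            state[term] = 0
            for p in self.parents.get(term, ()):
                if p not in self.parents:
                    raise KeyError(f"term {term} has unknown parent {p}")
                visit(p, stack)
            state[term] = 1

        for term in self.parents:
            visit(term, [])

    def ancestors(self, term: str) -> frozenset[str]:
        """Term plus all its ancestors up to the root."""
        cached = self._closure_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        for p in self.parents[term]:
            out |= self.ancestors(p)
        result = frozenset(out)
        self._closure_cache[term] = result
        return result

    def closure(self, protein: str) -> frozenset[str]:
        terms = self.annotations.get(protein, frozenset())
        out: set[str] = set()
        for t in terms:
            out |= self.ancestors(t)
        return frozenset(out)

    def information_content(self) -> dict[str, float]:
        """IC(t) = -log(fraction of corpus proteins whose closure contains t);
        the corpus is the annotated protein set, so universal (root) terms get 0."""
        if self._ic_cache is not None:
            return self._ic_cache
        n = len(self.annotations)
        counts: dict[str, int] = {}
        for prot in self.annotations:
            for t in self.closure(prot):
                counts[t] = counts.get(t, 0) + 1
        ic = {t: -math.log(c / n) if c < n else 0.0 for t, c in counts.items()}
        self._ic_cache = ic
        return ic


def simgic(protein_a: str, protein_b: str, annotations: GoAnnotationSet) -> float | None:
    """SimGIC similarity: IC-weighted Jaccard index of the two proteins'
    ancestor-closed annotation sets; None when either protein is unannotated."""
    if protein_a not in annotations.annotations or protein_b not in annotations.annotations:
        logger.debug("simgic undefined for (%s, %s)", protein_a, protein_b)
        return None
    ca = annotations.closure(protein_a)
    cb = annotations.closure(protein_b)
    if not ca or not cb:
        return None
    ic = annotations.information_content()
    union = sum(ic.get(t, 0.0) for t in ca | cb)
    if union == 0.0:
        return 0.0
    inter = sum(ic.get(t, 0.0) for t in ca & cb)
    return inter / union


@dataclass
class ExpressionMatrix:
    """Protein-by-tissue expression values; NaN marks undefined entries."""

    values: pd.DataFrame  # index: protein, columns: tissue
    source: str = "rnaseq_log2"

    def __post_init__(self) -> None:
        if self.source not in EXPRESSION_SOURCES:
            raise ValueError(f"unknown expression source {self.source!r}")
        if self.source == "categorical_0_3":
            vals = self.values.values
            ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0, 3.0))
            if not ok.all():
                raise ValueError("categorical expression values must be in {0,1,2,3}")

    def profile(self, protein: str) -> pd.Series | None:
        if protein not in self.values.index:
            return None
        return self.values.loc[protein]


def coexpression(
    protein_a: str,
    protein_b: str,
    matrix: ExpressionMatrix,
    min_shared_tissues: int = 5,
) -> float | None:
    """Pearson correlation of two tissue-expression profiles over tissues
    where both are defined; None below the shared-tissue threshold or when
    either profile is constant."""
    pa = matrix.profile(protein_a)
    pb = matrix.profile(protein_b)
    if pa is None or pb is None:
        return None
    mask = pa.notna() & pb.notna()
    if int(mask.sum()) < min_shared_tissues:
        return None
    x = pa[mask].to_numpy(dtype=float)
    y = pb[mask].to_numpy(dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.debug("constant profile for (%s, %s)", protein_a, protein_b)
        return None
    return float(np.corrcoef(x, y)[0, 1])


def qc_report(
    si,
    annotations: GoAnnotationSet | None,
    matrices: list[ExpressionMatrix],
    n_random_pairs: int = 1000,
    seed: int | None = None,
) -> dict:
    """Compare SimGIC / co-expression of interacting vs random protein pairs.

    Random pairs are drawn (seeded) from the proteins of the structural
    interactome, excluding actual edges.  Reports medians per group and a
    two-sided Mann-Whitney U p-value per metric.
    """
    rng = np.random.default_rng(seed)
    proteins = sorted({p for ppi in si for p in (ppi.protein_a, ppi.protein_b)})
    edge_set = {frozenset(ppi.key) for ppi in si}
    interacting = [tuple(sorted(ppi.key)) for ppi in si if ppi.protein_a != ppi.protein_b]

    random_pairs: list[tuple[str, str]] = []
    attempts = 0
    while len(random_pairs) < n_random_pairs and attempts < 50 * n_random_pairs:
        i, j = rng.integers(0, len(proteins), size=2)
        attempts += 1
        if i == j:
            continue
        pair = frozenset((proteins[i], proteins[j]))
        if pair in edge_set:
            continue
        random_pairs.append(tuple(sorted(pair)))

    report: dict = {
        "n_interacting_pairs": len(interacting),
        "n_random_pairs": len(random_pairs),
        "metrics": {},
    }

    def _compare(name: str, fn) -> None:
        vals_i = [v for v in (fn(a, b) for a, b in interacting) if v is not None]
        vals_r = [v for v in (fn(a, b) for a, b in random_pairs) if v is not None]
        entry: dict = {
            "n_interacting": len(vals_i),
            "n_random": len(vals_r),
            "median_interacting": float(np.median(vals_i)) if vals_i else None,
            "median_random": float(np.median(vals_r)) if vals_r else None,
        }
        if vals_i and vals_r:
            entry["mannwhitney_p"] = float(
                stats.mannwhitneyu(vals_i, vals_r, alternative="two-sided")[1]
            )
        report["metrics"][name] = entry

    if annotations is not None:
        _compare("simgic", lambda a, b: simgic(a, b, annotations))
    for idx, matrix in enumerate(matrices):
        _compare(
            f"coexpression_{matrix.source}_{idx}",
            lambda a, b, m=matrix: coexpression(a, b, m),
        )
    return report


# ---------------------------------------------------------------------------
# TSV readers (minimal OBO-like / GAF-like dialects)


def read_go_dag_tsv(path: str | Path) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Read `term<TAB>parent[<TAB>category]` rows; empty parent marks a root."""
    parents: dict[str, set[str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["term", "parent"]:
            raise ValueError(f"unexpected ontology header in {path}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            term, parent = fields[0], fields[1]
            parents.setdefault(term, set())
            if parent:
                parents[term].add(parent)
                parents.setdefault(parent, set())
            if len(fields) > 2 and fields[2]:
                categories[term] = fields[2]
    return {t: frozenset(ps) for t, ps in parents.items()}, categories


def read_annotations_tsv(path: str | Path) -> dict[str, frozenset[str]]:
    """Read `protein<TAB>term` rows into a protein -> term-set map."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein_id", "term"]:
            raise ValueError(f"unexpected annotation header in {path}")
        for line in fh:
            prot, term = line.rstrip("\n").split("\t")[:2]
            ann.setdefault(prot, set()).add(term)
    return {p: frozenset(ts) for p, ts in ann.items()}
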