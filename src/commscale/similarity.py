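"""Pairwise functional similarity of proteins: ontology (G), flat vocabulary (M),
and knockout growth-rate correlation (C).

The ontology measure follows a shared-set rarity idea: the set of terms
annotated to *both* proteins is formed (after propagating each protein's terms
to all ancestors in the DAG, root excluded), and ``n_ij`` counts the proteins
whose annotation set contains that shared set.  A rare shared set (small
``n_ij``) marks a functionally specific pair.  The similarity is

    G_ij = 1 - n_ij / N,

with ``N`` the number of proteins in the annotation universe: it is 0 when the
shared set is empty (vacuously shared by all N proteins) and approaches 1 as
the shared set becomes unique to the pair.  A protein without annotations
yields an empty intersection and hence similarity 0 — lack of annotation is
never penalized below the no-information level.  The flat measure M is the
same statistic over a one-level vocabulary (no propagation).

The growth measure C_ij is the Pearson correlation of the two knockout
strains' log-ratio growth profiles ``L_{i,t} = log2(g_{i,t} / control_mean_i)``
across conditions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np
import pandas as pd

Protein = Hashable
Term = str


class OntologyError(ValueError):
    """Cycle or missing root in the term DAG."""


@dataclass
class AnnotationSet:
    """Protein -> term-set annotations over a rooted DAG.

    ``dag`` maps each term to its parent terms; the root has no parents and is
    reachable from every term.  After :func:`propagate_annotations` each
    protein's set is its ancestral closure minus the root.
    """

    annotations: dict[Protein, set[Term]]
    dag: dict[Term, set[Term]]
    root: Term
    propagated: bool = False

    @property
    def proteins(self) -> list[Protein]:
        return sorted(self.annotations, key=str)

    @property
    def n_proteins(self) -> int:
        return len(self.annotations)


@dataclass
class GrowthMatrix:
    """Per-strain log-ratio growth profiles and control means.

    ``profiles`` rows are strains (proteins), columns conditions; entries are
    log2 ratios of treatment growth rate to the strain's control mean.
    """

    profiles: pd.DataFrame
    control_mean: pd.Series

    def __post_init__(self) -> None:
        if not self.profiles.index.is_unique:
            raise ValueError("duplicate strains in growth matrix")

    @property
    def proteins(self) -> list:
        return list(self.profiles.index)

    def has(self, protein) -> bool:
        return protein in self.profiles.index


@dataclass
class EdgeSimilarity:
    """One similarity measure evaluated on a network's interacting pairs."""

    measure: str  # "G" | "M" | "C"
    values: dict[tuple, float]  # canonical (sorted) pair -> similarity
    coverage: set
    interacting_mean: float = float("nan")
    all_pairs_mean: float = float("nan")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["protein_a", "protein_b", "measure", "value"])
            for (a, b), v in sorted(self.values.items()):
                writer.writerow([a, b, self.measure, repr(v)])


# ---------------------------------------------------------------------------
# ontology handling
# ---------------------------------------------------------------------------

def _ancestors(term: Term, dag: Mapping[Term, set[Term]], cache: dict) -> set[Term]:
    """All ancestors of ``term`` (term excluded), with cycle detection."""
    if term in cache:
        result = cache[term]
        if result is None:
            raise OntologyError(f"cycle detected at term {term!r}")
        return result
    cache[term] = None  # in-progress marker
    out: set[Term] = set()
    for parent in dag.get(term, ()):
        out.add(parent)
        out |= _ancestors(parent, dag, cache)
    cache[term] = out
    return out


def propagate_annotations(raw: AnnotationSet) -> AnnotationSet:
    """Replace every protein's term set by its ancestral closure minus the root.

    Proteins annotated only with the root end up with an empty set and count
    as unannotated.  Idempotent.
    """
    cache: dict[Term, set[Term] | None] = {}
    for term in raw.dag:
        _ancestors(term, raw.dag, cache)
    new_ann: dict[Protein, set[Term]] = {}
    for protein, terms in raw.annotations.items():
        closed: set[Term] = set()
        for t in terms:
            if t not in raw.dag:
                raise OntologyError(f"term {t!r} annotated to {protein!r} not in DAG")
            closed.add(t)
            closed |= _ancestors(t, raw.dag, cache)
        closed.discard(raw.root)
        new_ann[protein] = closed
    return AnnotationSet(annotations=new_ann, dag=dict(raw.dag), root=raw.root, propagated=True)


def read_obo(path: str | Path) -> tuple[dict[Term, set[Term]], Term]:
    """Minimal OBO reader (id / is_a); returns (dag, root)."""
    dag: dict[Term, set[Term]] = {}
    current: Term | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line == "[Term]":
            current = None
        elif line.startswith("id:"):
            current = line[3:].strip()
            dag.setdefault(current, set())
        elif line.startswith("is_a:") and current is not None:
            dag[current].add(line[5:].split("!")[0].strip())
    roots = [t for t, parents in dag.items() if not parents]
    if len(roots) != 1:
        raise OntologyError(f"expected exactly one root term, found {roots}")
    return dag, roots[0]


def read_annotation_tsv(
    path: str | Path, dag: dict[Term, set[Term]], root: Term
) -> AnnotationSet:
    annotations: dict[Protein, set[Term]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for protein, term in reader:
            annotations.setdefault(protein, set()).add(term)
    return AnnotationSet(annotations=annotations, dag=dag, root=root)


def read_growth_csv(path: str | Path, raw_rates: bool = False) -> GrowthMatrix:
    """Read a strains-by-conditions growth CSV (first column control_mean).

    With ``raw_rates`` the condition columns hold raw growth rates ``g_{i,t}``
    and are converted to log ratios ``log2(g_{i,t} / control_mean_i)``.
    """
    df = pd.read_csv(path, index_col=0)
    control = df["control_mean"].astype(float)
    prof = df.drop(columns=["control_mean"]).astype(float)
    if raw_rates:
        prof = np.log2(prof.div(control, axis=0))
    return GrowthMatrix(profiles=prof, control_mean=control)


# ---------------------------------------------------------------------------
# shared-set rarity similarity (G and M)
# ---------------------------------------------------------------------------

class _TermIndex:
    """Term -> set of proteins annotated with it (over propagated sets)."""

    def __init__(self, ann: AnnotationSet):
        self.by_term: dict[Term, set[Protein]] = {}
        for protein, terms in ann.annotations.items():
            for t in terms:
                self.by_term.setdefault(t, set()).add(protein)
        self.n = ann.n_proteins

    def n_sharing(self, shared: set[Term]) -> int:
        """Number of proteins whose set contains every term in ``shared``."""
        if not shared:
            return self.n
        sets = sorted((self.by_term.get(t, set()) for t in shared), key=len)
        out = set(sets[0])
        for s in sets[1:]:
            out &= s
            if not out:
                break
        return len(out)


def shared_set_count(ann: AnnotationSet, i: Protein, j: Protein, index: _TermIndex | None = None) -> int:
    """n_ij: proteins whose propagated set contains ann(i) ∩ ann(j).

    The empty intersection is vacuously contained in every set, so n_ij = N.
    """
    if i not in ann.annotations or j not in ann.annotations:
        missing = i if i not in ann.annotations else j
        raise KeyError(f"protein {missing!r} not in annotation set")
    shared = ann.annotations[i] & ann.annotations[j]
    if index is None:
        index = _TermIndex(ann)
    return index.n_sharing(shared)


def rarity_similarity(n_ij: int, n_total: int) -> float:
    """Default similarity form 1 - n_ij/N; swap here to register an alternative
    monotone-decreasing form (z-scoring downstream is invariant to the choice
    up to re-normalization)."""
    if n_total < 1:
        raise ValueError("N must be >= 1")
    return 1.0 - n_ij / n_total


def go_similarity(
    ann: AnnotationSet, i: Protein, j: Protein, n_total: int | None = None,
    index: _TermIndex | None = None,
) -> float:
    """Shared-set rarity similarity G_ij in [0, 1] on propagated annotations."""
    n = n_total if n_total is not None else ann.n_proteins
    return rarity_similarity(shared_set_count(ann, i, j, index=index), n)


def flat_similarity(
    flat_ann: Mapping[Protein, set[Term]], i: Protein, j: Protein, n_total: int | None = None
) -> float:
    """M_ij: same statistic over a flat (single-level) vocabulary."""
    ann = AnnotationSet(
        annotations={p: set(t) for p, t in flat_ann.items()}, dag={}, root="", propagated=True
    )
    return go_similarity(ann, i, j, n_total=n_total)


# ---------------------------------------------------------------------------
# growth correlation (C)
# ---------------------------------------------------------------------------

class CoverageError(KeyError):
    """Profile missing for a requested protein."""


def growth_correlation(gm: GrowthMatrix, i: Protein, j: Protein) -> float:
    """Pearson correlation C_ij of two strains' log-ratio profiles.

    Zero-variance profiles make the correlation undefined; NaN is returned and
    the pair is treated as uncovered upstream.
    """
    for p in (i, j):
        if not gm.has(p):
            raise CoverageError(f"no growth profile for {p!r}")
    x = gm.profiles.loc[i].to_numpy(dtype=float)
    y = gm.profiles.loc[j].to_numpy(dtype=float)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# edge-level evaluation
# ---------------------------------------------------------------------------

def _pair(u, v) -> tuple:
    return (u, v) if str(u) <= str(v) else (v, u)


def edge_similarity(
    net,
    measure: str,
    data,
    all_pairs_sample: int = 2000,
    seed: int = 0,
) -> EdgeSimilarity:
    """Evaluate one measure on every covered interacting pair of a network.

    ``data`` is an (optionally unpropagated) :class:`AnnotationSet` for G, a
    flat protein -> term-set mapping for M, or a :class:`GrowthMatrix` for C.
    Besides per-edge values, the mean over interacting pairs and over a
    uniform random sample of all covered pairs (``all_pairs_sample`` draws)
    are reported, which reproduces the interacting-vs-all-pairs contrast seen
    in real interaction data.
    """
    if measure not in ("G", "M", "C"):
        raise ValueError("measure must be one of G, M, C")
    nodes = sorted(net.nodes, key=str)

    if measure in ("G", "M"):
        if measure == "M":
            ann = AnnotationSet(
                annotations={p: set(t) for p, t in data.items()}, dag={}, root="",
                propagated=True,
            )
        else:
            ann = data if data.propagated else propagate_annotations(data)
        index = _TermIndex(ann)
        n_total = ann.n_proteins
        coverage = {v for v in nodes if v in ann.annotations}

        def value(u, v):
            return go_similarity(ann, u, v, n_total=n_total, index=index)

    else:
        gm: GrowthMatrix = data
        coverage = {v for v in nodes if gm.has(v)}

        def value(u, v):
            return growth_correlation(gm, u, v)

    values: dict[tuple, float] = {}
    for u, v in net.edges:
        if u == v or u not in coverage or v not in coverage:
            continue
        s = value(u, v)
        if not np.isnan(s):
            values[_pair(u, v)] = s

    covered = sorted(coverage, key=str)
    rng = np.random.default_rng(seed)
    sampled: list[float] = []
    if len(covered) >= 2:
        for _ in range(all_pairs_sample):
            u, v = rng.choice(len(covered), size=2, replace=False)
            s = value(covered[u], covered[v])
            if not np.isnan(s):
                sampled.append(s)
    return EdgeSimilarity(
        measure=measure,
        values=values,
        coverage=set(coverage),
        interacting_mean=float(np.mean(list(values.values()))) if values else float("nan"),
        all_pairs_mean=float(np.mean(sampled)) if sampled else float("nan"),
    )
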