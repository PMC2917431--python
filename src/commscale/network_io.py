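"""Read interaction edge lists, classify interaction types, and assemble networks.

Protein interaction databases distinguish two broad interaction categories in
the Molecular Interactions ontology: *associations* (type ``A``, dominated by
tandem-affinity-purification evidence) and *physical associations* (type
``P``, dominated by yeast-two-hybrid evidence).  The two networks have very
different global properties, so they are assembled and analyzed separately.

Input files are plain TSV exports with columns
``protein_a, protein_b, interaction_type, source, evidence``; the
authoritative A/P call is made from the evidence code through an editable
mapping table (database dialects drift, so the mapping ships as data, not
logic).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx


class InteractionType(str, Enum):
    A = "A"  # association (e.g. affinity capture / TAP-style evidence)
    P = "P"  # physical association (e.g. yeast-two-hybrid evidence)


#: Default evidence-code -> interaction-type mapping.  Seeded from the BioGrid
#: and Mint evidence vocabularies; keys are matched case-insensitively after
#: hyphen/underscore normalization.  Extend or override per input dialect.
DEFAULT_EVIDENCE_MAP: dict[str, InteractionType] = {
    # physical associations (P)
    "reconstituted complex": InteractionType.P,
    "pca": InteractionType.P,
    "co crystal structure": InteractionType.P,
    "yeast two hybrid": InteractionType.P,
    "two hybrid": InteractionType.P,
    "biophysical": InteractionType.P,
    "protein complementation assay": InteractionType.P,
    # associations (A)
    "affinity capture": InteractionType.A,
    "affinity capture ms": InteractionType.A,
    "affinity capture western": InteractionType.A,
    "biochemical activity": InteractionType.A,
    "biochemical": InteractionType.A,
    "co fractionation": InteractionType.A,
    "co purification": InteractionType.A,
    "far western": InteractionType.A,
}


def _normalize_evidence(code: str) -> str:
    return code.strip().lower().replace("-", " ").replace("_", " ")


class ParseError(ValueError):
    """Malformed input line; message carries the file and line number."""


class UnmappedEvidenceError(KeyError):
    """An evidence code has no entry in the evidence map."""


class EmptyNetworkError(ValueError):
    """No records remain after type filtering."""


@dataclass(frozen=True)
class InteractionRecord:
    protein_a: str
    protein_b: str
    itype: InteractionType
    source: str = ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("protein identifiers must be non-empty")


@dataclass
class SummaryStats:
    n_nodes: int
    n_edges: int
    n_self_edges: int
    mean_degree: float
    mean_clustering: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_self_edges": self.n_self_edges,
            "mean_degree": self.mean_degree,
            "mean_clustering": self.mean_clustering,
        }


class Network:
    """Undirected protein network.

    Thin wrapper around :class:`networkx.Graph` that pins down the counting
    conventions: each unordered pair is stored once, a self-loop contributes 2
    to its node's degree, and ``W`` (total edge count, self-loops included)
    satisfies ``sum(degree) == 2 W``.  Self-loops are retained in edge and
    degree counts but are dropped for connectivity, community detection and
    topology (a self-pair's energy contribution is partition-independent, so
    dropping them cannot change any optimum).
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Network":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g)

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> list:
        return list(self.graph.nodes())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> list[tuple]:
        """Edges in canonical (sorted-endpoint) order, each pair once."""
        return [tuple(sorted((u, v))) for u, v in self.graph.edges()]

    @property
    def W(self) -> int:
        """Total edge count (self-loops counted once)."""
        return self.graph.number_of_edges()

    @property
    def n_self_edges(self) -> int:
        return nx.number_of_selfloops(self.graph)

    def degree(self, node=None):
        if node is None:
            return dict(self.graph.degree())
        return self.graph.degree(node)

    def has_edge(self, u, v) -> bool:
        return self.graph.has_edge(u, v)

    # -- derived views ---------------------------------------------------
    def simple(self) -> nx.Graph:
        """Copy of the graph with self-loops removed."""
        g = self.graph.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
        return g

    def largest_connected_component(self) -> "Network":
        simple = self.simple()
        if simple.number_of_nodes() == 0:
            return Network(nx.Graph())
        lcc = max(nx.connected_components(simple), key=lambda c: (len(c), sorted(c)[0]))
        return Network(self.graph.subgraph(lcc).copy())

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["protein_a", "protein_b"])
            for u, v in sorted(self.edges):
                writer.writerow([u, v])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Network":
        g = nx.Graph()
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            ia, ib = header.index("protein_a"), header.index("protein_b")
            for row in reader:
                if not row:
                    continue
                g.add_edge(row[ia], row[ib])
        return cls(g)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return set(self.graph.nodes) == set(other.graph.nodes) and set(
            self.edges
        ) == set(other.edges)


REQUIRED_COLUMNS = ["protein_a", "protein_b", "interaction_type", "source", "evidence"]


def read_interactions(
    paths: Iterable[str | Path],
    evidence_map: Mapping[str, InteractionType] | None = None,
    on_unmapped: str = "fail",
) -> tuple[list[InteractionRecord], list[str]]:
    """Parse interaction TSV files into records, typing each by evidence code.

    Parameters
    ----------
    paths
        TSV files with header ``protein_a protein_b interaction_type source
        evidence``.
    evidence_map
        Evidence code -> :class:`InteractionType`.  Defaults to
        :data:`DEFAULT_EVIDENCE_MAP`.
    on_unmapped
        ``"fail"`` raises on the first unmapped evidence code; ``"skip"``
        drops the line and records the code.

    Returns
    -------
    (records, unmapped_codes)
        The unmapped list is always returned so callers can report coverage.
    """
    if on_unmapped not in ("fail", "skip"):
        raise ValueError("on_unmapped must be 'fail' or 'skip'")
    emap = {
        _normalize_evidence(k): InteractionType(v)
        for k, v in (evidence_map or DEFAULT_EVIDENCE_MAP).items()
    }
    records: list[InteractionRecord] = []
    unmapped: list[str] = []
    for path in paths:
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            try:
                idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
            except ValueError as exc:
                raise ParseError(f"{path}: missing required column ({exc})") from exc
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not f.strip() for f in row):
                    continue
                if len(row) < len(header):
                    raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
                evidence = row[idx["evidence"]]
                key = _normalize_evidence(evidence)
                if key not in emap:
                    if on_unmapped == "fail":
                        raise UnmappedEvidenceError(
                            f"{path}:{lineno}: evidence code {evidence!r} not in evidence map"
                        )
                    unmapped.append(evidence)
                    continue
                records.append(
                    InteractionRecord(
                        protein_a=row[idx["protein_a"]].strip(),
                        protein_b=row[idx["protein_b"]].strip(),
                        itype=emap[key],
                        source=row[idx["source"]].strip(),
                        evidence=evidence.strip(),
                    )
                )
    return records, unmapped


def build_network(
    records: Iterable[InteractionRecord],
    itype: InteractionType | str,
    keep_lcc: bool = True,
) -> Network:
    """Assemble one network (A or P) from typed records.

    Duplicate pairs in either orientation collapse to a single edge; records
    from different sources merge.  Self-loops are kept as edges.  With
    ``keep_lcc`` only the largest connected component (self-loops ignored for
    connectivity) is returned.
    """
    itype = InteractionType(itype)
    g = nx.Graph()
    for rec in records:
        if rec.itype is itype:
            g.add_edge(rec.protein_a, rec.protein_b)
    if g.number_of_nodes() == 0:
        raise EmptyNetworkError(f"no records of type {itype.value} to build from")
    net = Network(g)
    return net.largest_connected_component() if keep_lcc else net


def network_summary(net: Network) -> SummaryStats:
    """Node/edge counts, mean degree and mean clustering coefficient.

    Mean degree is ``2W / n`` with self-loops contributing 2 to degree;
    clustering ignores self-loops (a self-edge forms no triple).
    """
    from commscale.topology import node_clustering

    n = net.n_nodes
    simple = net.simple()
    clustering = (
        sum(node_clustering(simple, v) for v in simple.nodes()) / n if n else float("nan")
    )
    return SummaryStats(
        n_nodes=n,
        n_edges=net.W,
        n_self_edges=net.n_self_edges,
        mean_degree=(2.0 * net.W / n) if n else float("nan"),
        mean_clustering=clustering,
    )


def write_summary(stats: SummaryStats, path: str | Path) -> None:
    Path(path).write_text(json.dumps(stats.to_dict(), indent=2) + "\n")
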