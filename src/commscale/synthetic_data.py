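"""Synthetic benchmarks with known multi-scale community structure.

Real protein interaction networks have community structure at many scales but
no usable ground truth, so every pipeline stage is exercised on planted
benchmarks instead: a two-level hierarchical stochastic block model (fine
modules nested inside coarse modules, with edge probabilities ``p_fine >
p_coarse > p_between``), term annotations whose shared-set rarity is elevated
inside planted modules with tunable *fidelity*, and knockout growth-rate
profiles correlated within modules with tunable effect size and noise.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` per operation, so identical seeds give
byte-identical serialized outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from commscale.network_io import Network
from commscale.similarity import AnnotationSet, GrowthMatrix

ROOT_TERM = "T:root"


@dataclass
class PlantedStructure:
    """Ground-truth labels of the two-level planted hierarchy."""

    fine_labels: dict[Hashable, int]
    coarse_labels: dict[Hashable, int]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.fine_labels) != set(self.coarse_labels):
            raise ValueError("fine and coarse labels must cover the same nodes")
        # every fine module nested in exactly one coarse module
        seen: dict[int, int] = {}
        for node, fine in self.fine_labels.items():
            coarse = self.coarse_labels[node]
            if seen.setdefault(fine, coarse) != coarse:
                raise ValueError(f"fine module {fine} spans multiple coarse modules")

    def restrict(self, nodes) -> "PlantedStructure":
        keep = set(nodes)
        return PlantedStructure(
            fine_labels={n: l for n, l in self.fine_labels.items() if n in keep},
            coarse_labels={n: l for n, l in self.coarse_labels.items() if n in keep},
            params=dict(self.params),
        )

    @property
    def fine_modules(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for n, l in self.fine_labels.items():
            out.setdefault(l, set()).add(n)
        return out


def _node_name(i: int) -> str:
    return f"p{i:04d}"


def generate_planted_network(
    n_coarse: int,
    fine_per_coarse: int,
    fine_size: int,
    p_fine: float,
    p_coarse: float,
    p_between: float,
    seed: int = 0,
    fine_sizes: Sequence[int] | None = None,
    p_fine_per_module: Sequence[float] | None = None,
    keep_lcc: bool = True,
) -> tuple[Network, PlantedStructure]:
    """Two-level hierarchical planted-partition network.

    Edges are drawn independently with probability ``p_fine`` inside fine
    modules, ``p_coarse`` between fine modules of the same coarse module, and
    ``p_between`` otherwise; the ordering ``p_fine > p_coarse >= p_between >=
    0`` (strict between tiers unless a tier is switched off entirely at 0) is
    required so the hierarchy is actually planted.  Only the largest connected
    component is returned (labels restricted accordingly) unless
    ``keep_lcc=False``.

    ``fine_sizes`` (one entry per fine module, overriding ``fine_size``) and
    ``p_fine_per_module`` allow heterogeneous benchmarks in which modules
    differ in density.
    """
    ordered = p_fine > p_coarse >= p_between >= 0 and (
        p_coarse > p_between or p_between == 0
    )
    if not ordered:
        raise ValueError("need p_fine > p_coarse > p_between >= 0 (zeros may tie)")
    if min(n_coarse, fine_per_coarse, fine_size) < 1:
        raise ValueError("all sizes must be >= 1")
    n_fine = n_coarse * fine_per_coarse
    sizes = list(fine_sizes) if fine_sizes is not None else [fine_size] * n_fine
    if len(sizes) != n_fine:
        raise ValueError("fine_sizes must have n_coarse * fine_per_coarse entries")
    p_fine_mod = (
        list(p_fine_per_module) if p_fine_per_module is not None else [p_fine] * n_fine
    )
    if len(p_fine_mod) != n_fine:
        raise ValueError("p_fine_per_module must have one entry per fine module")
    if any(p <= p_coarse for p in p_fine_mod):
        raise ValueError("every per-module p_fine must exceed p_coarse")

    rng = np.random.default_rng(seed)
    fine_labels: dict[str, int] = {}
    coarse_labels: dict[str, int] = {}
    idx = 0
    for f in range(n_fine):
        for _ in range(sizes[f]):
            name = _node_name(idx)
            fine_labels[name] = f
            coarse_labels[name] = f // fine_per_coarse
            idx += 1
    nodes = sorted(fine_labels)
    n = len(nodes)
    fine_arr = np.array([fine_labels[v] for v in nodes])
    coarse_arr = np.array([coarse_labels[v] for v in nodes])
    pf_arr = np.asarray(p_fine_mod, dtype=float)

    iu, ju = np.triu_indices(n, k=1)
    same_fine = fine_arr[iu] == fine_arr[ju]
    same_coarse = coarse_arr[iu] == coarse_arr[ju]
    p = np.where(
        same_fine, pf_arr[fine_arr[iu]], np.where(same_coarse, p_coarse, p_between)
    )
    draw = rng.random(len(p)) < p
    g = nx.Graph()
    g.add_nodes_from(nodes)
    nodes_np = np.array(nodes)
    g.add_edges_from(zip(nodes_np[iu[draw]], nodes_np[ju[draw]]))

    net = Network(g)
    structure = PlantedStructure(
        fine_labels=fine_labels,
        coarse_labels=coarse_labels,
        params={
            "n_coarse": n_coarse,
            "fine_per_coarse": fine_per_coarse,
            "fine_size": fine_size,
            "fine_sizes": sizes,
            "p_fine": p_fine,
            "p_fine_per_module": p_fine_mod,
            "p_coarse": p_coarse,
            "p_between": p_between,
            "seed": seed,
        },
    )
    if not keep_lcc:
        return net, structure
    lcc = net.largest_connected_component()
    return lcc, structure.restrict(lcc.nodes)


def generate_er_network(n: int, p: float, seed: int = 0) -> Network:
    """Erdős–Rényi G(n, p), largest connected component.

    At ``p = 0`` there are no edges and the LCC is a single (lowest-named)
    node.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    g = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    g = nx.relabel_nodes(g, {i: _node_name(i) for i in g.nodes()})
    return Network(g).largest_connected_component()


def generate_annotations(
    structure: PlantedStructure,
    terms_per_module: int = 3,
    n_background_terms: int = 20,
    fidelity: float = 1.0,
    seed: int = 0,
    fidelity_per_module: Mapping[int, float] | None = None,
) -> AnnotationSet:
    """Planted term annotations over a three-level rooted tree.

    The ontology is root -> one branch term per coarse module -> a set of
    ``terms_per_module`` leaf terms per fine module, plus ``n_background_terms``
    terms directly under the root.  Each protein receives its fine module's
    full leaf-term set with probability ``fidelity``; otherwise it gets a
    single random background term.  ``fidelity = 1`` makes modules
    annotation-identical; ``fidelity = 0`` destroys all module signal.
    ``fidelity_per_module`` overrides the global fidelity per fine module.
    """
    if not 0 <= fidelity <= 1:
        raise ValueError("fidelity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dag: dict[str, set[str]] = {ROOT_TERM: set()}
    for c in sorted(set(structure.coarse_labels.values())):
        dag[f"T:coarse{c:03d}"] = {ROOT_TERM}
    module_terms: dict[int, set[str]] = {}
    fine_to_coarse = {
        structure.fine_labels[n]: structure.coarse_labels[n] for n in structure.fine_labels
    }
    for f in sorted(set(structure.fine_labels.values())):
        parent = f"T:coarse{fine_to_coarse[f]:03d}"
        terms = {f"T:fine{f:03d}.{k}" for k in range(terms_per_module)}
        for t in terms:
            dag[t] = {parent}
        module_terms[f] = terms
    background = [f"T:bg{k:03d}" for k in range(n_background_terms)]
    for t in background:
        dag[t] = {ROOT_TERM}

    annotations: dict[Hashable, set[str]] = {}
    fid_of = fidelity_per_module or {}
    for node in sorted(structure.fine_labels, key=str):
        node_fid = fid_of.get(structure.fine_labels[node], fidelity)
        if rng.random() < node_fid:
            annotations[node] = set(module_terms[structure.fine_labels[node]])
        else:
            annotations[node] = {background[rng.integers(len(background))]}
    return AnnotationSet(annotations=annotations, dag=dag, root=ROOT_TERM)


def generate_growth_profiles(
    structure: PlantedStructure,
    n_conditions: int = 418,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> GrowthMatrix:
    """Knockout growth log-ratio profiles with planted module correlation.

    Each fine module draws a latent standard-normal condition-response vector;
    a profiled protein's log-ratio vector is ``effect_size * latent +
    N(0, noise_sd^2)`` noise.  A ``missing_fraction`` of proteins carry no
    profile, mirroring the real situation where lethal deletions leave many
    proteins unprofiled.  The default 418 conditions matches the size of the
    published homozygous-deletion growth screen this emulates.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    modules = sorted(set(structure.fine_labels.values()))
    latent = {m: rng.standard_normal(n_conditions) for m in modules}
    nodes = sorted(structure.fine_labels, key=str)
    profiled = [n for n in nodes if rng.random() >= missing_fraction]
    rows = {
        node: effect_size * latent[structure.fine_labels[node]]
        + rng.normal(0.0, noise_sd, n_conditions)
        for node in profiled
    }
    profiles = pd.DataFrame.from_dict(rows, orient="index")
    profiles.columns = [f"condition_{t + 1}" for t in range(n_conditions)]
    control = pd.Series(rng.uniform(0.5, 2.0, len(profiled)), index=profiled)
    return GrowthMatrix(profiles=profiles, control_mean=control)


def generate_mixed_benchmark(
    n_coarse: int = 2,
    fine_per_coarse: int = 4,
    fine_size: int = 12,
    p_dense: float = 0.7,
    p_sparse: float = 0.25,
    p_coarse: float = 0.1,
    p_between: float = 0.01,
    seed: int = 0,
) -> tuple[Network, PlantedStructure, AnnotationSet]:
    """Benchmark mixing functionally homogeneous and incoherent communities.

    Alternating fine modules are dense (edge probability ``p_dense``) with
    perfect annotation fidelity, or sparse (``p_sparse``) with zero fidelity —
    coupling intra-community wiring density to functional coherence the way
    real interaction networks couple them.  This is the testbed for asking
    which topological metrics of a community predict its functional
    homogeneity.
    """
    n_fine = n_coarse * fine_per_coarse
    dense = [f % 2 == 0 for f in range(n_fine)]
    net, structure = generate_planted_network(
        n_coarse, fine_per_coarse, fine_size,
        p_fine=p_dense, p_coarse=p_coarse, p_between=p_between, seed=seed,
        p_fine_per_module=[p_dense if d else p_sparse for d in dense],
    )
    ann = generate_annotations(
        structure,
        fidelity=1.0,
        seed=seed + 1,
        fidelity_per_module={f: (1.0 if d else 0.0) for f, d in enumerate(dense)},
    )
    return net, structure, ann


# ---------------------------------------------------------------------------
# writers (all plain text)
# ---------------------------------------------------------------------------

def write_edge_tsv(net: Network, path: str | Path, itype: str = "A") -> None:
    """Interaction-record TSV in the standard five-column layout.

    The evidence code is chosen so the default evidence map reads the file
    back with the requested type (``affinity capture`` for A,
    ``yeast-two-hybrid`` for P).
    """
    evidence = "affinity capture" if itype == "A" else "yeast-two-hybrid"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein_a", "protein_b", "interaction_type", "source", "evidence"])
        for u, v in sorted(net.edges):
            writer.writerow([u, v, itype, "synthetic", evidence])


def write_annotation_tsv(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein", "term"])
        for protein in sorted(ann.annotations, key=str):
            for term in sorted(ann.annotations[protein]):
                writer.writerow([protein, term])


def write_obo(ann: AnnotationSet, path: str | Path) -> None:
    """Minimal OBO rendering of the term DAG (id / is_a stanzas only)."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(ann.dag):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        for parent in sorted(ann.dag[term]):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_growth_csv(gm: GrowthMatrix, path: str | Path, raw_rates: bool = False) -> None:
    """Growth CSV: rows = strains, columns = control_mean then conditions.

    With ``raw_rates`` the stored log-ratios L are converted back to raw
    growth rates ``control_mean * 2**L`` so the reader's log-ratio transform
    is exercised.
    """
    df = gm.profiles.copy()
    if raw_rates:
        df = gm.control_mean.loc[df.index].values[:, None] * np.exp2(df)
    out = df.copy()
    out.insert(0, "control_mean", gm.control_mean.loc[df.index])
    out.index.name = "strain"
    out.to_csv(path)


def write_labels_csv(structure: PlantedStructure, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein", "fine_module", "coarse_module"])
        for node in sorted(structure.fine_labels, key=str):
            writer.writerow([node, structure.fine_labels[node], structure.coarse_labels[node]])
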