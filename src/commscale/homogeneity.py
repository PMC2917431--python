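"""Interaction-controlled test of community functional homogeneity.

Interacting proteins are more functionally similar than random pairs, and a
community necessarily contains many interacting pairs, so term-enrichment
style tests overstate the functional coherence of communities.  The test here
controls for interaction: each interacting pair's similarity ``S_ij`` is
z-scored against the mean and population standard deviation of S over *all*
interacting pairs of the network,

    z_ij = (S_ij - mu) / sigma,

and a community is scored by the mean of ``z_ij`` over its internal edges.
A community is called *functionally homogeneous* when that mean exceeds a
threshold (default 0.3, strictly).  The aggregate z-score of n pair z-scores,
``sqrt(n) * mean_z``, deliberately plays no role in the call: using the mean
alone makes communities of different sizes (hence different resolutions)
comparable.  The 0.3 default is anchored by the aggregate statistic — for a
community with 30 internal pairs, mean_z = 0.3 sits at the one-sided 0.05
normal significance boundary — but the call itself ignores sample size and is
not a conventional significance test.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import numpy as np
import pandas as pd

from commscale.network_io import Network
from commscale.potts import Partition, PartitionSweep
from commscale.similarity import EdgeSimilarity

DEFAULT_THRESHOLD = 0.3
DEFAULT_MIN_SIZE = 4


class DegenerateSimilarityError(ValueError):
    """All interacting-pair similarities identical; z-scores undefined."""


@dataclass
class EdgeZScores:
    measure: str
    z: dict[tuple, float]  # canonical pair -> z-score
    mu: float
    sigma: float


@dataclass
class CommunityCall:
    """Homogeneity assessment of one community at one resolution (one measure)."""

    log_lambda: float
    community: int
    size: int
    measure: str
    n_internal_pairs: int
    mean_z: float
    aggregate_z: float
    homogeneous: bool


def zscore_edges(es: EdgeSimilarity) -> EdgeZScores:
    """Z-score interacting-pair similarities against their own population.

    Uses the population (divide-by-n) standard deviation: the scored pair set
    is the entire population of interacting pairs, not a sample from it.
    """
    if len(es.values) < 2:
        raise DegenerateSimilarityError("need at least 2 scored pairs to z-score")
    vals = np.array(list(es.values.values()), dtype=float)
    mu = float(vals.mean())
    sigma = float(vals.std())  # population convention (ddof=0)
    if sigma == 0.0:
        raise DegenerateSimilarityError("all pair similarities identical (sigma = 0)")
    return EdgeZScores(
        measure=es.measure,
        z={pair: (v - mu) / sigma for pair, v in es.values.items()},
        mu=mu,
        sigma=sigma,
    )


def community_mean_z(
    partition: Partition, net: Network, ez: EdgeZScores
) -> dict[int, tuple[int, float]]:
    """Per community: (number of scored internal edges, mean z over them).

    Communities with no scored internal edge map to (0, nan) — missing, not
    zero: absence of data is not evidence of inhomogeneity.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    assignment = partition.assignment
    for (u, v), z in ez.z.items():
        cu = assignment.get(u)
        if cu is not None and cu == assignment.get(v):
            sums[cu] = sums.get(cu, 0.0) + z
            counts[cu] = counts.get(cu, 0) + 1
    out: dict[int, tuple[int, float]] = {}
    for label in set(assignment.values()):
        n = counts.get(label, 0)
        out[label] = (n, sums[label] / n if n else float("nan"))
    return out


def aggregate_z(mean_z: float, n_pairs: int) -> float:
    """sqrt(n) * mean_z — the aggregate z of n individual pair z-scores."""
    if n_pairs < 1:
        raise ValueError("aggregate z undefined for zero pairs")
    return math.sqrt(n_pairs) * mean_z


def critical_mean_z(n_pairs: int, alpha: float = 0.05) -> float:
    """Smallest mean z whose aggregate z reaches one-sided significance alpha.

    Equals ``z_{1-alpha} / sqrt(n)``; at n = 30 this is ~0.300, the anchor for
    the default homogeneity threshold.
    """
    from scipy.stats import norm

    return float(norm.ppf(1.0 - alpha)) / math.sqrt(n_pairs)


def call_communities(
    sw: PartitionSweep,
    ez_by_measure: Mapping[str, EdgeZScores],
    net: Network,
    threshold: float = DEFAULT_THRESHOLD,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[CommunityCall]:
    """Homogeneity calls for every (resolution, community, measure).

    A community is homogeneous under a measure iff its mean internal-edge z
    strictly exceeds ``threshold`` and it has at least one scored internal
    edge; communities with no scored internal edge are excluded (missing
    data, not negative evidence).  Only communities of size >= ``min_size``
    are reported (pass 1 to disable the reporting filter).
    """
    calls: list[CommunityCall] = []
    for ll in sw.log_grid:
        part = sw.partitions[ll]
        sizes: dict[int, int] = {}
        for lab in part.assignment.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        for measure, ez in ez_by_measure.items():
            stats = community_mean_z(part, net, ez)
            for label in sorted(stats):
                size = sizes[label]
                if size < min_size:
                    continue
                n_pairs, mean_z = stats[label]
                if n_pairs == 0:
                    continue
                calls.append(
                    CommunityCall(
                        log_lambda=ll,
                        community=label,
                        size=size,
                        measure=measure,
                        n_internal_pairs=n_pairs,
                        mean_z=mean_z,
                        aggregate_z=aggregate_z(mean_z, n_pairs),
                        homogeneous=bool(mean_z > threshold),
                    )
                )
    return calls


def calls_to_frame(calls: Iterable[CommunityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "log10_lambda": c.log_lambda,
                "community": c.community,
                "size": c.size,
                "measure": c.measure,
                "n_internal_pairs": c.n_internal_pairs,
                "mean_z": c.mean_z,
                "aggregate_z": c.aggregate_z,
                "homogeneous": c.homogeneous,
            }
            for c in calls
        ]
    )


def sweep_summary(
    calls: Iterable[CommunityCall], sw: PartitionSweep, min_size: int = DEFAULT_MIN_SIZE
) -> pd.DataFrame:
    """Per-resolution counts: communities of size >= min_size, proteins in
    them, and (per measure) how many of each are homogeneous."""
    calls = list(calls)
    measures = sorted({c.measure for c in calls})
    rows = []
    for ll in sw.log_grid:
        part = sw.partitions[ll]
        comms = part.communities
        big = {lab: members for lab, members in comms.items() if len(members) >= min_size}
        row: dict = {
            "log10_lambda": ll,
            "n_communities": len(big),
            "n_proteins": sum(len(m) for m in big.values()),
        }
        for measure in measures:
            homog = {
                c.community
                for c in calls
                if c.log_lambda == ll and c.measure == measure and c.homogeneous
            }
            homog &= set(big)
            row[f"n_homog_{measure}"] = len(homog)
            row[f"n_proteins_homog_{measure}"] = sum(len(big[lab]) for lab in homog)
        rows.append(row)
    return pd.DataFrame(rows)


def type_fractions(
    calls: Iterable[CommunityCall],
    sw: PartitionSweep,
    type_sets: Mapping[str, set],
    measure: str = "G",
) -> pd.DataFrame:
    """Fraction of each protein type's members lying in homogeneous communities,
    per resolution.  Types with no members in the network are skipped."""
    import warnings

    calls = [c for c in calls if c.measure == measure]
    rows = []
    for ll in sw.log_grid:
        part = sw.partitions[ll]
        homog = {c.community for c in calls if c.log_lambda == ll and c.homogeneous}
        in_homog = {n for n, lab in part.assignment.items() if lab in homog}
        universe = set(part.assignment)
        for tname, members in type_sets.items():
            present = set(members) & universe
            if not present:
                warnings.warn(f"type {tname!r} has no proteins in the network; skipped")
                continue
            rows.append(
                {
                    "log10_lambda": ll,
                    "type": tname,
                    "n_proteins": len(present),
                    "fraction_in_homogeneous": len(present & in_homog) / len(present),
                }
            )
    return pd.DataFrame(rows)


def trace_protein(
    sw: PartitionSweep,
    calls: Iterable[CommunityCall],
    net: Network,
    protein: Hashable,
) -> pd.DataFrame:
    """Per-resolution record of the protein's community: size, mean clustering
    coefficient of the community's induced subgraph, and mean internal-edge z
    per measure.

    Long plateaus in community size across resolutions flag communities that
    resist splitting — the resolution-robust structures worth inspecting.
    ``calls`` should be produced with ``min_size=1`` so small communities are
    traced too.
    """
    from commscale.topology import community_metrics

    calls = list(calls)
    if protein not in sw.partitions[sw.log_grid[0]].assignment:
        raise KeyError(f"protein {protein!r} not in the swept network")
    measures = sorted({c.measure for c in calls})
    by_key = {(c.log_lambda, c.community, c.measure): c for c in calls}
    rows = []
    for ll in sw.log_grid:
        part = sw.partitions[ll]
        label = part.assignment[protein]
        members = {n for n, lab in part.assignment.items() if lab == label}
        rec = community_metrics(net, members, ["mean_clustering"])
        row: dict = {
            "log10_lambda": ll,
            "community": label,
            "size": len(members),
            "mean_clustering": rec.values["mean_clustering"],
        }
        for m in measures:
            call = by_key.get((ll, label, m))
            row[f"mean_z_{m}"] = call.mean_z if call else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
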