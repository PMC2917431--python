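"""Interaction-controlled homogeneity test: z-scoring, calls, summaries, traces."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from commscale import homogeneity as hmg
from commscale.network_io import Network
from commscale.potts import Partition, PartitionSweep, nmi, sweep
from commscale.similarity import EdgeSimilarity, edge_similarity
from commscale.synthetic_data import generate_annotations, generate_planted_network


def _es(values, measure="G"):
    vals = {tuple(sorted(k)): v for k, v in values.items()}
    return EdgeSimilarity(measure=measure, values=vals, coverage=set())


class TestZScoreEdges:
    def test_closed_form(self):
        es = _es({("a", "b"): 0.1, ("b", "c"): 0.2, ("c", "d"): 0.3, ("d", "e"): 0.4})
        ez = hmg.zscore_edges(es)
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        sigma = vals.std()  # population convention
        assert ez.z[("d", "e")] == pytest.approx((0.4 - 0.25) / sigma)

    def test_normalization_identity(self):
        rng = np.random.default_rng(1)
        es = _es({("a", str(i)): v for i, v in enumerate(rng.random(100))})
        ez = hmg.zscore_edges(es)
        z = np.array(list(ez.z.values()))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_degenerate_raises(self):
        es = _es({("a", "b"): 0.5, ("b", "c"): 0.5})
        with pytest.raises(hmg.DegenerateSimilarityError):
            hmg.zscore_edges(es)


class TestCommunityMeanZ:
    def _setup(self):
        rng = np.random.default_rng(7)
        edges = [(f"n{i}", f"n{j}") for i in range(12) for j in range(i + 1, 12) if rng.random() < 0.5]
        net = Network.from_edges(edges)
        es = _es({e: rng.random() for e in net.edges})
        return net, hmg.zscore_edges(es)

    def test_whole_network_mean_is_zero(self):
        net, ez = self._setup()
        part = Partition(assignment={n: 0 for n in net.nodes}, lam=1.0, energy=0.0)
        stats = hmg.community_mean_z(part, net, ez)
        n, mean = stats[0]
        assert n == len(ez.z)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_single_edge_community(self):
        net = Network.from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        ez = hmg.zscore_edges(_es({("a", "b"): 0.1, ("b", "c"): 0.5, ("c", "d"): 0.9}))
        part = Partition(assignment={"a": 0, "b": 0, "c": 1, "d": 1}, lam=1.0, energy=0.0)
        stats = hmg.community_mean_z(part, net, ez)
        assert stats[0] == (1, pytest.approx(ez.z[("a", "b")]))
        assert stats[1] == (1, pytest.approx(ez.z[("c", "d")]))

    def test_brute_force_bipartition(self):
        net, ez = self._setup()
        rng = np.random.default_rng(3)
        assignment = {n: int(rng.integers(2)) for n in net.nodes}
        part = Partition(assignment=assignment, lam=1.0, energy=0.0)
        stats = hmg.community_mean_z(part, net, ez)
        for label in (0, 1):
            zs = [
                z for (u, v), z in ez.z.items()
                if assignment[u] == label and assignment[v] == label
            ]
            n, mean = stats[label]
            assert n == len(zs)
            if zs:
                assert mean == pytest.approx(np.mean(zs))
            else:
                assert math.isnan(mean)


class TestAggregateZ:
    def test_paper_threshold_anchor(self):
        # mean z 0.3 with 30 pairs sits at the one-sided 0.05 boundary:
        # the critical mean z for 30 pairs is z_0.95/sqrt(30) = 0.3003 ~ 0.3
        assert hmg.aggregate_z(0.3, 30) == pytest.approx(math.sqrt(30) * 0.3)
        assert hmg.critical_mean_z(30) == pytest.approx(norm.ppf(0.95) / math.sqrt(30))
        assert round(hmg.critical_mean_z(30), 1) == 0.3

    def test_identities(self):
        assert hmg.aggregate_z(0.7, 1) == pytest.approx(0.7)
        assert hmg.aggregate_z(0.5, 4) == pytest.approx(1.0)

    def test_zero_pairs_undefined(self):
        with pytest.raises(ValueError):
            hmg.aggregate_z(0.3, 0)


def _planted_pipeline(fidelity, seed, shuffle=False):
    """Planted net + sweep + G-measure z-scores; optionally shuffled labels."""
    net, st = generate_planted_network(3, 2, 10, 0.8, 0.15, 0.01, seed=seed)
    sw = sweep(net, -0.5, 2.0, 0.25, seed=seed)
    ann = generate_annotations(st, fidelity=fidelity, seed=seed + 1)
    if shuffle:
        rng = np.random.default_rng(seed + 2)
        proteins = sorted(ann.annotations, key=str)
        perm = rng.permutation(len(proteins))
        ann.annotations = {
            proteins[i]: ann.annotations[proteins[perm[i]]] for i in range(len(proteins))
        }
    es = edge_similarity(net, "G", ann, all_pairs_sample=0, seed=seed)
    ez = hmg.zscore_edges(es)
    return net, st, sw, ez


class TestCallCommunities:
    def test_boundary_is_strict(self):
        # one community holds exactly one scored edge, so its mean z is that
        # edge's z; setting the threshold to that value must NOT call it
        net = Network.from_edges([("a", "b"), ("c", "d"), ("e", "f"), ("a", "c")])
        ez = hmg.zscore_edges(
            _es({("a", "b"): 0.4, ("c", "d"): 0.1, ("e", "f"): 0.2, ("a", "c"): 0.3})
        )
        z_ab = ez.z[("a", "b")]
        assignment = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 1, "f": 1}
        part = Partition(assignment=assignment, lam=1.0, energy=0.0)
        sw = PartitionSweep(log_grid=[0.0], partitions={0.0: part})
        at_exact = hmg.call_communities(sw, {"G": ez}, net, threshold=z_ab, min_size=1)
        below = hmg.call_communities(sw, {"G": ez}, net, threshold=z_ab - 1e-9, min_size=1)
        call_exact = next(c for c in at_exact if c.community == 0)
        call_below = next(c for c in below if c.community == 0)
        assert not call_exact.homogeneous
        assert call_below.homogeneous

    def test_recovered_planted_modules_called_homogeneous(self):
        net, st, sw, ez = _planted_pipeline(fidelity=1.0, seed=11)
        calls = hmg.call_communities(sw, {"G": ez}, net)
        # at the resolution best matching fine structure, most communities homogeneous
        best = max(sw.log_grid, key=lambda ll: nmi(sw.partitions[ll].assignment, st.fine_labels))
        at_best = [c for c in calls if c.log_lambda == best]
        assert at_best
        frac = np.mean([c.homogeneous for c in at_best])
        assert frac >= 0.9

    def test_shuffled_annotations_rarely_called(self):
        n_total = n_hom = 0
        for seed in range(10):
            net, st, sw, ez = _planted_pipeline(fidelity=1.0, seed=seed, shuffle=True)
            calls = hmg.call_communities(sw, {"G": ez}, net)
            n_total += len(calls)
            n_hom += sum(c.homogeneous for c in calls)
        assert n_total > 0
        assert n_hom / n_total <= 0.10

    def test_permutation_null_centered_at_zero(self):
        grand_means = []
        for seed in range(12):
            _, _, sw, ez = _planted_pipeline(fidelity=1.0, seed=seed + 100, shuffle=True)
            calls = hmg.call_communities(sw, {"G": ez}, net=None)
            grand_means.append(np.mean([c.mean_z for c in calls]))
        se = np.std(grand_means, ddof=1) / np.sqrt(len(grand_means))
        assert abs(np.mean(grand_means)) < 3 * se + 1e-12


class TestSummaries:
    def _toy_calls_sweep(self):
        assignment = {}
        for i in range(5):
            assignment[f"a{i}"] = 0
        for i in range(3):
            assignment[f"b{i}"] = 1
        for i in range(2):
            assignment[f"c{i}"] = 2
        part = Partition(assignment=assignment, lam=1.0, energy=0.0)
        sw = PartitionSweep(log_grid=[0.0], partitions={0.0: part})
        calls = [
            hmg.CommunityCall(0.0, 0, 5, "G", 4, 0.5, 1.0, True),
            hmg.CommunityCall(0.0, 1, 3, "G", 2, -0.1, -0.14, False),
        ]
        return sw, calls

    def test_counts_and_protein_sums(self):
        sw, calls = self._toy_calls_sweep()
        df = hmg.sweep_summary(calls, sw, min_size=4)
        row = df.iloc[0]
        assert row["n_communities"] == 1
        assert row["n_proteins"] == 5
        assert row["n_homog_G"] == 1
        assert row["n_proteins_homog_G"] == 5

    def test_no_homogeneous_gives_zeros(self):
        sw, calls = self._toy_calls_sweep()
        calls = [c for c in calls if not c.homogeneous]
        df = hmg.sweep_summary(calls, sw, min_size=4)
        assert df.iloc[0]["n_homog_G"] == 0
        assert df.iloc[0]["n_proteins_homog_G"] == 0

    def test_proteins_in_homogeneous_peaks_at_intermediate_resolution(self):
        net, st, sw, ez = _planted_pipeline(fidelity=1.0, seed=21)
        calls = hmg.call_communities(sw, {"G": ez}, net)
        df = hmg.sweep_summary(calls, sw)
        col = df["n_proteins_homog_G"].to_numpy()
        peak = int(np.argmax(col))
        assert col[peak] > col[0]  # not at the coarsest resolution


class TestTypeFractions:
    def test_extremes(self):
        assignment = {f"a{i}": 0 for i in range(5)} | {f"b{i}": 1 for i in range(4)}
        part = Partition(assignment=assignment, lam=1.0, energy=0.0)
        sw = PartitionSweep(log_grid=[0.0], partitions={0.0: part})
        calls = [
            hmg.CommunityCall(0.0, 0, 5, "G", 4, 0.6, 1.2, True),
            hmg.CommunityCall(0.0, 1, 4, "G", 3, -0.2, -0.35, False),
        ]
        inside = {f"a{i}" for i in range(5)}
        outside = {f"b{i}" for i in range(4)}
        df = hmg.type_fractions(calls, sw, {"in": inside, "out": outside})
        by_type = df.set_index("type")["fraction_in_homogeneous"]
        assert by_type["in"] == 1.0
        assert by_type["out"] == 0.0

    def test_empty_type_skipped_with_warning(self):
        part = Partition(assignment={"a": 0}, lam=1.0, energy=0.0)
        sw = PartitionSweep(log_grid=[0.0], partitions={0.0: part})
        with pytest.warns(UserWarning, match="skipped"):
            df = hmg.type_fractions([], sw, {"ghost": {"zzz"}})
        assert df.empty


class TestTraceProtein:
    def test_trace_shape_and_plateau(self):
        net, st, sw, ez = _planted_pipeline(fidelity=1.0, seed=31)
        calls = hmg.call_communities(sw, {"G": ez}, net, min_size=1)
        protein = sorted(net.nodes)[0]
        df = hmg.trace_protein(sw, calls, net, protein)
        assert len(df) == len(sw.log_grid)
        # during fine-module recovery the trace shows a positive mean-z plateau
        best = max(sw.log_grid, key=lambda ll: nmi(sw.partitions[ll].assignment, st.fine_labels))
        row = df[df["log10_lambda"] == best].iloc[0]
        assert row["mean_z_G"] > 0

    def test_unknown_protein_raises(self):
        net, st, sw, ez = _planted_pipeline(fidelity=1.0, seed=31)
        with pytest.raises(KeyError):
            hmg.trace_protein(sw, [], net, "not-a-protein")

    def test_singleton_community_has_missing_mean_z(self):
        net = Network.from_edges([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        ez = hmg.zscore_edges(
            _es({("a", "b"): 0.2, ("b", "c"): 0.4, ("c", "a"): 0.6, ("c", "d"): 0.9})
        )
        assignment = {"a": 0, "b": 0, "c": 0, "d": 1}
        part = Partition(assignment=assignment, lam=1.0, energy=0.0)
        sw = PartitionSweep(log_grid=[0.0], partitions={0.0: part})
        calls = hmg.call_communities(sw, {"G": ez}, net, min_size=1)
        df = hmg.trace_protein(sw, calls, net, "d")
        assert df.iloc[0]["size"] == 1
        assert math.isnan(df.iloc[0]["mean_z_G"])
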