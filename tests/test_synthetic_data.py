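"""Planted benchmark generators: densities, signal control, reproducibility."""

import itertools

import numpy as np
import pytest

from commscale import synthetic_data as syn
from commscale.similarity import (
    edge_similarity,
    go_similarity,
    growth_correlation,
    propagate_annotations,
    read_growth_csv,
)


class TestPlantedNetwork:
    def test_p_one_gives_complete_module(self):
        net, _ = syn.generate_planted_network(1, 1, 5, 1.0, 0.5, 0.0, seed=0)
        assert net.n_nodes == 5
        assert net.W == 10

    def test_within_fine_density(self):
        dens = []
        for seed in range(50):
            net, st = syn.generate_planted_network(2, 2, 8, 0.9, 0.3, 0.02, seed=seed)
            realized = possible = 0
            for mod in st.fine_modules.values():
                for u, v in itertools.combinations(sorted(mod), 2):
                    possible += 1
                    realized += net.has_edge(u, v)
            dens.append(realized / possible)
        assert np.mean(dens) == pytest.approx(0.9, abs=0.05)

    def test_isolated_modules_without_cross_edges(self):
        import networkx as nx

        net, st = syn.generate_planted_network(
            2, 2, 8, 0.95, 0.0, 0.0, seed=1, keep_lcc=False
        )
        n_comp = nx.number_connected_components(net.simple())
        assert n_comp == len(st.fine_modules)

    def test_probability_ordering_enforced(self):
        with pytest.raises(ValueError, match="p_fine > p_coarse"):
            syn.generate_planted_network(2, 2, 8, 0.3, 0.5, 0.1, seed=0)

    def test_reproducible_and_valid(self):
        a, sa = syn.generate_planted_network(2, 3, 6, 0.8, 0.2, 0.02, seed=42)
        b, sb = syn.generate_planted_network(2, 3, 6, 0.8, 0.2, 0.02, seed=42)
        assert a == b
        assert sa.fine_labels == sb.fine_labels
        # undirected, no duplicate edges, nested hierarchy
        assert len(a.edges) == len(set(a.edges))
        for node, f in sa.fine_labels.items():
            assert node in sa.coarse_labels

    def test_heterogeneous_modules(self):
        net, st = syn.generate_planted_network(
            2, 2, 10, 0.8, 0.1, 0.01, seed=0, p_fine_per_module=[0.9, 0.9, 0.3, 0.3]
        )
        dense = [m for f, m in st.fine_modules.items() if f < 2]
        sparse = [m for f, m in st.fine_modules.items() if f >= 2]

        def density(mod):
            pairs = list(itertools.combinations(sorted(mod), 2))
            return sum(net.has_edge(u, v) for u, v in pairs) / len(pairs)

        assert min(map(density, dense)) > max(map(density, sparse))


class TestErNetwork:
    def test_extremes(self):
        assert syn.generate_er_network(10, 0.0, seed=0).W == 0
        assert syn.generate_er_network(10, 1.0, seed=0).W == 45

    def test_mean_edge_count(self):
        counts = []
        for seed in range(100):
            import networkx as nx

            g = nx.fast_gnp_random_graph(200, 0.05, seed=seed)
            counts.append(g.number_of_edges())
        expected = 0.05 * 19900
        se = np.sqrt(19900 * 0.05 * 0.95) / np.sqrt(100)
        assert abs(np.mean(counts) - expected) < 3 * se


def _module_similarity_gap(fidelity, seed):
    """Mean within-module minus between-module G similarity."""
    net, st = syn.generate_planted_network(2, 1, 20, 0.9, 0.2, 0.05, seed=seed)
    ann = propagate_annotations(
        syn.generate_annotations(st, fidelity=fidelity, seed=seed + 1000)
    )
    n = ann.n_proteins
    within, between = [], []
    nodes = sorted(st.fine_labels)
    for u, v in itertools.combinations(nodes, 2):
        s = go_similarity(ann, u, v, n)
        (within if st.fine_labels[u] == st.fine_labels[v] else between).append(s)
    return np.mean(within) - np.mean(between)


class TestAnnotations:
    def test_full_fidelity_modules_share_terms(self):
        _, st = syn.generate_planted_network(2, 2, 6, 0.9, 0.3, 0.02, seed=0)
        ann = syn.generate_annotations(st, fidelity=1.0, seed=0)
        for mod in st.fine_modules.values():
            sets = {frozenset(ann.annotations[p]) for p in mod}
            assert len(sets) == 1

    def test_zero_fidelity_no_signal(self):
        gaps = [_module_similarity_gap(0.0, seed) for seed in range(20)]
        se = np.std(gaps, ddof=1) / np.sqrt(len(gaps))
        assert abs(np.mean(gaps)) < 2 * se + 1e-12

    def test_high_fidelity_within_exceeds_between(self):
        wins = sum(_module_similarity_gap(0.9, seed) > 0 for seed in range(100))
        assert wins >= 95

    def test_monotone_signal_in_fidelity(self):
        means = []
        for fid in (0.0, 0.5, 1.0):
            means.append(np.mean([_module_similarity_gap(fid, s) for s in range(10)]))
        assert means[0] <= means[1] <= means[2]


class TestGrowthProfiles:
    def test_small_noise_gives_perfect_correlation(self):
        _, st = syn.generate_planted_network(2, 1, 10, 0.9, 0.2, 0.05, seed=0)
        gm = syn.generate_growth_profiles(st, 50, effect_size=2.0, noise_sd=1e-9, seed=0)
        mod = sorted(next(iter(st.fine_modules.values())))
        assert growth_correlation(gm, mod[0], mod[1]) == pytest.approx(1.0, abs=1e-6)

    def test_zero_effect_no_within_module_correlation(self):
        means = []
        for seed in range(20):
            _, st = syn.generate_planted_network(2, 1, 10, 0.9, 0.2, 0.05, seed=seed)
            gm = syn.generate_growth_profiles(st, 100, effect_size=0.0, noise_sd=1.0, seed=seed)
            cors = []
            for mod in st.fine_modules.values():
                for u, v in itertools.combinations(sorted(mod), 2):
                    cors.append(growth_correlation(gm, u, v))
            means.append(np.mean(cors))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-12

    def test_missing_fraction_binomial(self):
        _, st = syn.generate_planted_network(2, 5, 10, 0.9, 0.2, 0.05, seed=0)
        n = len(st.fine_labels)
        assert n == 100
        counts = [
            len(
                syn.generate_growth_profiles(
                    st, 10, missing_fraction=0.3, seed=s
                ).proteins
            )
            for s in range(30)
        ]
        sd = np.sqrt(100 * 0.3 * 0.7)
        assert abs(np.mean(counts) - 70) < 3 * sd / np.sqrt(30)


class TestWriters:
    def test_seed_reproducibility_byte_for_byte(self, tmp_path):
        for name in ("x", "y"):
            net, st = syn.generate_planted_network(2, 2, 6, 0.8, 0.2, 0.02, seed=5)
            ann = syn.generate_annotations(st, fidelity=0.8, seed=6)
            gm = syn.generate_growth_profiles(st, 20, seed=7)
            d = tmp_path / name
            d.mkdir()
            syn.write_edge_tsv(net, d / "edges.tsv")
            syn.write_annotation_tsv(ann, d / "ann.tsv")
            syn.write_obo(ann, d / "ont.obo")
            syn.write_growth_csv(gm, d / "growth.csv")
            syn.write_labels_csv(st, d / "labels.csv")
        for f in ("edges.tsv", "ann.tsv", "ont.obo", "growth.csv", "labels.csv"):
            assert (tmp_path / "x" / f).read_bytes() == (tmp_path / "y" / f).read_bytes()

    def test_raw_rate_writer_roundtrips_through_log_transform(self, tmp_path):
        _, st = syn.generate_planted_network(1, 2, 5, 0.9, 0.2, 0.01, seed=3)
        gm = syn.generate_growth_profiles(st, 15, seed=3)
        path = tmp_path / "growth_raw.csv"
        syn.write_growth_csv(gm, path, raw_rates=True)
        back = read_growth_csv(path, raw_rates=True)
        np.testing.assert_allclose(back.profiles.values, gm.profiles.values, atol=1e-10)
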