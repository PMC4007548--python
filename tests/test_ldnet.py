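"""LD pairs, CI haplotype blocks, median-joining network, clade split."""

import numpy as np
import pytest

import oracles
from balsel.coalsim import DemographicModel, SimConfig, simulate, simulate_balanced
from balsel.haplotypes import HaplotypeAlignment
from balsel.ldnet import ci_blocks, clade_split, dprime_ci, ld_pair, mj_network
from conftest import random_alignment


def _aln(H, positions=None, pops=None, L=None):
    H = np.asarray(H, dtype=np.int8)
    n, S = H.shape
    positions = positions if positions is not None else np.arange(1, S + 1)
    L = L or (int(max(positions, default=1)) + 10)
    return HaplotypeAlignment(
        "t", 1, L, positions, H,
        [f"h{i}" for i in range(n)],
        list(pops) if pops else ["p"] * n,
        polarized=np.ones(S, dtype=bool),
        outgroup=np.zeros(S, dtype=np.int8),
    )


class TestLdPair:
    def test_identical_columns_full_ld(self):
        col = np.array([1, 1, 0, 0])
        p = ld_pair(_aln(np.stack([col, col], axis=1)), 0, 1)
        assert p.r2 == pytest.approx(1.0)
        assert p.Dprime == pytest.approx(1.0)

    def test_three_gametes_complete_but_imperfect(self):
        # gametes 11, 10, 00 present; 01 absent
        H = np.array([[1, 1], [1, 1], [1, 0], [0, 0], [0, 0], [0, 0]])
        p = ld_pair(_aln(H), 0, 1)
        assert p.Dprime == pytest.approx(1.0)
        assert p.r2 < 1.0

    def test_hand_computed_counts(self):
        H = np.array([[1, 1]] * 30 + [[1, 0]] * 10 + [[0, 1]] * 10 + [[0, 0]] * 30)
        p = ld_pair(_aln(H), 0, 1)
        assert p.D == pytest.approx(0.125)
        assert p.Dprime == pytest.approx(0.5)
        assert p.r2 == pytest.approx(0.25)

    def test_monomorphic_site_rejected(self):
        H = np.array([[1, 1], [0, 1], [1, 1], [0, 1]])
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair(_aln(H), 0, 1)

    def test_r2_equals_squared_pearson_correlation(self, rng):
        for _ in range(20):
            aln = random_alignment(rng, n=12, S=6)
            seg = np.flatnonzero(aln.segregating())
            if len(seg) < 2:
                continue
            i, j = int(seg[0]), int(seg[1])
            p = ld_pair(aln, i, j)
            r = np.corrcoef(aln.H[:, i], aln.H[:, j])[0, 1]
            assert p.r2 == pytest.approx(r * r, abs=1e-12)

    def test_matches_brute_force(self, rng):
        aln = random_alignment(rng, n=10, S=4)
        seg = np.flatnonzero(aln.segregating())
        i, j = int(seg[0]), int(seg[1])
        got = ld_pair(aln, i, j)
        D, dp, r2 = oracles.ld_bruteforce(aln.H[:, i], aln.H[:, j])
        assert got.D == pytest.approx(D, abs=1e-12)
        assert got.Dprime == pytest.approx(dp, abs=1e-12)
        assert got.r2 == pytest.approx(r2, abs=1e-12)


class TestCiBlocks:
    def test_perfect_run_one_block(self):
        col = np.array([1] * 20 + [0] * 20)
        H = np.stack([col] * 6, axis=1)
        blocks = ci_blocks(_aln(H, positions=[10, 20, 30, 40, 50, 60]))
        assert len(blocks) == 1
        assert blocks[0].n_sites == 6

    def test_recombinant_site_splits_blocks(self, rng):
        col = np.array([1] * 20 + [0] * 20)
        mid = col.copy()
        rng.shuffle(mid)  # r^2 ~ 0 with both runs
        H = np.stack([col, col, col, mid, col[::-1], col[::-1], col[::-1]], axis=1)
        blocks = ci_blocks(_aln(H, positions=[10, 20, 30, 40, 50, 60, 70]))
        assert len(blocks) == 2
        sites = [(b.first_site, b.last_site) for b in blocks]
        assert sites == [(0, 2), (4, 6)]

    def test_small_sample_cis_too_wide(self):
        col = np.array([1, 1, 1, 0, 0, 0])
        H = np.stack([col] * 4, axis=1)
        assert ci_blocks(_aln(H)) == []

    def test_maf_filter_leaves_no_pairs(self):
        col = np.array([1] + [0] * 39)   # MAF 0.025 < 0.05
        H = np.stack([col] * 3, axis=1)
        assert ci_blocks(_aln(H)) == []

    def test_blocks_never_cross_a_free_recombination_point(self):
        """Two independently simulated halves (crossover probability 1/2
        between the flanking SNPs) are never joined into one block."""
        model = DemographicModel.constant(10000)
        crossings = 0
        checked = 0
        for seed in range(25):
            left = simulate(
                SimConfig(n=[40], L=2000, theta=4.0, seed=700 + seed), model
            )[0].alignment
            right = simulate(
                SimConfig(n=[40], L=2000, theta=4.0, seed=800 + seed), model
            )[0].alignment
            if left.n_sites < 2 or right.n_sites < 2:
                continue
            H = np.concatenate([left.H, right.H], axis=1)
            pos = np.concatenate([left.positions, right.positions + 2000])
            aln = _aln(H, positions=pos, L=4000)
            boundary = left.n_sites  # first site index of the right half
            for b in ci_blocks(aln):
                checked += 1
                if b.first_site < boundary <= b.last_site:
                    crossings += 1
        assert checked > 0
        assert crossings == 0

    def test_dprime_ci_tightens_with_sample_size(self):
        col_small = np.array([1, 1, 1, 0, 0, 0])
        col_big = np.array([1] * 20 + [0] * 20)
        lo_s, _ = dprime_ci(_aln(np.stack([col_small] * 2, axis=1)), 0, 1)
        lo_b, _ = dprime_ci(_aln(np.stack([col_big] * 2, axis=1)), 0, 1)
        assert lo_b > lo_s


class TestMjNetwork:
    def test_path_topology(self):
        aln = _aln(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]]))
        net = mj_network(aln)
        haps = {d["hap"] for _, d in net.nodes(data=True)}
        assert haps == {(0, 0, 0), (1, 0, 0), (1, 1, 0)}
        edges = {
            frozenset((net.nodes[a]["hap"], net.nodes[b]["hap"]))
            for a, b in net.edges
        }
        assert edges == {
            frozenset({(0, 0, 0), (1, 0, 0)}),
            frozenset({(1, 0, 0), (1, 1, 0)}),
        }
        assert all(d["weight"] == 1 for _, _, d in net.edges(data=True))

    def test_median_vector_steiner_point(self):
        aln = _aln(np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]]))
        net = mj_network(aln, epsilon=0)
        medians = [d for _, d in net.nodes(data=True) if d["median"]]
        assert len(medians) == 1
        assert medians[0]["hap"] == (1, 1, 1)
        # brute force over the whole 3-site haplotype space: 111 is the
        # unique point minimising the total connection cost
        obs = [(1, 1, 0), (1, 0, 1), (0, 1, 1)]
        costs = {}
        for x in range(8):
            v = tuple(int(b) for b in f"{x:03b}")
            costs[v] = sum(sum(a != b for a, b in zip(v, o)) for o in obs)
        assert min(costs, key=costs.get) == (1, 1, 1)

    def test_single_haplotype_single_node(self):
        aln = _aln(np.zeros((5, 0)))
        net = mj_network(aln)
        assert net.number_of_nodes() == 1
        assert net.nodes[0]["count"] == 5

    def test_edge_endpoints_differ_at_labelled_sites(self, rng):
        aln = random_alignment(rng, n=10, S=8)
        net = mj_network(aln)
        for a, b, d in net.edges(data=True):
            ha = np.asarray(net.nodes[a]["hap"])
            hb = np.asarray(net.nodes[b]["hap"])
            assert sorted(np.flatnonzero(ha != hb)) == sorted(d["sites"])
            assert d["weight"] == len(d["sites"])

    def test_multiplicities_sum_to_n(self, rng):
        aln = random_alignment(rng, n=14, S=9)
        net = mj_network(aln)
        assert sum(d["count"] for _, d in net.nodes(data=True)) == 14

    def test_infinite_sites_network_is_the_mutation_tree(self):
        """Recombination-free simulated data: total edge labels equal S."""
        model = DemographicModel.constant(10000)
        for seed in range(5):
            cfg = SimConfig(n=[20], L=3000, theta=6.0, seed=400 + seed)
            aln = simulate(cfg, model)[0].alignment
            if aln.n_sites == 0:
                continue
            net = mj_network(aln, attach_mrca=True)
            total = sum(d["weight"] for _, _, d in net.edges(data=True))
            assert total == aln.n_sites
            assert net.number_of_edges() == net.number_of_nodes() - 1  # tree

    def test_mrca_requires_polarized(self, rng):
        aln = random_alignment(rng, n=6, S=4)
        aln.polarized = np.zeros(4, dtype=bool)
        with pytest.raises(ValueError, match="polarized"):
            mj_network(aln, attach_mrca=True)


class TestCladeSplit:
    def test_heaviest_edge_cut(self):
        # path A -(1)- B -(5)- C
        H = np.zeros((3, 6), dtype=np.int8)
        H[1, 0] = 1                 # B differs from A at 1 site
        H[2, :] = 1                 # C differs from B at 5 more
        aln = _aln(H, pops=["x", "x", "y"])
        split = clade_split(mj_network(aln))
        assert split.cut_weight == 5
        assert split.clade_counts == (2, 1)
        assert split.pop_counts[0] == {"x": 2}
        assert split.pop_counts[1] == {"y": 1}

    def test_star_network_weak_split(self):
        H = np.eye(5, dtype=np.int8)  # star: each haplotype private mutation
        aln = _aln(H)
        split = clade_split(mj_network(aln, attach_mrca=True))
        assert split.weak
        assert min(split.clade_counts) == 1

    def test_balanced_simulation_recovers_allelic_classes(self):
        model = DemographicModel.constant(18000)
        agreements = []
        for seed in range(20):
            cfg = SimConfig(
                n=[40], L=4867, theta=8.0, seed=600 + seed,
                mode="balanced", balanced_age=160_000,
            )
            rep = simulate_balanced(cfg, model)[0]
            truth = rep.alignment.H[:, rep.focal_index]
            net = mj_network(rep.alignment)
            split = clade_split(net)
            assign = np.array(
                [split.clade_of_sample[i] for i in range(rep.alignment.n_hap)]
            )
            agree = max(
                np.mean(assign == truth), np.mean(assign == 1 - truth)
            )
            agreements.append(agree)
        assert np.median(agreements) >= 0.95
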