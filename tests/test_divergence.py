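import numpy as np
import pytest

from conftest import make_genome
from wisentmix.divergence import (
    distance_matrix,
    kde_density,
    neighbor_joining,
    window_divergence,
)
from wisentmix.windows import partition_windows


class TestWindowDivergence:
    def test_identical_sequences_zero_divergence(self):
        ga = make_genome("a", {"c": "ACGT" * 50})
        gb = make_genome("b", {"c": "ACGT" * 50})
        wt = partition_windows({"c": 200}, 100)
        rec = window_divergence(ga, gb, wt)
        assert (rec["divergence"] == 0).all()
        assert not rec["excluded"].any()

    def test_ten_site_toy_hand_count(self):
        # A<->G transition at position 4 and C<->T transition at position 9:
        # 2 total differences, 0 transversions
        ga = make_genome("a", {"c": "ACGTACGTAC"})
        gb = make_genome("b", {"c": "ACGTGCGTAT"})
        wt = partition_windows({"c": 10}, 10)
        rec_tv = window_divergence(ga, gb, wt, mode="tv").iloc[0]
        rec_all = window_divergence(ga, gb, wt, mode="all").iloc[0]
        assert rec_all["n_all_diff"] == 2
        assert rec_tv["n_tv_diff"] == 0
        assert rec_tv["divergence"] == 0.0
        assert rec_all["divergence"] == pytest.approx(0.2)

    def test_mostly_missing_window_excluded(self):
        ga = make_genome("a", {"c": "A" * 100})
        gb = make_genome("b", {"c": "N" * 80 + "A" * 20})
        wt = partition_windows({"c": 100}, 100)
        rec = window_divergence(ga, gb, wt).iloc[0]
        assert rec["missing_fraction"] == pytest.approx(0.8)
        assert rec["excluded"]

    def test_boundary_missing_not_excluded(self):
        gb = make_genome("b", {"c": "N" * 75 + "A" * 25})
        ga = make_genome("a", {"c": "A" * 100})
        wt = partition_windows({"c": 100}, 100)
        rec = window_divergence(ga, gb, wt).iloc[0]
        assert not rec["excluded"]  # rule is strictly greater than 75%

    def test_symmetry_and_mode_ordering(self, small_sim):
        _, genomes, _, windows = small_sim
        g = list(genomes.values())
        ab = window_divergence(g[0], g[1], windows, mode="tv")
        ba = window_divergence(g[1], g[0], windows, mode="tv")
        assert np.array_equal(ab["n_tv_diff"], ba["n_tv_diff"])
        assert np.array_equal(ab["n_comparable"], ba["n_comparable"])
        # tv-only differences can never exceed all differences
        assert (ab["n_tv_diff"] <= ab["n_all_diff"]).all()
        assert (ab["n_all_diff"] <= ab["n_comparable"]).all()

    def test_degenerate_flag_when_no_comparable_sites(self):
        ga = make_genome("a", {"c": "N" * 50})
        gb = make_genome("b", {"c": "A" * 50})
        wt = partition_windows({"c": 50}, 50)
        rec = window_divergence(ga, gb, wt, max_missing=1.0).iloc[0]
        assert rec["degenerate"] and np.isnan(rec["divergence"])


class TestKde:
    def test_density_integrates_to_one(self):
        x = np.random.default_rng(0).normal(size=512)
        grid, dens = kde_density(x)
        integral = np.trapezoid(dens, grid)
        assert abs(integral - 1) < 1e-3

    def test_symmetric_data_symmetric_density(self):
        x = np.concatenate([0.5 - np.linspace(0.01, 0.3, 100), 0.5 + np.linspace(0.01, 0.3, 100)])
        grid, dens = kde_density(x)
        # mean of the density matches the data centre to grid tolerance
        assert abs(np.trapezoid(grid * dens, grid) - 0.5) < 1e-3

    def test_two_separated_modes_detected(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0.0, 0.05, 400), rng.normal(1.0, 0.05, 400)])
        grid, dens = kde_density(x)
        interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])
        peaks = grid[1:-1][interior]
        assert peaks.size == 2
        assert abs(peaks[0] - 0.0) < 0.1 and abs(peaks[1] - 1.0) < 0.1

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            kde_density([0.5])


class TestDistanceMatrix:
    def test_identical_genomes_zero_matrix(self):
        gs = [make_genome(n, {"c": "ACGT" * 30}) for n in "abc"]
        wt = partition_windows({"c": 120}, 60)
        labels, mat = distance_matrix(gs, wt)
        assert labels == ["a", "b", "c"]
        assert np.allclose(mat, 0)

    def test_pooled_distance_is_weighted_window_mean(self, small_sim):
        _, genomes, _, windows = small_sim
        g = list(genomes.values())[:3]
        labels, mat = distance_matrix(g, windows, mode="tv")
        rec = window_divergence(g[0], g[1], windows, mode="tv")
        keep = ~rec["excluded"]
        w = rec.loc[keep, "n_comparable"]
        expected = np.average(rec.loc[keep, "divergence"], weights=w)
        assert mat[0, 1] == pytest.approx(expected, rel=1e-12)
        assert np.allclose(mat, mat.T) and np.allclose(np.diag(mat), 0)

    def test_requires_three_genomes(self):
        gs = [make_genome(n, {"c": "ACGT"}) for n in "ab"]
        wt = partition_windows({"c": 4}, 4)
        with pytest.raises(ValueError):
            distance_matrix(gs, wt)


def _patristic_from_newick(nwk: str):
    import dendropy

    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


class TestNeighborJoining:
    def test_three_taxa_solves_three_point_exactly(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        nwk = neighbor_joining(d, ["a", "b", "c"])
        dist = _patristic_from_newick(nwk)
        assert dist("a", "b") == pytest.approx(0.3, abs=1e-12)
        assert dist("a", "c") == pytest.approx(0.5, abs=1e-12)
        assert dist("b", "c") == pytest.approx(0.6, abs=1e-12)

    def test_five_taxon_additive_matrix_recovered(self):
        # additive distances from a known tree:
        # ((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.1,e:0.4) at a central node
        import dendropy

        src = "((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.1,e:0.4);"
        taxa = ["a", "b", "c", "d", "e"]
        dist_src = _patristic_from_newick(src)
        d = np.zeros((5, 5))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i != j:
                    d[i, j] = dist_src(x, y)
        nwk = neighbor_joining(d, taxa)
        dist = _patristic_from_newick(nwk)
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i < j:
                    assert dist(x, y) == pytest.approx(d[i, j], abs=1e-9)
        # topology agrees with an independent NJ implementation
        import io
        import skbio

        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
        t_ours = dendropy.Tree.get(data=nwk, schema="newick",
                                   taxon_namespace=dendropy.TaxonNamespace(taxa))
        t_sk = dendropy.Tree.get(data=str(sk_tree.root_at_midpoint()).strip(),
                                 schema="newick",
                                 taxon_namespace=t_ours.taxon_namespace)
        t_ours.encode_bipartitions()
        t_sk.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t_ours, t_sk) == 0

    def test_random_additive_matrices_roundtrip(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            # random caterpillar tree over 5 taxa with random branch lengths
            bl = rng.uniform(0.05, 1.0, size=7)
            src = (f"((a:{bl[0]},b:{bl[1]}):{bl[2]},c:{bl[3]},"
                   f"(d:{bl[4]},e:{bl[5]}):{bl[6]});")
            taxa = ["a", "b", "c", "d", "e"]
            dist_src = _patristic_from_newick(src)
            d = np.zeros((5, 5))
            for i, x in enumerate(taxa):
                for j, y in enumerate(taxa):
                    if i != j:
                        d[i, j] = dist_src(x, y)
            dist = _patristic_from_newick(neighbor_joining(d, taxa))
            for i, x in enumerate(taxa):
                for j, y in enumerate(taxa):
                    if i < j:
                        assert dist(x, y) == pytest.approx(d[i, j], abs=1e-9)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.array([[0, 1], [1, 0]]), ["a", "b"])
        bad = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(bad, ["a", "b", "c"])
        nonzero_diag = np.array([[0.1, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(nonzero_diag, ["a", "b", "c"])


class TestDamageAndMissingnessInvariants:
    def test_tv_divergence_invariant_to_damage(self):
        from wisentmix.sim import SimConfig, simulate

        recs = []
        for delta in (0.0, 0.1):
            config = SimConfig(
                chrom_lengths={"c": 300_000}, tau=1.0, mu=0.05, window_size=5_000,
                seed=5, delta=delta, miss=0.2, historical=("P2", "P3"),
            )
            genomes, _ = simulate(config)
            wt = partition_windows(config.chrom_lengths, config.window_size)
            recs.append(window_divergence(genomes["P2"], genomes["P3"], wt, mode="tv"))
        assert np.array_equal(recs[0]["n_tv_diff"], recs[1]["n_tv_diff"])
        assert np.array_equal(recs[0]["n_comparable"], recs[1]["n_comparable"])
        # transitions-included counts do move under damage
        assert not np.array_equal(recs[0]["n_all_diff"], recs[1]["n_all_diff"])

    def test_window_exclusion_monotone_in_missingness(self):
        from wisentmix.sim import SimConfig, simulate

        excluded = []
        for miss in (0.3, 0.6):
            config = SimConfig(
                chrom_lengths={"c": 200_000}, tau=1.0, mu=0.02, window_size=5_000,
                seed=9, delta=0.0, miss=miss,
            )
            genomes, _ = simulate(config)
            wt = partition_windows(config.chrom_lengths, config.window_size)
            rec = window_divergence(genomes["P1"], genomes["P2"], wt)
            excluded.append(int(rec["excluded"].sum()))
        assert excluded[1] >= excluded[0]
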