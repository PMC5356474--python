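import numpy as np
import pytest

from wisentmix.genomes import N, decode_sequence
from wisentmix.sim import (
    CLASS_NAMES,
    CONCORDANT,
    AdmixtureEvent,
    SimConfig,
    apply_damage_and_missingness,
    mutate_sequences,
    sample_block_genealogies,
    simulate,
    simulate_tracts,
)
from wisentmix.pseudohap import classify_site_pair
from wisentmix.windows import partition_windows


class TestBlockGenealogies:
    def test_large_tau_gives_all_concordant(self):
        rng = np.random.default_rng(0)
        classes = sample_block_genealogies(50.0, 2_000, rng)
        assert (classes == CONCORDANT).all()

    @pytest.mark.parametrize("tau", [0.0, 1.0])
    def test_class_frequencies_match_closed_form(self, tau):
        rng = np.random.default_rng(1)
        n = 10_000
        classes = sample_block_genealogies(tau, n, rng)
        p_disc = np.exp(-tau) / 3.0
        p_conc = 1.0 - 2.0 * p_disc
        se = np.sqrt(p_conc * (1 - p_conc) / n)
        assert abs((classes == CONCORDANT).mean() - p_conc) < 3 * se
        se_d = np.sqrt(p_disc * (1 - p_disc) / n)
        for code in (1, 2):
            assert abs((classes == code).mean() - p_disc) < 3 * se_d

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            sample_block_genealogies(-0.1, 10, np.random.default_rng(0))


class TestTracts:
    def test_zero_proportion_gives_no_tracts(self):
        assert simulate_tracts(20.0, 0.0, 1e-8, {"c": 10_000_000}, 0) == []

    def test_bad_proportion_rejected(self):
        with pytest.raises(ValueError):
            simulate_tracts(20.0, 1.5, 1e-8, {"c": 1_000}, 0)
        with pytest.raises(ValueError):
            simulate_tracts(0.0, 0.5, 1e-8, {"c": 1_000}, 0)

    def test_mean_covered_fraction_matches_target(self):
        # f = 0.15, r = 1e-8, t = 20 generations on a 100 Mb genome
        chroms = {f"c{i}": 25_000_000 for i in range(4)}
        fracs = []
        for seed in range(50):
            tracts = simulate_tracts(20.0, 0.15, 1e-8, chroms, seed)
            covered = sum(e - s for _, s, e in tracts)
            fracs.append(covered / 100_000_000)
        assert abs(np.mean(fracs) - 0.15) < 0.03

    def test_mean_tract_length_near_exponential_mean(self):
        # expected mean 1/(r t) = 5 Mb; use a long chromosome so truncation
        # at the ends is a minor effect
        lengths = []
        seed = 0
        while len(lengths) < 200:
            tracts = simulate_tracts(20.0, 0.15, 1e-8, {"c": 400_000_000}, seed)
            lengths += [e - s for _, s, e in tracts]
            seed += 1
        mean = np.mean(lengths)
        assert abs(mean - 5e6) / 5e6 < 0.20

    def test_tracts_disjoint_and_in_bounds(self):
        tracts = simulate_tracts(20.0, 0.4, 1e-7, {"c": 50_000_000}, 3)
        prev_end = -1
        for _, s, e in sorted(tracts):
            assert 0 <= s < e <= 50_000_000
            assert s > prev_end
            prev_end = e


class TestMutation:
    def _mutate(self, mu=0.05, kappa=2.0, tau=1.0, seed=0, tracts=(), L=200_000):
        config = SimConfig(
            chrom_lengths={"c": L}, tau=tau, mu=mu, kappa=kappa,
            window_size=5_000, seed=seed, delta=0.0, miss=0.0,
        )
        windows = partition_windows(config.chrom_lengths, config.window_size)
        rng = np.random.default_rng(seed)
        classes = sample_block_genealogies(tau, len(windows), rng)
        return mutate_sequences(config, windows, classes, list(tracts), rng), classes

    def test_zero_mu_gives_identical_individuals(self):
        seqs, _ = self._mutate(mu=0.0)
        arrs = [seqs[t]["c"] for t in ("P1", "P2", "P3", "O")]
        for a in arrs[1:]:
            assert np.array_equal(arrs[0], a)

    def test_mu_bound_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_lengths={"c": 100}, mu=0.1)

    def test_ts_tv_ratio_tracks_kappa(self):
        kappa = 2.0
        seqs, _ = self._mutate(mu=0.08, kappa=kappa, L=2_000_000, seed=5)
        a, b = seqs["P1"]["c"], seqs["O"]["c"]
        diff = a != b
        ts = int((diff & ((a & 1) == (b & 1))).sum())
        tv = int((diff & ((a & 1) != (b & 1))).sum())
        assert ts + tv > 1e5
        assert abs(ts / tv - kappa) / kappa < 0.10

    def test_concordant_windows_share_sister_alleles(self):
        seqs, classes = self._mutate(tau=3.0, seed=7, L=500_000)
        windows = partition_windows({"c": 500_000}, 5_000)
        p1, p2, p3 = (seqs[t]["c"] for t in ("P1", "P2", "P3"))
        o = seqs["O"]["c"]
        conc = np.zeros(500_000, dtype=bool)
        for wi in np.flatnonzero(classes == CONCORDANT):
            row = windows.df.iloc[wi]
            conc[row["start"]:row["end"]] = True
        derived = conc & (o != p1) & (p1 == p2)  # shared P1-P2 derived allele
        cross13 = conc & (o != p1) & (p1 == p3) & (p1 != p2)
        cross23 = conc & (o != p2) & (p2 == p3) & (p1 != p2)
        assert derived.sum() > 3 * cross13.sum()
        assert derived.sum() > 3 * cross23.sum()

    def test_tract_alleles_copied_from_donor_lineage(self):
        tracts = [("c", 10_000, 60_000, "P3", "P2")]
        seqs, _ = self._mutate(seed=9, tracts=tracts)
        from wisentmix.sim import DONOR_TIP

        assert np.array_equal(
            seqs["P2"]["c"][10_000:60_000], seqs[DONOR_TIP]["c"][10_000:60_000]
        )


class TestDamageAndMissingness:
    def _genomes(self, seed=0):
        config = SimConfig(
            chrom_lengths={"c": 300_000}, mu=0.02, window_size=5_000,
            seed=seed, delta=0.0, miss=0.0, historical=("P3",),
        )
        genomes, _ = simulate(config)
        return genomes

    def test_noop_when_rates_zero(self):
        genomes = self._genomes()
        before = {n: g.chroms["c"].copy() for n, g in genomes.items()}
        apply_damage_and_missingness(genomes, 0.0, 0.0, seed=1)
        for n, g in genomes.items():
            assert np.array_equal(before[n], g.chroms["c"])

    def test_damage_creates_only_transitions(self):
        genomes = self._genomes()
        before = {n: g.chroms["c"].copy() for n, g in genomes.items()}
        apply_damage_and_missingness(genomes, 0.3, 0.0, seed=1)
        for n, g in genomes.items():
            after = g.chroms["c"]
            changed = np.flatnonzero(before[n] != after)
            if not g.historical:
                assert changed.size == 0
                continue
            assert changed.size > 0
            for i in changed[:200]:
                assert classify_site_pair(int(before[n][i]), int(after[i])) == "transition"

    def test_missingness_fraction_binomial(self):
        config = SimConfig(
            chrom_lengths={"c": 1_000_000}, mu=0.0, window_size=10_000,
            seed=3, delta=0.0, miss=0.3,
        )
        genomes, _ = simulate(config)
        frac = (genomes["P1"].chroms["c"] == N).mean()
        assert 0.297 < frac < 0.303

    def test_missing_pattern_independent_of_delta(self):
        g0 = self._genomes()
        g1 = self._genomes()
        apply_damage_and_missingness(g0, 0.0, 0.25, seed=11)
        apply_damage_and_missingness(g1, 0.1, 0.25, seed=11)
        for n in g0:
            assert np.array_equal(g0[n].chroms["c"] == N, g1[n].chroms["c"] == N)

    def test_rate_bounds_checked(self):
        genomes = self._genomes()
        with pytest.raises(ValueError):
            apply_damage_and_missingness(genomes, 1.5, 0.0, seed=0)


class TestSimulateEndToEnd:
    def test_reproducible_and_truth_consistent(self):
        config = SimConfig(
            chrom_lengths={"a": 200_000, "b": 100_000}, tau=0.8, mu=0.03,
            window_size=5_000, seed=77, delta=0.05, miss=0.1,
            historical=("P2",),
            admixture_events=(AdmixtureEvent("P3", "P2", 25.0, 0.2),),
            r=1e-6,
        )
        g1, t1 = simulate(config)
        g2, t2 = simulate(config)
        for n in g1:
            for c in g1[n].chroms:
                assert np.array_equal(g1[n].chroms[c], g2[n].chroms[c])
        assert np.array_equal(t1.block_class, t2.block_class)
        assert t1.tracts == t2.tracts
        covered = sum(e - s for _, s, e, _, _ in t1.tracts)
        assert t1.admixed_fraction["P2"] == pytest.approx(covered / 300_000)
        assert set(np.unique(t1.block_class)) <= {0, 1, 2}
        assert len(CLASS_NAMES) == 3

    def test_donor_not_in_output_and_roles_validated(self):
        config = SimConfig(chrom_lengths={"c": 50_000}, window_size=5_000, seed=0)
        genomes, _ = simulate(config)
        assert set(genomes) == {"P1", "P2", "P3", "O"}
        with pytest.raises(ValueError):
            SimConfig(chrom_lengths={"c": 100}, populations=("P1", "P2", "O"))
        with pytest.raises(ValueError):
            SimConfig(
                chrom_lengths={"c": 100},
                admixture_events=(AdmixtureEvent("P1", "P2", 10.0, 0.1),),
            )
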