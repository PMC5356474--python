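"""Canned simulation experiments that validate the analysis stack.

Each function simulates data under a known history and pushes it through the
full analysis path (pattern counting, jackknife, block trees, admixture map),
so recovery can be scored against the generator's truth.  They are used both
by the test suite and by the reproduction script.

Problem sizes are desk-scale by design: genome sizes, window sizes and (for
the tract-dating experiment) the recombination rate are scaled so that the
expected information content per window and the expected tract counts match
what genome-scale data would provide, while a full experiment stays in the
minutes range on one core.  The methods note discusses each scaling choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .admixmap import (
    EcdfComparison,
    RunLengthSet,
    build_admixture_map,
    ecdf_compare,
    run_lengths,
    topology_fractions,
)
from .blocktree import best_topologies
from .dstat import d_test, f_hat, polarize_and_count
from .sim import AdmixtureEvent, SimConfig, simulate
from .windows import partition_windows

#: 500 windows of 5 kb: a miniature stand-in for 500 x 1 Mb blocks, with the
#: per-lineage substitution probability raised so each window carries a
#: realistic number of informative sites.
NULL_CALIBRATION_KW = dict(
    chrom_lengths={f"chr{i}": 500_000 for i in range(1, 6)},
    tau=1.0,
    mu=0.05,
    window_size=5_000,
    delta=0.05,
    miss=0.2,
    historical=("P3",),
)

#: f-hat recovery: tract physics at the stated scale (t_admix = 20
#: generations, r = 1e-8/bp/gen -> 5 Mb expected tract length) needs real
#: megabase coordinates, so this one runs on a 240 Mb genome.
FHAT_RECOVERY_KW = dict(
    chrom_lengths={f"chr{i}": 20_000_000 for i in range(1, 13)},
    populations=("P1", "P2", "P3a", "P3b", "O"),
    tau=1.0,
    mu=0.005,
    window_size=1_000_000,
    delta=0.0,
    miss=0.0,
    r=1e-8,
)

#: tract-length dating: a 160 Mb mini-genome with recombination scaled up
#: five-fold and 200 kb windows, preserving expected tract lengths (in window
#: units) and counts of a cattle-sized genome; low ILS (tau = 4) isolates the
#: tract-length signal being dated.
DATING_KW = dict(
    chrom_lengths={f"chr{i}": 20_000_000 for i in range(1, 9)},
    tau=4.0,
    mu=0.005,
    window_size=200_000,
    r=5e-8,
    delta=0.0,
    miss=0.0,
)

#: discordant-topology symmetry: 1,000 windows, moderate ILS.
SYMMETRY_KW = dict(
    chrom_lengths={f"chr{i}": 1_000_000 for i in range(1, 6)},
    tau=2.0,
    mu=0.05,
    window_size=5_000,
    delta=0.05,
    miss=0.2,
    historical=("P3",),
)

DAMAGE_KW = dict(
    chrom_lengths={f"chr{i}": 500_000 for i in range(1, 5)},
    tau=1.0,
    mu=0.05,
    window_size=5_000,
    miss=0.2,
    historical=("P2", "P3"),
)


def null_d_z_scores(n_replicates: int = 100, seed0: int = 1) -> np.ndarray:
    """Z scores of the D test under the null (no admixture, tau = 1).

    One D test per replicate over 500 windows; with a calibrated jackknife,
    |Z| > 3 should occur in at most ~2% of replicates.
    """
    zs = []
    for i in range(n_replicates):
        config = SimConfig(seed=seed0 + i, **NULL_CALIBRATION_KW)
        genomes, _ = simulate(config)
        windows = partition_windows(config.chrom_lengths, config.window_size)
        res = d_test(genomes["P1"], genomes["P2"], genomes["P3"], genomes["O"], windows)
        zs.append(res.z)
    return np.array(zs)


def fhat_recovery(
    proportion: float, n_replicates: int = 20, seed0: int = 1, t_admix: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """f-hat estimates and realized tract fractions for a pulse of given size.

    Returns ``(estimates, realized_fractions)``, one entry per replicate.
    """
    est, real = [], []
    for i in range(n_replicates):
        config = SimConfig(
            seed=seed0 + i,
            admixture_events=(AdmixtureEvent("P3a", "P2", t_admix, proportion),),
            **FHAT_RECOVERY_KW,
        )
        genomes, truth = simulate(config)
        windows = partition_windows(config.chrom_lengths, config.window_size)
        res = f_hat(
            genomes["P1"], genomes["P2"], genomes["P3a"], genomes["P3b"],
            genomes["O"], windows,
        )
        est.append(res.fhat)
        real.append(truth.admixed_fraction.get("P2", 0.0))
    return np.array(est), np.array(real)


def admixture_run_set(
    t_admix: float, seed: int, proportion: float = 0.15
) -> tuple[RunLengthSet, dict]:
    """Bridged admix-category run lengths for one simulated pulse."""
    config = SimConfig(
        seed=seed,
        admixture_events=(AdmixtureEvent("P3", "P2", t_admix, proportion),),
        **DATING_KW,
    )
    genomes, truth = simulate(config)
    windows = partition_windows(config.chrom_lengths, config.window_size)
    order = [genomes[n] for n in ("P2", "P1", "P3", "O")]
    results = best_topologies(order, windows, outgroup="O", tol=1e-3, max_rounds=20)
    amap = build_admixture_map(
        results, windows, [g.name for g in order], "P2", "P1", "P3"
    )
    fractions = topology_fractions(amap)
    return run_lengths(amap, "admix", bridge_missing=True), fractions


def dating_comparison(seed_pair: int) -> EcdfComparison:
    """Compare run-length ECDFs of an old (150 gen) vs recent (20 gen) pulse.

    The older event must show more small blocks: its ECDF lies above, and the
    two-sample KS test separates the distributions.
    """
    old_runs, _ = admixture_run_set(150.0, seed=seed_pair)
    young_runs, _ = admixture_run_set(20.0, seed=100_000 + seed_pair)
    return ecdf_compare(old_runs, young_runs)


def discordant_topology_counts(seed: int = 1) -> tuple[int, int]:
    """Counts of the two discordant topology calls in a no-admixture run.

    Under incomplete lineage sorting alone the two discordant rooted
    topologies are equally frequent — the premise of the ILS-correction
    subtraction.
    """
    config = SimConfig(seed=seed, **SYMMETRY_KW)
    genomes, _ = simulate(config)
    windows = partition_windows(config.chrom_lengths, config.window_size)
    order = [genomes[n] for n in ("P2", "P1", "P3", "O")]
    results = best_topologies(order, windows, outgroup="O", tol=1e-3, max_rounds=20)
    amap = build_admixture_map(
        results, windows, [g.name for g in order], "P2", "P1", "P3"
    )
    n_admix = int((amap["category"] == "admix").sum())
    n_ils = int((amap["category"] == "ils_alt").sum())
    return n_admix, n_ils


@dataclass
class DamageContrast:
    counts_clean: tuple[int, int]  # tv-mode (ABBA, BABA) with delta = 0
    counts_damaged: tuple[int, int]  # tv-mode (ABBA, BABA) with delta = 0.1
    d_all_clean: float
    d_all_damaged: float

    @property
    def tv_counts_identical(self) -> bool:
        return self.counts_clean == self.counts_damaged

    @property
    def all_mode_changed(self) -> bool:
        return self.d_all_clean != self.d_all_damaged


def damage_contrast(seed: int = 1) -> DamageContrast:
    """Same simulation at delta = 0 vs 0.1: transversion-mode pattern counts
    must match bitwise, while the transitions-included D shifts — the reason
    damage-prone data are analysed on transversions only."""
    out = []
    for delta in (0.0, 0.1):
        config = SimConfig(seed=seed, delta=delta, **DAMAGE_KW)
        genomes, _ = simulate(config)
        windows = partition_windows(config.chrom_lengths, config.window_size)
        g = [genomes[n] for n in ("P1", "P2", "P3", "O")]
        pc_tv = polarize_and_count(*g, windows, mode="tv")
        res_all = d_test(*g, windows, mode="all")
        out.append(((int(pc_tv.n_abba.sum()), int(pc_tv.n_baba.sum())), res_all.d))
    return DamageContrast(
        counts_clean=out[0][0],
        counts_damaged=out[1][0],
        d_all_clean=out[0][1],
        d_all_damaged=out[1][1],
    )
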