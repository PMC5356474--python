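"""ABBA/BABA D statistics, weighted block jackknife, and f-hat estimation.

Site patterns are polarized against the outgroup O: at sites where the
candidate introgressor P3 carries the derived allele B and exactly one of the
two sister individuals P1/P2 carries it, the pattern is ABBA (P2 shares with
P3) or BABA (P1 shares with P3).  Under incomplete lineage sorting alone the
two patterns are equally frequent and

    D = (n_ABBA - n_BABA) / (n_ABBA + n_BABA)

has expectation zero; a significant excess of either pattern indicates
admixture.  In the default transversion-only mode sites are recoded to their
purine/pyrimidine class before pattern matching, so post-mortem deamination
damage (C->T, G->A: within-class changes) cannot alter a single count.

Significance uses a weighted block jackknife over genomic windows (blocks
weighted by their informative-site content, the delete-m(j) jackknife of
Busing et al. 1999), which is robust to linkage within blocks.  The f-hat
ratio estimator of the admixed genome fraction substitutes a second,
unadmixed introgressor individual into the P2 slot of the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomes import N, PseudoHaploidGenome, shared_frame
from .windows import WindowTable

Z_SIGNIFICANT = 3.0


@dataclass
class PatternCounts:
    """Per-window ABBA/BABA tallies for one taxon-role assignment."""

    roles: tuple[str, str, str, str]  # P1, P2, P3, O labels
    mode: str
    n_abba: np.ndarray  # per window
    n_baba: np.ndarray

    @property
    def n_informative(self) -> np.ndarray:
        return self.n_abba + self.n_baba


@dataclass
class JackknifeResult:
    estimate: float
    se: float
    z: float
    m: int  # number of blocks used

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.z) and abs(self.z) > Z_SIGNIFICANT)


@dataclass
class DStatResult:
    roles: tuple[str, str, str, str]
    mode: str
    n_abba: int
    n_baba: int
    d: float
    se: float
    z: float
    m: int

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.z) and abs(self.z) > Z_SIGNIFICANT)


@dataclass
class FHatResult:
    roles: tuple[str, str, str, str, str]  # P1, P2, P3a, P3b, O
    mode: str
    s_num: int
    s_den: int
    fhat: float
    se: float
    z: float
    m: int

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.z) and abs(self.z) > Z_SIGNIFICANT)


def _select_windows(windows: WindowTable, chroms) -> np.ndarray:
    if chroms is None:
        return np.ones(len(windows), dtype=bool)
    return windows.df["chrom"].isin(list(chroms)).to_numpy()


def polarize_and_count(
    p1: PseudoHaploidGenome,
    p2: PseudoHaploidGenome,
    p3: PseudoHaploidGenome,
    o: PseudoHaploidGenome,
    windows: WindowTable,
    mode: str = "tv",
) -> PatternCounts:
    """Count ABBA and BABA site patterns per window.

    ``tv`` mode recodes bases to purine/pyrimidine classes first and requires
    the derived/ancestral pair to straddle the two classes, which scores
    transversion configurations only and is exactly invariant to deamination
    damage.  ``all`` mode matches raw base patterns and requires strict
    biallelicity (P1 and P2 each equal to either the O or the P3 allele).
    """
    if mode not in ("tv", "all", "ts+tv"):
        raise ValueError(f"unknown mode {mode!r}")
    mode = "all" if mode == "ts+tv" else mode
    frame = shared_frame([p1, p2, p3, o])
    nw = len(windows)
    n_abba = np.zeros(nw, dtype=np.int64)
    n_baba = np.zeros(nw, dtype=np.int64)
    for chrom, L in frame.items():
        a1, a2, a3, ao = (g.chroms[chrom] for g in (p1, p2, p3, o))
        valid = (a1 != N) & (a2 != N) & (a3 != N) & (ao != N)
        if mode == "tv":
            r1, r2, r3, ro = a1 & 1, a2 & 1, a3 & 1, ao & 1
            informative = valid & (r3 != ro) & (r1 != r2)
            abba = informative & (r2 == r3)
            baba = informative & (r1 == r3)
        else:
            derived = valid & (a3 != ao)
            abba = derived & (a1 == ao) & (a2 == a3)
            baba = derived & (a2 == ao) & (a1 == a3)
        windows.count_by_window(chrom, abba, n_abba)
        windows.count_by_window(chrom, baba, n_baba)
    return PatternCounts(
        roles=(p1.name, p2.name, p3.name, o.name), mode=mode, n_abba=n_abba, n_baba=n_baba
    )


def d_statistic(n_abba: int, n_baba: int) -> float:
    """D = (ABBA - BABA) / (ABBA + BABA); NaN when no informative sites."""
    tot = n_abba + n_baba
    if tot == 0:
        return float("nan")
    return (n_abba - n_baba) / tot


def weighted_block_jackknife(
    block_counts: np.ndarray,
    stat_fn,
    weights: np.ndarray | None = None,
    weighted: bool = True,
) -> JackknifeResult:
    """Leave-one-block-out jackknife of a statistic of summed counts.

    ``block_counts`` has one row per genomic block; ``stat_fn`` maps a totals
    vector (or an array of them) to the statistic.  Blocks with zero weight
    (no informative sites) are dropped from M.  With ``weighted`` the
    delete-m(j) variance of Busing et al. (1999) is used, weighting each
    block by its informative-site count; otherwise all retained blocks get
    equal weight, which reduces to the classic delete-one jackknife.
    """
    counts = np.asarray(block_counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    if weights is None:
        weights = counts.sum(axis=1)
    weights = np.asarray(weights, dtype=float)
    keep = weights > 0
    counts, weights = counts[keep], weights[keep]
    m = counts.shape[0]
    total = counts.sum(axis=0)
    theta = float(stat_fn(total))
    if m < 2:
        return JackknifeResult(estimate=theta, se=float("nan"), z=float("nan"), m=m)
    if not weighted:
        weights = np.ones(m)
    loo = np.asarray(stat_fn(total[None, :] - counts), dtype=float)
    n = weights.sum()
    h = n / weights
    theta_j = m * theta - ((1.0 - weights / n) * loo).sum()
    terms = (h * theta - (h - 1.0) * loo - theta_j) ** 2 / (h - 1.0)
    var = terms.mean()
    se = float(np.sqrt(var))
    if se > 0:
        z = theta / se
    else:
        # degenerate: identical leave-one-out values; a zero statistic is
        # exactly zero standard errors from zero
        z = 0.0 if theta == 0 else float("nan")
    return JackknifeResult(estimate=theta, se=se, z=float(z), m=m)


def _d_from_counts(totals: np.ndarray) -> np.ndarray:
    totals = np.asarray(totals, dtype=float)
    a, b = totals[..., 0], totals[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a - b) / (a + b)


def d_test(
    p1: PseudoHaploidGenome,
    p2: PseudoHaploidGenome,
    p3: PseudoHaploidGenome,
    o: PseudoHaploidGenome,
    windows: WindowTable,
    mode: str = "tv",
    chroms=None,
    weighted: bool = True,
) -> DStatResult:
    """Full D-statistic test with block-jackknife standard error and Z."""
    pc = polarize_and_count(p1, p2, p3, o, windows, mode=mode)
    sel = _select_windows(windows, chroms)
    blocks = np.stack([pc.n_abba[sel], pc.n_baba[sel]], axis=1)
    jk = weighted_block_jackknife(blocks, _d_from_counts, weighted=weighted)
    return DStatResult(
        roles=pc.roles,
        mode=pc.mode,
        n_abba=int(pc.n_abba[sel].sum()),
        n_baba=int(pc.n_baba[sel].sum()),
        d=jk.estimate,
        se=jk.se,
        z=jk.z,
        m=jk.m,
    )


def _fhat_from_counts(totals: np.ndarray) -> np.ndarray:
    totals = np.asarray(totals, dtype=float)
    num = totals[..., 0] - totals[..., 1]
    den = totals[..., 2] - totals[..., 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def f_hat(
    p1: PseudoHaploidGenome,
    p2: PseudoHaploidGenome,
    p3a: PseudoHaploidGenome,
    p3b: PseudoHaploidGenome,
    o: PseudoHaploidGenome,
    windows: WindowTable,
    mode: str = "tv",
    chroms=None,
    weighted: bool = True,
) -> FHatResult:
    """Admixed-genome-fraction estimate from a dual-introgressor design.

    f-hat = S_num / S_den with S_num = sum(ABBA - BABA) for (P1, P2, P3a, O)
    and S_den = sum(ABBA - BABA) for (P1, P3b, P3a, O) — the second
    introgressor individual substituted into the P2 slot, which measures the
    pattern imbalance expected under complete admixture.
    """
    pc_num = polarize_and_count(p1, p2, p3a, o, windows, mode=mode)
    pc_den = polarize_and_count(p1, p3b, p3a, o, windows, mode=mode)
    sel = _select_windows(windows, chroms)
    blocks = np.stack(
        [pc_num.n_abba[sel], pc_num.n_baba[sel], pc_den.n_abba[sel], pc_den.n_baba[sel]],
        axis=1,
    )
    s_num = int(pc_num.n_abba[sel].sum() - pc_num.n_baba[sel].sum())
    s_den = int(pc_den.n_abba[sel].sum() - pc_den.n_baba[sel].sum())
    jk = weighted_block_jackknife(blocks, _fhat_from_counts, weighted=weighted)
    return FHatResult(
        roles=(p1.name, p2.name, p3a.name, p3b.name, o.name),
        mode=pc_num.mode,
        s_num=s_num,
        s_den=s_den,
        fhat=jk.estimate if s_den != 0 else float("nan"),
        se=jk.se,
        z=jk.z,
        m=jk.m,
    )
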