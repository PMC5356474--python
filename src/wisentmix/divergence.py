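"""Windowed pairwise divergence, kernel densities, distances and NJ trees.

Divergence is the proportion of differing sites among *comparable* sites
(both genomes non-N) in each non-overlapping window, in one of two modes:
``tv`` counts transversion differences only (robust to deamination damage),
``all`` counts transitions plus transversions.  Windows with more than 75%
missing data are flagged excluded and take no part in densities or pooled
distances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomes import N, PseudoHaploidGenome, shared_frame
from .windows import WindowTable

MODES = ("tv", "all")


def _norm_mode(mode: str) -> str:
    mode = {"ts+tv": "all"}.get(mode, mode)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES} (or 'ts+tv'), got {mode!r}")
    return mode


def window_divergence(
    ga: PseudoHaploidGenome,
    gb: PseudoHaploidGenome,
    windows: WindowTable,
    mode: str = "tv",
    max_missing: float = 0.75,
) -> pd.DataFrame:
    """Per-window divergence between two genomes sharing a coordinate frame.

    Returns a DataFrame with one row per window: comparable-site and
    difference counts in both modes, the missing fraction, the divergence in
    the requested mode, and ``excluded`` / ``degenerate`` flags.  Symmetric
    in its two genome arguments.
    """
    mode = _norm_mode(mode)
    frame = shared_frame([ga, gb])
    nw = len(windows)
    n_comp = np.zeros(nw, dtype=np.int64)
    n_tv = np.zeros(nw, dtype=np.int64)
    n_all = np.zeros(nw, dtype=np.int64)
    for chrom, L in frame.items():
        a, b = ga.chroms[chrom], gb.chroms[chrom]
        comparable = (a != N) & (b != N)
        diff = comparable & (a != b)
        tvdiff = comparable & ((a & 1) != (b & 1))
        windows.count_by_window(chrom, comparable, n_comp)
        windows.count_by_window(chrom, diff, n_all)
        windows.count_by_window(chrom, tvdiff, n_tv)

    out = windows.df.copy()
    wlen = windows.lengths_bp()
    out["n_comparable"] = n_comp
    out["n_tv_diff"] = n_tv
    out["n_all_diff"] = n_all
    out["missing_fraction"] = 1.0 - n_comp / wlen
    out["excluded"] = out["missing_fraction"] > max_missing
    ndiff = n_tv if mode == "tv" else n_all
    with np.errstate(divide="ignore", invalid="ignore"):
        out["divergence"] = np.where(n_comp > 0, ndiff / np.maximum(n_comp, 1), np.nan)
    out["degenerate"] = (~out["excluded"]) & (n_comp == 0)
    out.insert(0, "pair", f"{ga.name}|{gb.name}")
    return out


def kde_density(
    values, n_grid: int = 512, cut: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density with the rule-of-thumb bandwidth
    ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``.

    Returns a grid spanning the data plus ``cut`` bandwidths on each side and
    the density evaluated on it; the trapezoid integral over the grid is 1 to
    within ~1e-3.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError(f"kde_density requires >= 2 finite values, got {n}")
    sd = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = abs(x[0]) if x[0] != 0 else 1.0
        spread *= 1e-3
    bw = 0.9 * spread * n ** (-0.2)
    grid = np.linspace(x.min() - cut * bw, x.max() + cut * bw, n_grid)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (n * bw * np.sqrt(2 * np.pi))
    return grid, dens


def distance_matrix(
    genomes: list[PseudoHaploidGenome],
    windows: WindowTable,
    mode: str = "tv",
    max_missing: float = 0.75,
) -> tuple[list[str], np.ndarray]:
    """Whole-genome pairwise distances pooled over non-excluded windows.

    The pooled distance is ``sum(differences) / sum(comparable sites)`` over
    windows passing the missing-data filter, i.e. the comparable-site-weighted
    mean of per-window divergences.
    """
    if len(genomes) < 3:
        raise ValueError("distance_matrix requires >= 3 genomes")
    mode = _norm_mode(mode)
    k = len(genomes)
    labels = [g.name for g in genomes]
    mat = np.zeros((k, k))
    col = "n_tv_diff" if mode == "tv" else "n_all_diff"
    for i in range(k):
        for j in range(i + 1, k):
            rec = window_divergence(genomes[i], genomes[j], windows, mode, max_missing)
            keep = ~rec["excluded"]
            comp = int(rec.loc[keep, "n_comparable"].sum())
            if comp == 0:
                raise ValueError(
                    f"pair {labels[i]}|{labels[j]}: no comparable sites in any retained window"
                )
            mat[i, j] = mat[j, i] = rec.loc[keep, col].sum() / comp
    return labels, mat


def neighbor_joining(matrix: np.ndarray, labels: list[str]) -> str:
    """Neighbor joining (Q criterion, Studier–Keppler branch lengths).

    Ties in Q are broken by the lowest (row, column) pair index.  Additive
    matrices are recovered exactly; negative branch-length estimates are kept
    as computed so additivity is preserved.  Returns a Newick string with a
    trifurcating (unrooted) root.
    """
    d = np.array(matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")

    nodes = [str(l) for l in labels]
    while len(nodes) > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        best = int(np.argmin(flat))  # argmin returns the first = lowest pair index
        i, j = int(iu[0][best]), int(iu[1][best])
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        node = f"({nodes[i]}:{li:.12g},{nodes[j]}:{lj:.12g})"
        keep = [k_ for k_ in range(m) if k_ not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k_] for k_ in keep] + [node]

    # final three nodes: solve the three-point equations exactly
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    return f"({nodes[0]}:{la:.12g},{nodes[1]}:{lb:.12g},{nodes[2]}:{lc:.12g});"
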