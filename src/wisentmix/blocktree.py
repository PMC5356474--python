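"""Per-window ML phylogenies on purine/pyrimidine-recoded alignments.

Each genomic window is recoded to binary characters (purines R -> 0,
pyrimidines Y -> 1, N -> ?), which scores transversions only: transition
differences become invisible by construction, so deamination damage cannot
move a window between topologies.  If any taxon exceeds the gap threshold
(default 50% missing) the window is recorded as having insufficient data.

Likelihoods use the symmetric two-state (CFN) substitution model with
stationary frequencies (1/2, 1/2) and change probability
``(1 - exp(-2t)) / 2`` along a branch of length ``t`` (substitutions/site),
evaluated by Felsenstein pruning with missing states marginalized.  Because
only 4 or 5 taxa are analysed, all unrooted topologies (3 or 15) are
enumerated and each one's branch lengths optimized by bounded coordinate-wise
search — no heuristic tree search is needed.  Ties in the optimized
log-likelihood are flagged, never silently broken.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genomes import N, PseudoHaploidGenome, shared_frame
from .windows import WindowTable

MISSING_STATE = 2
TIE_TOL = 1e-9

#: leaf conditional likelihoods for states 0, 1, ? (missing)
_LEAF_LUT = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


@dataclass
class BinaryAlignment:
    """Binary-recoded alignment of one window."""

    window: int
    taxa: list[str]
    matrix: np.ndarray  # (k, L) uint8 over {0 purine, 1 pyrimidine, 2 missing}
    gap_fraction: np.ndarray  # per taxon
    status: str  # "scored" | "insufficient_data"


@dataclass
class TopologyResult:
    """Outcome of exhaustive topology scoring for one window."""

    window: int
    status: str  # "scored" | "insufficient_data"
    log_likelihoods: np.ndarray | None  # per candidate topology
    best_index: int | None
    rooted_tree: tuple | None  # nested tuple of taxon indices, (ingroup, outgroup)
    rooted_newick: str | None
    tie: bool
    delta_lnl: float | None  # best minus runner-up
    converged: bool = True


def binarize_sequences(arr: np.ndarray) -> np.ndarray:
    """Map base codes to binary states: A,G -> 0; C,T -> 1; N -> 2."""
    return np.where(arr == N, MISSING_STATE, arr & 1).astype(np.uint8)


def binarize_block(
    genomes: list[PseudoHaploidGenome],
    windows: WindowTable,
    window: int,
    gap_threshold: float = 0.5,
) -> BinaryAlignment:
    """Binary-recode one window; flag it insufficient when any taxon has a
    missing fraction above ``gap_threshold``."""
    shared_frame(genomes)
    row = windows.df.iloc[window]
    chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
    mat = np.stack([binarize_sequences(g.chroms[chrom][start:end]) for g in genomes])
    gaps = (mat == MISSING_STATE).mean(axis=1)
    status = "insufficient_data" if (gaps > gap_threshold).any() else "scored"
    return BinaryAlignment(
        window=window,
        taxa=[g.name for g in genomes],
        matrix=mat,
        gap_fraction=gaps,
        status=status,
    )


def write_phylip(alignment: BinaryAlignment, path) -> None:
    """Write one window's binary alignment as relaxed PHYLIP (0/1/? states),
    for cross-checking against external ML programs."""
    symbols = np.array(["0", "1", "?"])
    with open(path, "w") as fh:
        k, length = alignment.matrix.shape
        fh.write(f"{k} {length}\n")
        for name, row in zip(alignment.taxa, alignment.matrix):
            fh.write(f"{name} {''.join(symbols[row])}\n")


def enumerate_topologies(k: int) -> list[tuple]:
    """All unrooted binary topologies over taxa 0..k-1, represented as a
    trifurcating root whose children are leaves or cherries.

    3 topologies for 4 taxa, 15 for 5.
    """
    if k == 4:
        return [
            ((0, 1), 2, 3),
            ((0, 2), 1, 3),
            ((0, 3), 1, 2),
        ]
    if k == 5:
        tops = []
        taxa = set(range(5))
        for c1 in combinations(range(5), 2):
            rest = sorted(taxa - set(c1))
            for c2 in combinations(rest, 2):
                if c1 > c2:
                    continue  # unordered pair of cherries
                mid = (taxa - set(c1) - set(c2)).pop()
                tops.append((tuple(c1), mid, tuple(c2)))
        assert len(tops) == 15
        return tops
    raise ValueError(f"taxon count must be 4 or 5, got {k}")


def n_branches(topology: tuple) -> int:
    def count(node) -> int:
        if isinstance(node, int):
            return 1
        return 1 + sum(count(c) for c in node)

    return sum(count(c) for c in topology)


def all_patterns(k: int) -> np.ndarray:
    """All ternary site patterns over k taxa; pattern code = sum(state_i * 3**i)."""
    codes = np.arange(3**k)
    out = np.empty((3**k, k), dtype=np.int64)
    for i in range(k):
        out[:, i] = (codes // 3**i) % 3
    return out


def pattern_counts_by_window(
    genomes: list[PseudoHaploidGenome], windows: WindowTable
) -> tuple[np.ndarray, np.ndarray]:
    """Binary site-pattern counts and per-taxon gap fractions per window.

    Returns ``(counts, gap_fraction)`` with shapes (n_windows, 3**k) and
    (n_windows, k); taxon order follows the input list.
    """
    frame = shared_frame(genomes)
    k = len(genomes)
    if 3**k > 256:
        raise ValueError("pattern coding supports at most 5 taxa")
    nw = len(windows)
    counts = np.zeros((nw, 3**k), dtype=np.int64)
    for chrom, L in frame.items():
        code = np.zeros(L, dtype=np.uint8)  # 3**5 - 1 = 242 fits
        for i, g in enumerate(genomes):
            code += binarize_sequences(g.chroms[chrom]) * np.uint8(3**i)
        first, starts, ends = windows.chrom_bounds(chrom)
        for j, (s, e) in enumerate(zip(starts, ends)):
            counts[first + j] += np.bincount(code[s:e], minlength=3**k)
    # per-taxon gap fractions fall straight out of the pattern counts
    missing = (all_patterns(k) == MISSING_STATE).astype(float)  # (P, k)
    gaps = (counts @ missing) / windows.lengths_bp()[:, None]
    return counts, gaps


def _site_likelihoods_e(
    topology: tuple, evec: np.ndarray, leaf_partials: np.ndarray
) -> np.ndarray:
    """Pruning likelihood of every pattern: returns (W, P).

    Branches are parameterized by ``e = exp(-2t)`` (``evec`` is (W, nb), with
    branch indices assigned in depth-first pre-order over the
    trifurcating-root structure); ``leaf_partials`` is (P, k, 2).  The site
    likelihood is linear in each branch's ``e`` individually, which the
    optimizer exploits.
    """
    w = evec.shape[0]
    p = leaf_partials.shape[0]
    counter = iter(range(evec.shape[1]))

    def edge(child_partial: np.ndarray, b: int) -> np.ndarray:
        e = evec[:, b][:, None, None]
        return 0.5 * ((1.0 + e) * child_partial + (1.0 - e) * child_partial[..., ::-1])

    def rec(node) -> np.ndarray:
        b = next(counter)
        if isinstance(node, int):
            part = np.broadcast_to(leaf_partials[:, node, :], (w, p, 2))
        else:
            part = rec(node[0]) * rec(node[1])
        return edge(part, b)

    root = rec(topology[0]) * rec(topology[1]) * rec(topology[2])
    return 0.5 * root.sum(axis=-1)


def _site_likelihoods(
    topology: tuple, t: np.ndarray, leaf_partials: np.ndarray
) -> np.ndarray:
    """Pruning likelihood of every pattern given branch lengths ``t`` (W, nb)."""
    return _site_likelihoods_e(topology, np.exp(-2.0 * t), leaf_partials)


def _weighted_logsum(counts: np.ndarray, site: np.ndarray) -> np.ndarray:
    ll = np.full_like(site, -np.inf)
    np.log(site, out=ll, where=site > 0)
    with np.errstate(invalid="ignore"):
        vals = counts * ll
    return np.where(counts > 0, vals, 0.0).sum(axis=-1)


def cfn_loglik(
    topology: tuple, t: np.ndarray, counts: np.ndarray, leaf_partials: np.ndarray
) -> np.ndarray:
    """Log-likelihood per window: sum over patterns of count * ln(likelihood)."""
    return _weighted_logsum(counts, _site_likelihoods(topology, t, leaf_partials))


def cfn_likelihood(
    topology: tuple, branch_lengths, alignment: BinaryAlignment | np.ndarray, k: int | None = None
) -> float:
    """Scalar log-likelihood of one window under the CFN model.

    ``alignment`` may be a :class:`BinaryAlignment` or a pattern-count vector
    of length 3**k.
    """
    branch_lengths = np.asarray(branch_lengths, dtype=float)
    if (branch_lengths < 0).any():
        raise ValueError("branch lengths must be >= 0")
    if isinstance(alignment, BinaryAlignment):
        k = alignment.matrix.shape[0]
        code = np.zeros(alignment.matrix.shape[1], dtype=np.int64)
        for i in range(k):
            code += alignment.matrix[i].astype(np.int64) * 3**i
        counts = np.bincount(code, minlength=3**k).astype(float)
    else:
        counts = np.asarray(alignment, dtype=float)
        if k is None:
            k = int(round(np.log(counts.size) / np.log(3)))
    leafp = _LEAF_LUT[all_patterns(k)]
    return float(cfn_loglik(topology, branch_lengths[None, :], counts[None, :], leafp)[0])


def pattern_likelihoods(topology: tuple, branch_lengths, k: int) -> np.ndarray:
    """Likelihood of every complete (non-missing) binary pattern; sums to 1."""
    branch_lengths = np.asarray(branch_lengths, dtype=float)
    pats = all_patterns(k)
    leafp = _LEAF_LUT[pats]
    site = _site_likelihoods(topology, branch_lengths[None, :], leafp)[0]
    complete = (pats != MISSING_STATE).all(axis=1)
    return site[complete]


def optimize_branch_lengths(
    topology: tuple,
    counts: np.ndarray,
    k: int,
    tol: float = 1e-6,
    max_rounds: int = 50,
    upper: float = 10.0,
    init: float = 0.1,
    ternary_iters: int = 30,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximize the CFN log-likelihood over branch lengths, batched over
    windows.

    ``counts`` is (W, 3**k).  Branch lengths are bounded to [0, ``upper``]
    and optimized coordinate-wise (vectorized ternary search per branch, all
    windows at once), cycling until the largest per-window improvement in a
    full round falls below ``tol``.  Returns ``(lnl, lengths, converged)``;
    the returned likelihood never falls below the value at initialization.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    w = counts.shape[0]
    nb = n_branches(topology)
    leafp = _LEAF_LUT[all_patterns(k)]
    e_min = float(np.exp(-2.0 * upper))
    evec = np.full((w, nb), np.exp(-2.0 * init))
    lnl = _weighted_logsum(counts, _site_likelihoods_e(topology, evec, leafp))
    converged = False
    active = np.arange(w)  # windows still improving by >= tol per round
    for _ in range(max_rounds):
        ev = evec[active]
        cn = counts[active]
        ln = lnl[active]
        na = active.size
        prev = ln.copy()
        for b in range(nb):
            # site likelihood is linear in this branch's e = exp(-2t):
            # two full tree evaluations give the coefficients, after which
            # the concave 1-D profile is maximized by cheap ternary search.
            saved = ev[:, b].copy()
            ev[:, b] = 0.0
            alpha = _site_likelihoods_e(topology, ev, leafp)
            ev[:, b] = 1.0
            beta = _site_likelihoods_e(topology, ev, leafp) - alpha
            ev[:, b] = saved

            def f(e: np.ndarray) -> np.ndarray:
                return _weighted_logsum(cn, alpha + beta * e[:, None])

            lo = np.full(na, e_min)
            hi = np.ones(na)
            for _i in range(ternary_iters):
                m1 = lo + (hi - lo) / 3.0
                m2 = hi - (hi - lo) / 3.0
                move_up = f(m1) < f(m2)
                lo = np.where(move_up, m1, lo)
                hi = np.where(move_up, hi, m2)
            cand = 0.5 * (lo + hi)
            cands = np.stack([cand, np.ones(na), np.full(na, e_min)])  # interior + bounds
            fvals = np.stack([f(c) for c in cands])
            pick = fvals.argmax(axis=0)
            f_new = fvals[pick, np.arange(na)]
            e_new = cands[pick, np.arange(na)]
            improve = f_new > ln
            ev[:, b] = np.where(improve, e_new, ev[:, b])
            ln = np.where(improve, f_new, ln)
        evec[active] = ev
        lnl[active] = ln
        still = ln - prev >= tol
        active = active[still]
        if active.size == 0:
            converged = True
            break
    t = -0.5 * np.log(np.clip(evec, e_min, 1.0))
    return lnl, t, converged


def root_on_outgroup(topology: tuple, outgroup: int) -> tuple:
    """Re-root an unrooted (trifurcating) topology on the outgroup leaf.

    Returns a nested tuple ``(ingroup_structure, outgroup)``.
    """
    children = list(topology)
    for i, ch in enumerate(children):
        if ch == outgroup:
            others = children[:i] + children[i + 1 :]
            return ((others[0], others[1]), outgroup)
        if isinstance(ch, tuple) and outgroup in ch:
            sib = ch[0] if ch[1] == outgroup else ch[1]
            others = children[:i] + children[i + 1 :]
            return ((sib, (others[0], others[1])), outgroup)
    raise ValueError(f"outgroup {outgroup} not found in topology {topology}")


def newick(node, labels: list[str]) -> str:
    if isinstance(node, int):
        return labels[node]
    return "(" + ",".join(newick(c, labels) for c in node) + ")"


def rooted_clades(node) -> list[frozenset]:
    """Leaf sets of all internal nodes of a rooted nested-tuple tree."""
    clades: list[frozenset] = []

    def leaves(n) -> frozenset:
        if isinstance(n, int):
            return frozenset([n])
        s = frozenset().union(*(leaves(c) for c in n))
        clades.append(s)
        return s

    leaves(node)
    return clades


def best_topologies(
    genomes: list[PseudoHaploidGenome],
    windows: WindowTable,
    outgroup: str,
    gap_threshold: float = 0.5,
    tol: float = 1e-6,
    max_rounds: int = 50,
) -> list[TopologyResult]:
    """Exhaustive ML topology scoring of every window.

    For each window with sufficient data, all candidate unrooted topologies
    are optimized and the maximum-likelihood one is reported, rooted on the
    outgroup.  Windows whose best and runner-up log-likelihoods differ by
    less than 1e-9 are tie-flagged (classified unresolved downstream).
    """
    k = len(genomes)
    if k not in (4, 5):
        raise ValueError(f"taxon count must be 4 or 5, got {k}")
    labels = [g.name for g in genomes]
    if outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among taxa {labels}")
    og = labels.index(outgroup)
    counts, gaps = pattern_counts_by_window(genomes, windows)
    insufficient = (gaps > gap_threshold).any(axis=1)
    scored_idx = np.flatnonzero(~insufficient)
    tops = enumerate_topologies(k)
    lnls = np.full((len(tops), len(windows)), -np.inf)
    conv_all = True
    if scored_idx.size:
        sub = counts[scored_idx]
        for ti, top in enumerate(tops):
            lnl, _t, conv = optimize_branch_lengths(
                top, sub, k, tol=tol, max_rounds=max_rounds
            )
            lnls[ti, scored_idx] = lnl
            conv_all = conv_all and conv

    results: list[TopologyResult] = []
    for wi in range(len(windows)):
        if insufficient[wi]:
            results.append(
                TopologyResult(
                    window=wi,
                    status="insufficient_data",
                    log_likelihoods=None,
                    best_index=None,
                    rooted_tree=None,
                    rooted_newick=None,
                    tie=False,
                    delta_lnl=None,
                )
            )
            continue
        col = lnls[:, wi]
        order = np.argsort(col)[::-1]
        best = int(order[0])
        delta = float(col[order[0]] - col[order[1]])
        tie = delta < TIE_TOL
        rooted = root_on_outgroup(tops[best], og)
        results.append(
            TopologyResult(
                window=wi,
                status="scored",
                log_likelihoods=col.copy(),
                best_index=best,
                rooted_tree=rooted,
                rooted_newick=newick(rooted, labels) + ";",
                tie=tie,
                delta_lnl=delta,
                converged=conv_all,
            )
        )
    return results
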