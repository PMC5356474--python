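"""Admixture maps, topology fractions, run lengths and tract-length dating.

Per-window ML topology calls are grouped into four categories relative to a
role assignment (focal individual, reference individual, candidate
introgressor): ``species`` when the focal and reference individuals are
monophyletic, ``admix`` when the focal individual groups with the
introgressor, ``ils_alt`` when the *reference* groups with the introgressor
(the opposing topology, attributable to incomplete lineage sorting), and
``other`` for remaining shapes and ties.  Windows with insufficient data pass
through as ``insufficient``.

Because incomplete lineage sorting produces the admix-like and opposing
topologies at equal frequency, the excess of the admix fraction over the
opposing fraction estimates the genuinely introgressed genome fraction.
Contiguous same-category runs measure tract lengths; since recombination
breaks tracts up over time, comparing run-length distributions (ECDFs)
between two admixture signals orders them in time — more small blocks means
an older event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .blocktree import TopologyResult, rooted_clades
from .windows import WindowTable

SPECIES = "species"
ADMIX = "admix"
ILS_ALT = "ils_alt"
OTHER = "other"
INSUFFICIENT = "insufficient"
CATEGORIES = (SPECIES, ADMIX, ILS_ALT, OTHER)


@dataclass
class RunLengthSet:
    """Lengths (bp) of contiguous same-category runs."""

    category: str
    lengths_bp: np.ndarray
    bridged: bool

    @property
    def largest(self) -> int:
        return int(self.lengths_bp.max()) if self.lengths_bp.size else 0

    def lengths_mb(self) -> np.ndarray:
        return self.lengths_bp / 1e6


@dataclass
class EcdfComparison:
    grid: np.ndarray
    ecdf_a: np.ndarray
    ecdf_b: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    verdict: str  # "A_older" | "B_older" | "no_order"


def classify_topology(
    result: TopologyResult,
    labels: list[str],
    focal: str,
    reference: str,
    introgressor: str,
) -> str:
    """Categorize one window's rooted ML tree relative to the role mapping.

    The category is decided by which pair forms a two-taxon clade (cherry) in
    the rooted tree; tie-flagged windows and any other shape fall into
    ``other``.
    """
    for role in (focal, reference, introgressor):
        if role not in labels:
            raise ValueError(f"role {role!r} not among taxa {labels}")
    if result.status == "insufficient_data":
        return INSUFFICIENT
    if result.tie or result.rooted_tree is None:
        return OTHER
    fi, ri, ii = (labels.index(x) for x in (focal, reference, introgressor))
    cherries = {c for c in rooted_clades(result.rooted_tree) if len(c) == 2}
    if frozenset((fi, ri)) in cherries:
        return SPECIES
    if frozenset((fi, ii)) in cherries:
        return ADMIX
    if frozenset((ri, ii)) in cherries:
        return ILS_ALT
    return OTHER


def build_admixture_map(
    results: list[TopologyResult],
    windows: WindowTable,
    labels: list[str],
    focal: str,
    reference: str,
    introgressor: str,
) -> pd.DataFrame:
    """Ordered per-window category table (chrom, start, end, category, tree)."""
    if len(results) != len(windows):
        raise ValueError("one TopologyResult per window required")
    df = windows.df.copy()
    df["category"] = [
        classify_topology(r, labels, focal, reference, introgressor) for r in results
    ]
    df["tree"] = [r.rooted_newick or "." for r in results]
    return df


def topology_fractions(calls: pd.DataFrame | list[str]) -> dict[str, float]:
    """Category fractions over scored (non-insufficient) windows.

    The ``insufficient`` entry reports coverage loss as a fraction of all
    windows and is not part of the sum-to-one scored fractions.
    """
    cats = list(calls["category"]) if isinstance(calls, pd.DataFrame) else list(calls)
    n_total = len(cats)
    scored = [c for c in cats if c != INSUFFICIENT]
    if not scored:
        raise ValueError("no scored windows")
    out = {cat: scored.count(cat) / len(scored) for cat in CATEGORIES}
    out[INSUFFICIENT] = (n_total - len(scored)) / n_total
    return out


def excess_admixture_fraction(f_admix: float, f_ils_alt: float) -> float:
    """ILS-corrected admixed fraction: admix-topology fraction minus the
    opposing-topology fraction, floored at zero.

    A negative difference signals no excess over the lineage-sorting
    background and is reported as 0 with a warning.
    """
    for f in (f_admix, f_ils_alt):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fractions must be in [0,1], got {f}")
    corrected = f_admix - f_ils_alt
    if corrected < 0:
        warnings.warn(
            f"admix fraction {f_admix:.4g} below opposing-topology fraction "
            f"{f_ils_alt:.4g}: no excess admixture",
            stacklevel=2,
        )
        return 0.0
    return corrected


def run_lengths(
    calls: pd.DataFrame, category: str, bridge_missing: bool = False
) -> RunLengthSet:
    """Lengths of maximal consecutive same-category runs, per chromosome.

    With ``bridge_missing``, insufficient-data windows flanked on both sides
    by the category (within a chromosome) are absorbed into a single run and
    their length counted; any other category always breaks a run.  Lengths
    are in bp (terminal short windows contribute their true length).
    """
    lengths: list[int] = []
    for chrom, sub in calls.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if np.any(np.diff(starts) <= 0):
            raise ValueError(f"windows of chromosome {chrom!r} are not position-ordered")
        cats = sub["category"].tolist()
        bp = (sub["end"] - sub["start"]).to_numpy()
        run = 0  # bp in current confirmed run
        pending = 0  # bp of insufficient windows awaiting a right flank
        for c, w in zip(cats, bp):
            if c == category:
                run += pending + w if (bridge_missing and run > 0) else w
                pending = 0
            elif bridge_missing and c == INSUFFICIENT and run > 0:
                pending += w
            else:
                if run > 0:
                    lengths.append(run)
                run = 0
                pending = 0
        if run > 0:
            lengths.append(run)
    return RunLengthSet(
        category=category,
        lengths_bp=np.array(sorted(lengths), dtype=np.int64),
        bridged=bridge_missing,
    )


def ecdf(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Right-continuous empirical CDF of ``values`` evaluated on ``grid``."""
    values = np.sort(np.asarray(values, dtype=float))
    return np.searchsorted(values, grid, side="right") / values.size


def ecdf_compare(
    runs_a: RunLengthSet | np.ndarray,
    runs_b: RunLengthSet | np.ndarray,
    tol: float = 0.05,
) -> EcdfComparison:
    """Compare two run-length distributions.

    Returns both ECDFs on the union grid, the two-sample KS statistic and
    p-value, and a stochastic-order verdict: ``A_older`` when ECDF_A lies
    above ECDF_B pointwise (within ``tol``) and exceeds it somewhere by more
    than ``tol`` — an older admixture event leaves more small blocks.
    """
    a = runs_a.lengths_bp if isinstance(runs_a, RunLengthSet) else np.asarray(runs_a)
    b = runs_b.lengths_bp if isinstance(runs_b, RunLengthSet) else np.asarray(runs_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both run-length sets must be non-empty")
    grid = np.unique(np.concatenate([a, b]).astype(float))
    fa, fb = ecdf(a, grid), ecdf(b, grid)
    ks = stats.ks_2samp(a, b)
    diff = fa - fb
    if diff.min() >= -tol and diff.max() > tol:
        verdict = "A_older"
    elif diff.max() <= tol and diff.min() < -tol:
        verdict = "B_older"
    else:
        verdict = "no_order"
    return EcdfComparison(
        grid=grid,
        ecdf_a=fa,
        ecdf_b=fb,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        verdict=verdict,
    )


def map_to_bed(calls: pd.DataFrame, path) -> None:
    """Write the admixture map as BED (0-based half-open) with the category
    in the name column and the rooted tree as an extra field."""
    cols = calls[["chrom", "start", "end", "category", "tree"]]
    cols.to_csv(path, sep="\t", header=False, index=False)
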