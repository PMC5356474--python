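"""Synthetic aligned-genome simulator with a known population history.

The generator produces per-individual haploid sequences on a shared
coordinate frame from a four- or five-population history
``((P1,P2),P3),O`` (the third population may be sampled twice, as P3a/P3b,
for ratio estimation of admixture proportions).  It models:

* incomplete lineage sorting (ILS): each non-overlapping window is assigned a
  genealogy class — concordant with the species tree with probability
  ``1 - (2/3) exp(-tau)``, or one of the two discordant classes with
  probability ``(1/3) exp(-tau)`` each, where ``tau`` is the internal-branch
  length of the species tree in coalescent units;
* dated admixture pulses: contiguous donor tracts in a recipient genome whose
  lengths are exponential with mean ``1/(r * t_admix)`` bp, the classic
  approximation for a pulse ``t_admix`` generations ago under per-bp
  per-generation recombination probability ``r``;
* transition:transversion-biased mutation (odds ``kappa : 1``);
* post-mortem deamination damage (C->T / G->A, transitions only) on
  individuals flagged historical;
* per-site missingness.

Within each window the genealogy is constant (blocks are the analysis unit);
within-window recombination enters only through tract boundaries.  Mutation
is infinite-sites style: the ancestral allele is uniform over ACGT and each
branch substitutes each site independently with probability
``mu * (branch length / root-to-tip length)``, so ``mu`` is the per-site
substitution probability per root-to-tip lineage.

Donor haplotypes for admixture tracts are an extra, unsampled lineage inside
the P3 clade, so the recipient's tract alleles share the P3 stem (but not the
P3 tip) mutations — exactly the sharing structure the downstream D and f-hat
estimators assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genomes import PseudoHaploidGenome, C, G, N
from .util import prefer_heap_allocations
from .windows import WindowTable, partition_windows

CLASS_NAMES = ("concordant", "discordant_1", "discordant_2")
CONCORDANT, DISCORDANT_1, DISCORDANT_2 = 0, 1, 2

DONOR_TIP = "_donor"


@dataclass(frozen=True)
class AdmixtureEvent:
    """A single admixture pulse from ``donor`` into ``recipient``.

    ``t_admix`` is the age of the pulse in generations and ``proportion`` the
    expected fraction of the recipient genome replaced by donor tracts.
    """

    donor: str
    recipient: str
    t_admix: float
    proportion: float

    def validate(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"admixture proportion must be in [0,1], got {self.proportion}")
        if self.proportion > 0 and self.t_admix <= 0:
            raise ValueError(f"admixture age must be positive, got {self.t_admix}")


@dataclass
class SimConfig:
    """Full parameterization of a simulation run.

    Defaults emulate a wisent-like history: tau = 0.44 coalescent units gives
    ~57% concordant windows, kappa = 2 is a typical mammalian genome-wide
    ts/tv ratio, r = 1e-8/bp/generation is a conventional bovid-scale
    recombination rate, and historical samples carry 5% deamination damage
    with 20% per-site missingness.
    """

    chrom_lengths: dict[str, int]
    populations: tuple[str, ...] = ("P1", "P2", "P3", "O")
    tau: float = 0.44
    t_split: dict[str, float] = field(
        default_factory=lambda: {
            "p1p2": 60_000.0,      # P1/P2 split, generations
            "ingroup": 100_000.0,  # ingroup/P3 split
            "p3_tips": 10_000.0,   # splits among sampled P3 lineages
            "outgroup": 400_000.0, # outgroup split (root-to-tip length)
        }
    )
    admixture_events: tuple[AdmixtureEvent, ...] = ()
    mu: float = 0.005
    kappa: float = 2.0
    r: float = 1e-8
    delta: float = 0.05
    miss: float = 0.2
    historical: tuple[str, ...] = ()
    window_size: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} length must be positive")
        if not 0 <= self.mu < 0.1:
            raise ValueError(f"mu must be in [0, 0.1), got {self.mu}")
        for p, name in [(self.delta, "delta"), (self.miss, "miss")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.tau < 0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        pops = set(self.populations)
        if "O" not in pops or "P1" not in pops or "P2" not in pops:
            raise ValueError("populations must include P1, P2 and O")
        if not ({"P3"} <= pops or {"P3a", "P3b"} <= pops):
            raise ValueError("populations must include P3 or both P3a and P3b")
        events = tuple(
            e if isinstance(e, AdmixtureEvent) else AdmixtureEvent(*e)
            for e in self.admixture_events
        )
        self.admixture_events = events
        clade = set(self.p3_tips)
        for e in events:
            e.validate()
            if e.donor not in clade:
                raise ValueError(
                    f"admixture donor {e.donor!r} must be a P3-clade population {sorted(clade)}"
                )
            if e.recipient not in {"P1", "P2"}:
                raise ValueError(f"admixture recipient must be P1 or P2, got {e.recipient!r}")
        unknown = set(self.historical) - pops
        if unknown:
            raise ValueError(f"historical flags for undeclared populations: {sorted(unknown)}")

    @property
    def p3_tips(self) -> tuple[str, ...]:
        return tuple(p for p in self.populations if p.startswith("P3"))

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def to_json(self) -> str:
        d = asdict(self)
        d["admixture_events"] = [asdict(e) for e in self.admixture_events]
        return json.dumps(d, indent=2)


@dataclass
class SimTruth:
    """Ground truth of a simulation run, for recovery scoring."""

    windows: WindowTable
    block_class: np.ndarray  # int codes into CLASS_NAMES, one per window
    tracts: list[tuple[str, int, int, str, str]]  # chrom, start, end, donor, recipient
    admixed_fraction: dict[str, float]  # realized fraction per recipient
    seed: int

    def class_fractions(self) -> dict[str, float]:
        n = len(self.block_class)
        return {
            name: float((self.block_class == code).sum()) / n
            for code, name in enumerate(CLASS_NAMES)
        }


def sample_block_genealogies(tau: float, n_windows: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a genealogy class for each window independently.

    Concordant with probability ``1 - (2/3) exp(-tau)``; each of the two
    discordant classes with probability ``(1/3) exp(-tau)``.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    p_disc = np.exp(-tau) / 3.0
    probs = [1.0 - 2.0 * p_disc, p_disc, p_disc]
    return rng.choice(3, size=n_windows, p=probs).astype(np.uint8)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def simulate_tracts(
    t_admix: float,
    proportion: float,
    r: float,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator | int,
) -> list[tuple[str, int, int]]:
    """Place admixture tracts so the expected covered genome fraction is
    ``proportion``.

    Tract lengths are exponential with mean ``1/(r * t_admix)`` bp.  Tracts
    are laid down as a stationary Boolean process with start intensity
    ``-ln(1 - proportion) * r * t_admix`` per bp, which makes the pointwise
    coverage probability of the merged process exactly ``proportion``;
    overlapping tracts are merged and tracts are truncated at chromosome
    ends.  The tract count is set deterministically to the rounded expected
    count (allocated across chromosomes by largest remainder) rather than
    drawn Poisson, which halves the replicate-to-replicate variance of the
    realized covered fraction without affecting its expectation.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must be in [0,1], got {proportion}")
    if proportion == 0.0:
        return []
    if proportion == 1.0:
        return [(chrom, 0, L) for chrom, L in chrom_lengths.items()]
    if r * t_admix <= 0:
        raise ValueError("r * t_admix must be positive when proportion > 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mean_len = 1.0 / (r * t_admix)
    lam = -np.log1p(-proportion) / mean_len  # starts per bp
    out: list[tuple[str, int, int]] = []
    ext = 8.0 * mean_len  # left extension so the process is stationary on [0, L)
    chroms = list(chrom_lengths)
    expected = np.array([lam * (chrom_lengths[c] + ext) for c in chroms])
    n_total = int(round(expected.sum()))
    n_per = np.floor(expected).astype(int)
    frac_order = np.argsort(-(expected - np.floor(expected)), kind="stable")
    for i in frac_order[: max(0, n_total - int(n_per.sum()))]:
        n_per[i] += 1
    for ci, chrom in enumerate(chroms):
        L = chrom_lengths[chrom]
        n = int(n_per[ci])
        if n == 0:
            continue
        starts = rng.uniform(-ext, L, size=n)
        lengths = rng.exponential(mean_len, size=n)
        s = np.maximum(starts, 0.0)
        e = np.minimum(starts + lengths, float(L))
        keep = e > s
        ivals = [
            (int(np.floor(a)), int(np.ceil(b)))
            for a, b in zip(s[keep], e[keep])
            if int(np.ceil(b)) > int(np.floor(a))
        ]
        out.extend((chrom, a, b) for a, b in _merge_intervals(ivals))
    return out


def _mutated_values(parent: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """New base codes after one substitution per site of ``parent``.

    A transition is chosen with odds ``kappa:1``; otherwise one of the two
    transversion targets uniformly.  With the ACGTN encoding, the transition
    partner is ``code ^ 2`` and the transversion partners are ``code ^ 1``
    and ``code ^ 3``.
    """
    u = rng.random(parent.size)
    p_ts = kappa / (kappa + 1.0)
    m = np.where(u < p_ts, 2, np.where(u < (1.0 + p_ts) / 2.0, 1, 3)).astype(np.uint8)
    return parent ^ m


def mutate_sequences(
    config: SimConfig,
    windows: WindowTable,
    block_class: np.ndarray,
    tracts: list[tuple[str, int, int, str, str]],
    rng: np.random.Generator,
    include_donor: bool = False,
) -> dict[str, dict[str, np.ndarray]]:
    """Generate haploid sequences for every population tip (plus the internal
    donor lineage) given per-window genealogy classes and admixture tracts.

    Returns a mapping ``tip name -> {chrom: uint8 codes}``.
    """
    if not 0 <= config.mu < 0.1:
        raise ValueError(f"mu must be in [0, 0.1), got {config.mu}")
    ts = config.t_split
    t12, t123, t_p3, t_out = ts["p1p2"], ts["ingroup"], ts["p3_tips"], ts["outgroup"]
    if not (0 < t12 <= t123 <= t_out and 0 < t_p3 <= t123):
        raise ValueError("t_split times must satisfy 0 < p1p2 <= ingroup <= outgroup")
    clade = list(config.p3_tips)
    need_donor = bool(tracts) or include_donor
    clade_all = clade + ([DONOR_TIP] if need_donor else [])
    tips = ["P1", "P2", *clade_all, "O"]
    ingroup = ["P1", "P2", *clade_all]

    def bp(length_gens: float) -> float:
        return config.mu * length_gens / t_out

    seqs: dict[str, dict[str, np.ndarray]] = {t: {} for t in tips}
    for chrom, L in config.chrom_lengths.items():
        anc = rng.integers(0, 4, size=L, dtype=np.uint8)
        cur = {t: anc.copy() for t in tips}

        def apply(members: list[str], p: float, positions: np.ndarray | None = None):
            if positions is None:
                n = rng.binomial(L, p)
                if n == 0:
                    return
                positions = rng.integers(0, L, size=n)
            if positions.size == 0:
                return
            newvals = _mutated_values(cur[members[0]][positions], config.kappa, rng)
            for m in members:
                cur[m][positions] = newvals

        # root-to-tip order so shallower branches overwrite deeper ones
        apply(["O"], bp(t_out))
        apply(ingroup, bp(t_out - t123))
        # internal branch: sister pair depends on the window's genealogy class
        n_int = rng.binomial(L, bp(t123 - t12))
        if n_int:
            pint = rng.integers(0, L, size=n_int)
            cls = block_class[windows.index_of_positions(chrom, pint)]
            apply(["P1", "P2"], 0.0, pint[cls == CONCORDANT])
            apply(["P1", *clade_all], 0.0, pint[cls == DISCORDANT_1])
            apply(["P2", *clade_all], 0.0, pint[cls == DISCORDANT_2])
        apply(clade_all, bp(t123 - t_p3))
        apply(["P1"], bp(t12))
        apply(["P2"], bp(t12))
        for tip in clade_all:
            apply([tip], bp(t_p3))

        for t in tips:
            seqs[t][chrom] = cur[t]

    # admixture tracts: the recipient inherits the donor lineage's alleles
    for chrom, start, end, donor, recipient in tracts:
        seqs[recipient][chrom][start:end] = seqs[DONOR_TIP][chrom][start:end]

    if not include_donor and DONOR_TIP in seqs and not tracts:
        del seqs[DONOR_TIP]
    return seqs


def apply_damage_and_missingness(
    genomes: dict[str, PseudoHaploidGenome],
    delta: float,
    miss: float,
    seed: int,
) -> dict[str, PseudoHaploidGenome]:
    """Degrade sequences in place: deamination damage then missingness.

    On individuals flagged historical, each C is flipped to T (and each G to
    A) with probability ``delta`` — transition-type changes only.  Every site
    of every individual is independently set to N with probability ``miss``.
    The missingness random stream is independent of the damage stream, so the
    missing-site pattern at a fixed seed does not depend on ``delta``.
    """
    for p, name in [(delta, "delta"), (miss, "miss")]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {p}")
    for gi, name in enumerate(sorted(genomes)):
        g = genomes[name]
        rng_dmg = np.random.default_rng([seed, gi, 0])
        rng_miss = np.random.default_rng([seed, gi, 1])
        for chrom in g.chroms:
            arr = g.chroms[chrom]
            if delta > 0 and g.historical:
                idx = np.flatnonzero((arr == C) | (arr == G))
                if idx.size:
                    hit = idx[rng_dmg.random(idx.size) < delta]
                    arr[hit] ^= 2  # C(1)->T(3), G(2)->A(0)
            if miss > 0:
                arr[rng_miss.random(arr.size) < miss] = N
    return genomes


def simulate(config: SimConfig) -> tuple[dict[str, PseudoHaploidGenome], SimTruth]:
    """Run the full generator: genealogies, tracts, mutation, degradation."""
    prefer_heap_allocations()
    ss = np.random.SeedSequence(config.seed)
    rng_gen, rng_tract, rng_mut = (np.random.default_rng(s) for s in ss.spawn(3))

    windows = partition_windows(config.chrom_lengths, config.window_size)
    block_class = sample_block_genealogies(config.tau, len(windows), rng_gen)

    tracts: list[tuple[str, int, int, str, str]] = []
    admixed_fraction: dict[str, float] = {}
    for event in config.admixture_events:
        ivals = simulate_tracts(
            event.t_admix, event.proportion, config.r, config.chrom_lengths, rng_tract
        )
        tracts.extend((chrom, s, e, event.donor, event.recipient) for chrom, s, e in ivals)
    for recipient in {t[4] for t in tracts}:
        per_rec = [(c, s, e) for c, s, e, _, r_ in tracts if r_ == recipient]
        covered = 0
        for chrom in config.chrom_lengths:
            covered += sum(
                e - s
                for s, e in _merge_intervals(
                    [(s, e) for c, s, e in per_rec if c == chrom]
                )
            )
        admixed_fraction[recipient] = covered / config.genome_length

    seqs = mutate_sequences(config, windows, block_class, tracts, rng_mut)
    genomes = {
        name: PseudoHaploidGenome(
            name=name, chroms=chrs, historical=name in config.historical
        )
        for name, chrs in seqs.items()
        if name != DONOR_TIP
    }
    apply_damage_and_missingness(genomes, config.delta, config.miss, config.seed)

    truth = SimTruth(
        windows=windows,
        block_class=block_class,
        tracts=tracts,
        admixed_fraction=admixed_fraction,
        seed=config.seed,
    )
    return genomes, truth


def write_truth(truth: SimTruth, tract_path, class_path) -> None:
    """Write tracts as BED-like TSV and per-window classes as TSV."""
    with open(tract_path, "w") as fh:
        fh.write("#chrom\tstart\tend\tdonor\trecipient\n")
        for chrom, s, e, donor, rec in truth.tracts:
            fh.write(f"{chrom}\t{s}\t{e}\t{donor}\t{rec}\n")
    df = truth.windows.df.copy()
    df["class"] = [CLASS_NAMES[c] for c in truth.block_class]
    df.to_csv(class_path, sep="\t", index=False)
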