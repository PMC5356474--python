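"""Pseudo-haploidization of per-site read stacks and site-pair classification.

Low-coverage genomes do not support diploid genotype calls; instead a single
high-quality base is drawn uniformly at random from the read stack at every
reference position.  Heterozygous sites contribute one of their two alleles,
which is unbiased in expectation and is the standard representation for
degraded historical samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from .genomes import BASES, N, PseudoHaploidGenome, shared_frame

logger = logging.getLogger(__name__)

IDENTICAL = "identical"
TRANSITION = "transition"
TRANSVERSION = "transversion"
MISSING = "missing"

_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class ReadStack:
    """All reads covering one 0-based reference position."""

    chrom: str
    position: int
    reads: list[tuple[str, int, int]]  # (base, base quality, mapping quality)


def classify_site_pair(a: str | int, b: str | int) -> str:
    """Classify an aligned pair of bases.

    ``missing`` if either is N; ``transition`` for A/G and C/T pairs;
    ``transversion`` for the four purine<->pyrimidine pairs; ``identical``
    otherwise.  Symmetric in its arguments.
    """
    ca = _BASE_TO_CODE[a.upper()] if isinstance(a, str) else int(a)
    cb = _BASE_TO_CODE[b.upper()] if isinstance(b, str) else int(b)
    if not (0 <= ca <= N and 0 <= cb <= N):
        raise ValueError(f"invalid base codes: {a!r}, {b!r}")
    if ca == N or cb == N:
        return MISSING
    if ca == cb:
        return IDENTICAL
    if (ca & 1) == (cb & 1):  # same purine/pyrimidine class
        return TRANSITION
    return TRANSVERSION


def draw_base(stack: ReadStack, min_baseq: int, min_mapq: int, rng: np.random.Generator) -> int:
    """Draw one base code uniformly among reads passing both quality cutoffs.

    Returns N when no read qualifies.
    """
    passing = [
        _BASE_TO_CODE[b.upper()]
        for b, bq, mq in stack.reads
        if bq >= min_baseq and mq >= min_mapq and b.upper() in "ACGT"
    ]
    if not passing:
        return N
    return passing[int(rng.integers(0, len(passing)))]


def iter_pileup(path):
    """Yield ``(line_number, ReadStack)`` from a pileup-like TSV.

    Format: ``chrom <TAB> pos0 <TAB> base:baseq:mapq,base:baseq:mapq,...``.
    Malformed rows are logged with their line number and skipped.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                chrom, pos, triples = line.split("\t")
                reads = []
                for t in triples.split(","):
                    if not t:
                        continue
                    base, bq, mq = t.split(":")
                    if base.upper() not in "ACGT":
                        raise ValueError(f"bad base {base!r}")
                    bq_i, mq_i = int(bq), int(mq)
                    if bq_i < 0 or mq_i < 0:
                        raise ValueError("negative quality")
                    reads.append((base.upper(), bq_i, mq_i))
                yield lineno, ReadStack(chrom, int(pos), reads)
            except ValueError as exc:
                logger.warning("pileup %s line %d malformed, skipped: %s", path, lineno, exc)


def sample_pseudohaploid(
    stacks,
    chrom_lengths: dict[str, int],
    min_baseq: int = 30,
    min_mapq: int = 30,
    seed: int = 0,
    name: str = "sample",
    historical: bool = False,
) -> PseudoHaploidGenome:
    """Collapse read stacks into a pseudo-haploid genome.

    ``stacks`` is an iterable of ``ReadStack`` (or ``(lineno, ReadStack)``
    pairs as produced by :func:`iter_pileup`).  Positions with no qualifying
    read emit N; positions never covered are N.
    """
    if min_baseq < 0 or min_mapq < 0:
        raise ValueError("quality thresholds must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = {c: np.full(L, N, dtype=np.uint8) for c, L in chrom_lengths.items()}
    for item in stacks:
        stack = item[1] if isinstance(item, tuple) else item
        if stack.chrom not in chroms:
            raise ValueError(f"pileup chromosome {stack.chrom!r} not in chromosome table")
        if not 0 <= stack.position < chrom_lengths[stack.chrom]:
            raise ValueError(
                f"position {stack.position} out of bounds for chromosome {stack.chrom!r}"
            )
        chroms[stack.chrom][stack.position] = draw_base(stack, min_baseq, min_mapq, rng)
    return PseudoHaploidGenome(name=name, chroms=chroms, historical=historical)


def sample_from_vcf(
    path,
    chrom_lengths: dict[str, int],
    seed: int = 0,
    historical: dict[str, bool] | None = None,
) -> dict[str, PseudoHaploidGenome]:
    """Build pseudo-haploid genomes from a VCF by drawing one allele per
    genotype at random.  Positions absent from the VCF are emitted as N.
    """
    rng = np.random.default_rng(seed)
    historical = historical or {}
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    genomes = {
        s: PseudoHaploidGenome(
            name=s,
            chroms={c: np.full(L, N, dtype=np.uint8) for c, L in chrom_lengths.items()},
            historical=historical.get(s, False),
        )
        for s in samples
    }
    for rec in vcf:
        if rec.chrom not in chrom_lengths:
            continue
        pos = rec.pos - 1  # VCF is 1-based
        alleles = rec.alleles
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None:
                continue
            called = [a for a in gt if a is not None]
            if not called:
                continue
            allele = alleles[called[int(rng.integers(0, len(called)))]]
            if allele is not None and len(allele) == 1 and allele.upper() in "ACGT":
                genomes[s].chroms[rec.chrom][pos] = _BASE_TO_CODE[allele.upper()]
    return genomes


def mask_transitions(genomes: list[PseudoHaploidGenome]) -> dict[str, np.ndarray]:
    """Boolean retain-mask per chromosome for transversion-only analyses.

    A site is excluded (mask False) when any pair of genomes is
    transition-polymorphic there, i.e. when both purines A and G, or both
    pyrimidines C and T, are present in the column.  The operation is
    idempotent: masking a masked set changes nothing further.
    """
    frame = shared_frame(genomes)
    masks: dict[str, np.ndarray] = {}
    for chrom, L in frame.items():
        seen = np.zeros((5, L), dtype=bool)
        for g in genomes:
            arr = g.chroms[chrom]
            for code in range(4):
                seen[code] |= arr == code
        ts_poly = (seen[0] & seen[2]) | (seen[1] & seen[3])
        masks[chrom] = ~ts_poly
    return masks
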