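"""Aligned genome containers and plain-text I/O.

Genomes are stored as one ``numpy.uint8`` array per chromosome, using the
integer codes in :data:`BASES` (``A=0, C=1, G=2, T=3, N=4``).  All genomes
taking part in a comparison must share a coordinate frame: identical
chromosome names and identical per-chromosome lengths.  The encoding is
chosen so that the purine/pyrimidine class of a base is its low bit
(``code & 1``: A,G -> 0; C,T -> 1), which makes transversion masking and
binary recoding cheap vectorised operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = "ACGTN"
A, C, G, T, N = 0, 1, 2, 3, 4

#: lookup table mapping ASCII codes to base codes; anything that is not one of
#: the four nucleotides (IUPAC ambiguity codes, gaps, ...) maps to N.
_ENCODE_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 base codes (non-ACGT -> N)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    return _DECODE_LUT[codes].tobytes().decode("ascii")


@dataclass
class PseudoHaploidGenome:
    """One sampled allele per reference position for a single individual.

    Parameters
    ----------
    name:
        Individual label.
    chroms:
        Mapping chromosome name -> uint8 code array of the full chromosome
        length (missing positions are N).
    historical:
        Whether the individual is a degraded (museum/ancient) sample, i.e.
        subject to post-mortem deamination damage.
    """

    name: str
    chroms: dict[str, np.ndarray] = field(default_factory=dict)
    historical: bool = False

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.chroms.items()}

    def n_fraction(self) -> float:
        total = sum(len(a) for a in self.chroms.values())
        miss = sum(int((a == N).sum()) for a in self.chroms.values())
        return miss / total if total else 0.0

    def copy(self) -> "PseudoHaploidGenome":
        return PseudoHaploidGenome(
            self.name, {c: a.copy() for c, a in self.chroms.items()}, self.historical
        )


class CoordinateFrameError(ValueError):
    """Raised when genomes do not share chromosome names/lengths."""


def shared_frame(genomes: list[PseudoHaploidGenome]) -> dict[str, int]:
    """Validate that all genomes share one coordinate frame and return it.

    Raises :class:`CoordinateFrameError` naming the offending sample and
    chromosome on any mismatch.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    ref = genomes[0].chrom_lengths
    for g in genomes[1:]:
        got = g.chrom_lengths
        if set(got) != set(ref):
            extra = set(got) ^ set(ref)
            raise CoordinateFrameError(
                f"sample {g.name!r}: chromosome set mismatch ({sorted(extra)})"
            )
        for chrom, length in ref.items():
            if got[chrom] != length:
                raise CoordinateFrameError(
                    f"sample {g.name!r}, chromosome {chrom!r}: length "
                    f"{got[chrom]} != expected {length}"
                )
    return ref


def read_fasta(path, name: str | None = None, historical: bool = False) -> PseudoHaploidGenome:
    """Read a per-individual FASTA (one record per chromosome).

    Lowercase bases are accepted; IUPAC codes other than ACGT are mapped to N
    and the total count is logged.
    """
    chroms: dict[str, np.ndarray] = {}
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        codes = encode_sequence(seq)
        raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        n_mapped += int(((codes == N) & (raw != ord("N"))).sum())
        chroms[rec.id] = codes
    if n_mapped:
        logger.info("%s: %d non-ACGTN symbols mapped to N", path, n_mapped)
    if name is None:
        name = str(path)
    return PseudoHaploidGenome(name=name, chroms=chroms, historical=historical)


def write_fasta(genome: PseudoHaploidGenome, path) -> None:
    """Write a genome as FASTA, one record per chromosome, N-padded."""
    records = [
        SeqRecord(Seq(decode_sequence(arr)), id=chrom, description="")
        for chrom, arr in genome.chroms.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_chrom_table(path) -> dict[str, int]:
    """Read a two-column TSV of chromosome name and length in bp."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            out[chrom] = int(length)
    if not out:
        raise ValueError(f"empty chromosome table: {path}")
    return out


def write_chrom_table(chrom_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
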