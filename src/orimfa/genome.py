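"""Chromosome model and synthetic genome generation.

The synthetic genomes emulate the architecture of haloarchaeal replication
origins: each planted ``cdc6`` initiator gene carries, in its upstream
intergenic region, a pair of origin-recognition-box (ORB) repeats in
inverted orientation.  The planted coordinates are recorded as ground truth
in the returned annotation, so downstream sequence-based origin prediction
can be validated by round trip.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default length of a planted cdc6 coding region (bp); haloarchaeal
#: orc1/cdc6 genes run ~1.1-1.3 kb
CDC6_GENE_LENGTH = 1200

#: intergenic space reserved upstream of every planted cdc6 gene (bp)
MIN_UPSTREAM_SPACE = 300


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Chromosome:
    """A (by default circular) replicon.

    Parameters
    ----------
    name : replicon identifier used in all genomic output files.
    length : size in base pairs; must be positive.
    circular : whether coordinates wrap (archaeal chromosomes are circles).
    sequence : optional nucleotide string over {A,C,G,T} of length ``length``.
    """

    name: str
    length: int
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"chromosome length must be positive, got {self.length}")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
            if set(self.sequence) - set(DNA_ALPHABET):
                bad = sorted(set(self.sequence) - set(DNA_ALPHABET))
                raise ValueError(f"sequence contains non-ACGT characters: {bad}")

    def circular_distance(self, a, b):
        """Shortest arc (bp) between coordinates ``a`` and ``b``.

        Vectorized over numpy arrays.  On a linear chromosome this is the
        plain absolute difference.
        """
        d = np.abs(np.asarray(a) - np.asarray(b))
        if self.circular:
            d = np.minimum(d, self.length - d)
        return d


@dataclass(frozen=True)
class Feature:
    """A genomic feature (gene or planted motif instance).

    ``start``/``end`` are 0-based half-open; GFF3 conversion happens only at
    the I/O boundary.
    """

    id: str
    type: str  # "gene" | "ORB"
    start: int
    end: int
    strand: str  # "+" | "-"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"feature {self.id}: end {self.end} <= start {self.start}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id}: bad strand {self.strand!r}")


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.6) -> str:
    """Random background with haloarchaeal GC content (~60%)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(list(DNA_ALPHABET))[idx])


def generate_genome(
    length: int,
    cdc6_loci: list[tuple[int, str]],
    orb_consensus: str,
    orb_spacing: int,
    seed: int,
    gene_length: int = CDC6_GENE_LENGTH,
    gc: float = 0.6,
    name: str = "chr",
) -> tuple[Chromosome, list[Feature]]:
    """Generate a random circular chromosome with planted cdc6/ORB loci.

    At each requested cdc6 locus ``(position, strand)`` a gene feature of
    ``gene_length`` bp is placed with its coding start at ``position`` (on
    the given strand), and two copies of ``orb_consensus`` are planted in
    the intergenic region immediately upstream of the gene: one on each
    strand (an inverted pair), separated by ``orb_spacing`` bp.

    Returns the chromosome (with sequence) and the ground-truth annotation:
    one ``gene`` feature per locus plus two ``ORB`` features per locus whose
    attributes carry ``planted=true``.

    Raises
    ------
    ValueError
        If planted elements would overlap each other or run off the
        available space.
    """
    if not 18 <= len(orb_consensus) <= 35:
        raise ValueError(
            f"orb_consensus length {len(orb_consensus)} outside the ORB motif range [18, 35]"
        )
    if set(orb_consensus) - set(DNA_ALPHABET):
        raise ValueError("orb_consensus must be over ACGT")
    if orb_spacing < 0:
        raise ValueError("orb_spacing must be >= 0")

    cassette = 2 * len(orb_consensus) + orb_spacing
    if cassette > MIN_UPSTREAM_SPACE:
        raise ValueError(
            f"ORB cassette ({cassette} bp) exceeds the reserved upstream space "
            f"({MIN_UPSTREAM_SPACE} bp)"
        )

    rng = np.random.default_rng(seed)
    seq = list(_random_sequence(rng, length, gc=gc))

    features: list[Feature] = []
    occupied: list[tuple[int, int, str]] = []  # (start, end, locus id)

    def claim(start: int, end: int, what: str):
        if start < 0 or end > length:
            raise ValueError(
                f"{what}: span [{start}, {end}) falls outside the {length}-bp chromosome"
            )
        for s, e, other in occupied:
            if start < e and s < end:
                raise ValueError(
                    f"{what}: span [{start}, {end}) overlaps {other} at [{s}, {e})"
                )
        occupied.append((start, end, what))

    for n, (pos, strand) in enumerate(sorted(cdc6_loci), start=1):
        gene_id = f"cdc6_{n}"
        if strand == "+":
            g_start, g_end = pos, pos + gene_length
            u_start, u_end = g_start - MIN_UPSTREAM_SPACE, g_start
        elif strand == "-":
            g_start, g_end = pos, pos + gene_length
            u_start, u_end = g_end, g_end + MIN_UPSTREAM_SPACE
        else:
            raise ValueError(f"bad strand {strand!r} for locus at {pos}")
        claim(g_start, g_end, f"gene {gene_id}")
        claim(u_start, u_end, f"upstream region of {gene_id}")

        # centre the inverted ORB cassette within the upstream window
        pad = (MIN_UPSTREAM_SPACE - cassette) // 2
        a_start = u_start + pad
        b_start = a_start + len(orb_consensus) + orb_spacing
        seq[a_start : a_start + len(orb_consensus)] = orb_consensus
        seq[b_start : b_start + len(orb_consensus)] = reverse_complement(orb_consensus)

        features.append(
            Feature(gene_id, "gene", g_start, g_end, strand, {"name": gene_id})
        )
        for tag, s, orb_strand in ((f"{gene_id}_ORB1", a_start, "+"),
                                   (f"{gene_id}_ORB2", b_start, "-")):
            features.append(
                Feature(
                    tag,
                    "ORB",
                    s,
                    s + len(orb_consensus),
                    orb_strand,
                    {"planted": "true", "parent_gene": gene_id},
                )
            )

    features.sort(key=lambda f: f.start)
    chrom = Chromosome(name=name, length=length, circular=True, sequence="".join(seq))
    return chrom, features
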