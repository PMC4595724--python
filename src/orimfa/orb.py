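"""Sequence-based origin prediction via inverted ORB repeats.

Archaeal replication origins typically sit in the intergenic region
immediately upstream of an ``orc1/cdc6`` initiator gene and contain a pair
of origin-recognition-box (ORB) repeats in inverted orientation flanking an
AT-rich duplex-unwinding element.  The predictor here automates that rule:

1. extract the intergenic region immediately upstream of each cdc6 gene
   (:func:`extract_upstream_intergenic`);
2. find repeated 18-35 bp motifs within the region, on either strand,
   tolerating a configurable number of mismatches
   (:func:`find_repeated_motifs` — an exhaustive seed-and-extend repeat
   search);
3. keep motifs whose consensus carries a G-string (a run of >= 4 G on
   either strand, :func:`has_g_string`) — the hallmark of genuine ORB
   elements;
4. keep loci where the motif occurs on both strands (an inverted pair);
   each surviving locus is one origin prediction (:func:`predict_origins`).

The repeat search is exhaustive rather than an expectation-maximization
motif model: upstream regions are at most a few kb, where enumerating all
substring pairs is tractable and exactly verifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Chromosome, Feature, reverse_complement

MIN_MOTIF_LEN = 18
MAX_MOTIF_LEN = 35
DEFAULT_MAX_MISMATCH = 3
DEFAULT_G_RUN = 4

_BASE_TO_INT = {c: i for i, c in enumerate("ACGT")}
_INT_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G


@dataclass(frozen=True)
class IntergenicRegion:
    """The intergenic gap immediately upstream of an anchored gene."""

    chrom_name: str
    start: int
    end: int
    gene_id: str
    gene_strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"region for {self.gene_id}: end {self.end} <= start {self.start}"
            )

    @property
    def length(self):
        return self.end - self.start


@dataclass
class MotifInstance:
    position: int  # region-relative start
    strand: str
    mismatches: int


@dataclass
class ORBMotif:
    """A repeated motif with its instances within one region."""

    consensus: str
    instances: list[MotifInstance]
    g_string: bool = False

    @property
    def length(self):
        return len(self.consensus)

    def strands(self) -> set[str]:
        return {inst.strand for inst in self.instances}


@dataclass
class OriginPrediction:
    """A cdc6-anchored origin call with its inverted ORB pair."""

    gene_id: str
    region: IntergenicRegion
    orb: ORBMotif
    inverted_pair: tuple[int, int]  # instance indices on opposite strands

    @property
    def position(self) -> int:
        """Representative chromosomal coordinate (midpoint of the region)."""
        return (self.region.start + self.region.end) // 2


@dataclass
class PredictionFailure:
    """A cdc6 gene that failed the origin rule, with the failing step."""

    gene_id: str
    step: str  # "no intergenic region" | "no repeated motif" | "no G-string" | "no inverted pair"


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_TO_INT[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"degenerate or non-ACGT character in sequence: {exc}") from None


def extract_upstream_intergenic(
    annotation: list[Feature],
    gene_id: str,
    chrom: Chromosome,
    max_span: int = 2000,
) -> IntergenicRegion:
    """The gap between a gene's strand-aware upstream boundary and its
    nearest neighbouring gene, truncated to ``max_span`` bp.

    For a plus-strand gene the region ends at the gene start; for a
    minus-strand gene it begins at the gene end.  Raises on an absent gene
    or a zero-length gap.
    """
    genes = sorted((f for f in annotation if f.type == "gene"), key=lambda f: f.start)
    target = next((g for g in genes if g.id == gene_id), None)
    if target is None:
        raise ValueError(f"gene {gene_id!r} not found in annotation")
    if target.strand == "+":
        upstream_ends = [g.end for g in genes if g is not target and g.end <= target.start]
        lo = max(upstream_ends) if upstream_ends else 0
        hi = target.start
        lo = max(lo, hi - max_span)
    else:
        downstream_starts = [g.start for g in genes if g is not target and g.start >= target.end]
        lo = target.end
        hi = min(downstream_starts) if downstream_starts else chrom.length
        hi = min(hi, lo + max_span)
    if hi <= lo:
        raise ValueError(f"no intergenic region upstream of {gene_id}")
    return IntergenicRegion(chrom.name, lo, hi, gene_id, target.strand)


def _mismatch_runs(a: np.ndarray, b: np.ndarray, min_len: int, max_len: int,
                   max_mismatch: int):
    """Maximal matching windows between two equal-length encoded sequences.

    Yields (offset, length, mismatches) for every maximal window of a
    diagonal comparison whose mismatch count is within budget.  A window is
    maximal if it cannot be extended on either side without exceeding the
    mismatch budget, running off the diagonal, or passing ``max_len``.
    """
    neq = (a != b).astype(np.int64)
    m = len(neq)
    if m < min_len:
        return
    cum = np.concatenate([[0], np.cumsum(neq)])

    starts = np.arange(m - min_len + 1)
    # farthest right end within the mismatch budget, then the length cap
    jmax = np.searchsorted(cum, cum[starts] + max_mismatch, side="right") - 1
    ends = np.minimum(jmax, np.minimum(starts + max_len, m))
    ok = ends - starts >= min_len
    starts, ends = starts[ok], ends[ok]
    if len(starts) == 0:
        return
    # extend left while the budget and the length cap allow
    smin = np.searchsorted(cum, cum[ends] - max_mismatch, side="left")
    s = np.maximum(smin, ends - max_len)
    windows = np.unique(np.stack([s, ends], axis=1), axis=0)
    for s_i, j_i in windows:
        yield int(s_i), int(j_i - s_i), int(cum[j_i] - cum[s_i])


@dataclass(frozen=True)
class RepeatPair:
    """A maximal matched substring pair within a region.

    ``pos_a`` is always on the forward strand.  For ``strand == '-'`` the
    second instance is the reverse complement at ``pos_b`` (forward-strand
    coordinate of its leftmost base).
    """

    pos_a: int
    pos_b: int
    length: int
    strand: str  # strand of the second instance
    mismatches: int


def maximal_repeat_pairs(
    seq: str,
    min_len: int = MIN_MOTIF_LEN,
    max_len: int = MAX_MOTIF_LEN,
    max_mismatch: int = 0,
) -> list[RepeatPair]:
    """All maximal substring pairs of length in [min_len, max_len] repeated
    within ``seq`` (either orientation) with at most ``max_mismatch``
    mismatches.

    Direct repeats are scanned diagonal-by-diagonal against the shifted
    sequence; inverted repeats against the reverse complement, mapping hit
    coordinates back to the forward strand.
    """
    enc = encode(seq)
    n = len(enc)
    rc = _INT_COMP[enc][::-1]
    pairs: set[RepeatPair] = set()

    # direct repeats: compare seq[i] with seq[i+d] along each shift d
    for d in range(1, n - min_len + 1):
        a, b = enc[:-d], enc[d:]
        for off, length, mism in _mismatch_runs(a, b, min_len, max_len, max_mismatch):
            pairs.add(RepeatPair(off, off + d, length, "+", mism))

    # inverted repeats: seq window vs reverse-complement window.  rc[k]
    # corresponds to forward position n-1-k, so a match of seq[i:i+L] with
    # rc[j:j+L] is an inverted repeat whose second copy occupies forward
    # coordinates [n-j-L, n-j).
    for d in range(-(n - min_len), n - min_len + 1):
        if d > 0:
            a, b = enc[:-d] if d else enc, rc[d:]
            base_i, base_j = 0, d
        elif d < 0:
            a, b = enc[-d:], rc[:d]
            base_i, base_j = -d, 0
        else:
            a, b = enc, rc
            base_i = base_j = 0
        for off, length, mism in _mismatch_runs(a, b, min_len, max_len, max_mismatch):
            i = base_i + off
            j_rc = base_j + off
            j_fwd = n - j_rc - length
            if j_fwd == i:
                # a palindrome matching itself in place is not a repeat pair
                continue
            lo, hi = (i, j_fwd) if i <= j_fwd else (j_fwd, i)
            strand_pair = RepeatPair(lo, hi, length, "-", mism)
            pairs.add(strand_pair)

    # drop pairs properly contained in a longer pair on the same diagonal
    # and orientation
    out = []
    plist = sorted(pairs, key=lambda p: (-p.length, p.pos_a, p.pos_b))
    for p in plist:
        contained = False
        for q in out:
            if (
                q.strand == p.strand
                and q.length >= p.length
                and q.pos_a <= p.pos_a
                and p.pos_a + p.length <= q.pos_a + q.length
                and q.pos_b <= p.pos_b
                and p.pos_b + p.length <= q.pos_b + q.length
                and (
                    (p.strand == "+" and p.pos_b - p.pos_a == q.pos_b - q.pos_a)
                    or (p.strand == "-" and p.pos_a + p.pos_b + p.length
                        == q.pos_a + q.pos_b + q.length)
                )
            ):
                contained = True
                break
        if not contained:
            out.append(p)
    return sorted(out, key=lambda p: (p.pos_a, p.pos_b))


def _consensus(seqs: list[str]) -> str:
    cols = zip(*seqs)
    out = []
    for col in cols:
        vals, counts = np.unique(list(col), return_counts=True)
        out.append(str(vals[np.argmax(counts)]))  # ties: lexicographically first
    return "".join(out)


def find_repeated_motifs(
    seq: str,
    min_len: int = MIN_MOTIF_LEN,
    max_len: int = MAX_MOTIF_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    g_run: int = DEFAULT_G_RUN,
) -> list[ORBMotif]:
    """Repeated-motif discovery within one intergenic region.

    Wraps :func:`maximal_repeat_pairs`: each maximal pair becomes a
    two-instance motif; pairs whose instance footprints substantially
    overlap are collapsed onto the longest.  The consensus is the
    majority base per column over the forward-oriented instance sequences.
    """
    if len(seq) < 2 * min_len:
        raise ValueError(
            f"region of {len(seq)} bp is shorter than two motif copies "
            f"({2 * min_len} bp)"
        )
    pairs = maximal_repeat_pairs(seq, min_len, max_len, max_mismatch)

    def footprint(p: RepeatPair):
        return {(p.pos_a, p.pos_a + p.length), (p.pos_b, p.pos_b + p.length)}

    def overlaps(p: RepeatPair, q: RepeatPair) -> bool:
        def iv_overlap(u, v):
            inter = min(u[1], v[1]) - max(u[0], v[0])
            return inter > 0.5 * min(u[1] - u[0], v[1] - v[0])

        fp, fq = footprint(p), footprint(q)
        return all(any(iv_overlap(u, v) for v in fq) for u in fp)

    kept: list[RepeatPair] = []
    for p in sorted(pairs, key=lambda p: (-p.length, p.mismatches, p.pos_a)):
        if not any(overlaps(p, q) for q in kept):
            kept.append(p)

    motifs = []
    for p in sorted(kept, key=lambda p: (p.pos_a, p.pos_b)):
        first = seq[p.pos_a : p.pos_a + p.length]
        second_fwd = seq[p.pos_b : p.pos_b + p.length]
        if p.strand == "+":
            oriented = [first, second_fwd]
            inst = [
                MotifInstance(p.pos_a, "+", 0),
                MotifInstance(p.pos_b, "+", p.mismatches),
            ]
        else:
            oriented = [first, reverse_complement(second_fwd)]
            inst = [
                MotifInstance(p.pos_a, "+", 0),
                MotifInstance(p.pos_b, "-", p.mismatches),
            ]
        cons = _consensus(oriented)
        motifs.append(
            ORBMotif(cons, inst, g_string=has_g_string(cons, g_run=g_run))
        )
    return motifs


def has_g_string(consensus: str, g_run: int = DEFAULT_G_RUN) -> bool:
    """True iff the consensus or its reverse complement carries a run of at
    least ``g_run`` consecutive G (equivalently: a G- or C-run on the
    forward strand)."""
    if not consensus:
        raise ValueError("empty consensus")
    return "G" * g_run in consensus or "C" * g_run in consensus


def predict_origins(
    chrom: Chromosome,
    annotation: list[Feature],
    cdc6_ids: list[str],
    max_span: int = 2000,
    min_len: int = MIN_MOTIF_LEN,
    max_len: int = MAX_MOTIF_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    g_run: int = DEFAULT_G_RUN,
) -> tuple[list[OriginPrediction], list[PredictionFailure]]:
    """Apply the full origin rule to each cdc6 gene.

    Region extraction -> repeat search -> G-string filter -> inverted-pair
    filter.  Genes failing any step are reported with the failing step
    named.  Among qualifying motifs the longest (then least-mismatched) one
    is attached to the prediction.
    """
    if chrom.sequence is None:
        raise ValueError("chromosome carries no sequence")
    predictions, failures = [], []
    for gid in cdc6_ids:
        try:
            region = extract_upstream_intergenic(annotation, gid, chrom, max_span)
        except ValueError as exc:
            if "no intergenic region" in str(exc):
                failures.append(PredictionFailure(gid, "no intergenic region"))
                continue
            raise
        rseq = chrom.sequence[region.start : region.end]
        try:
            motifs = find_repeated_motifs(rseq, min_len, max_len, max_mismatch, g_run)
        except ValueError:
            motifs = []
        if not motifs:
            failures.append(PredictionFailure(gid, "no repeated motif"))
            continue
        with_g = [m for m in motifs if m.g_string]
        if not with_g:
            failures.append(PredictionFailure(gid, "no G-string"))
            continue
        inverted = [m for m in with_g if {"+", "-"} <= m.strands()]
        if not inverted:
            failures.append(PredictionFailure(gid, "no inverted pair"))
            continue
        best = max(inverted, key=lambda m: (m.length, -sum(i.mismatches for i in m.instances)))
        pair_idx = (
            next(i for i, x in enumerate(best.instances) if x.strand == "+"),
            next(i for i, x in enumerate(best.instances) if x.strand == "-"),
        )
        predictions.append(OriginPrediction(gid, region, best, pair_idx))
    return predictions, failures
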