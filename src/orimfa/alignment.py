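"""Pairwise Cdc6/Orc1 identity for origin-conservation calls.

Conservation of an origin across related genomes is scored through its
initiator protein: two Cdc6 proteins are called orthologous (and their
origins shared) when their pairwise identity exceeds a threshold, 80% by
default.

Identity is computed from a global alignment under BLOSUM62 with affine
gap cost 11 + g for a gap of length g (open 11, extend 1), as
``100 x identical aligned columns / total alignment columns`` with gap
columns counted in the denominator.  The measure is symmetric and equals
100 for identical sequences.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

GAP_OPEN = 11
GAP_EXTEND = 1
DEFAULT_IDENTITY_THRESHOLD = 80.0


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # first gap column scores open+extend, later columns extend: cost 11 + g
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _validate(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty protein sequence")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{label}: invalid residues {sorted(bad)}")
    return seq


def cdc6_identity(protein_a: str, protein_b: str) -> float:
    """Percent identity of two initiator proteins under global alignment.

    Gaps count as (non-identical) alignment columns, so the value is the
    fraction of columns with the same residue on both rows, in percent.
    """
    _validate(protein_a, "protein_a")
    _validate(protein_b, "protein_b")
    alignment = _aligner().align(protein_a, protein_b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


def alignment_score(protein_a: str, protein_b: str) -> float:
    """Optimal global alignment score (BLOSUM62, gap cost 11 + g)."""
    _validate(protein_a, "protein_a")
    _validate(protein_b, "protein_b")
    return float(_aligner().score(protein_a, protein_b))


def is_ortholog(protein_a: str, protein_b: str,
                threshold: float = DEFAULT_IDENTITY_THRESHOLD) -> bool:
    """Ortholog-of-origin call: identity strictly above the threshold."""
    return cdc6_identity(protein_a, protein_b) > threshold


def identity_matrix(proteins: dict[str, str]) -> pd.DataFrame:
    """Symmetric pairwise identity matrix over a set of named proteins."""
    names = list(proteins)
    mat = pd.DataFrame(100.0, index=names, columns=names)
    for a, b in combinations(names, 2):
        ident = cdc6_identity(proteins[a], proteins[b])
        mat.loc[a, b] = mat.loc[b, a] = ident
    return mat
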