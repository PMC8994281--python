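"""Pairwise alignment identity with ClustalW-style DNA scoring.

Scoring follows the published parameters: IUB-style DNA matrix
(+1.9 for an identical unambiguous match, 0 for a mismatch, ambiguity
codes scored as the mean over their expansions), gap open 15 and gap
extend 6.66 as penalties.  Terminal gaps are free and, by default,
excluded from the identity denominator.

The dynamic programming itself is delegated to
:class:`Bio.Align.PairwiseAligner`; an independent exhaustive-enumeration
oracle for short sequences lives in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "IUPAC_EXPANSIONS",
    "SequenceAlphabetError",
    "ScoringScheme",
    "AlignmentResult",
    "IdentityTable",
    "ParalogRanking",
    "DegenerateHit",
    "global_identity",
    "identity_table",
    "classify_paralog",
    "degenerate_scan",
]

IUPAC_EXPANSIONS = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_ALPHABET = "".join(sorted(set(IUPAC_EXPANSIONS) - {"U"}))


class SequenceAlphabetError(ValueError):
    """A sequence contains a non-IUPAC character."""


def _validate(seq: str, name: str = "sequence") -> str:
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise SequenceAlphabetError(f"{name} is empty")
    bad = set(seq) - set(IUPAC_EXPANSIONS)
    if bad:
        raise SequenceAlphabetError(
            f"{name} contains non-IUPAC characters: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap DNA scoring parameters."""

    match: float = 1.9
    mismatch: float = 0.0
    gap_open: float = 15.0
    gap_extend: float = 6.66
    free_end_gaps: bool = True
    count_terminal_gaps_in_identity: bool = False

    def substitution_score(self, x: str, y: str) -> float:
        """Mean match score over the IUPAC expansions of x and y."""
        ex, ey = IUPAC_EXPANSIONS[x], IUPAC_EXPANSIONS[y]
        hits = sum(1 for a in ex for b in ey if a == b)
        total = len(ex) * len(ey)
        return (hits * self.match + (total - hits) * self.mismatch) / total

    def matrix(self) -> substitution_matrices.Array:
        arr = substitution_matrices.Array(_ALPHABET, dims=2)
        for x, y in itertools.product(_ALPHABET, repeat=2):
            arr[x, y] = self.substitution_score(x, y)
        return arr

    def aligner(self, mode: str = "global") -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local" if mode == "local" else "global"
        aligner.substitution_matrix = self.matrix()
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        if mode != "local" and self.free_end_gaps:
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
            aligner.open_end_deletion_score = 0.0
            aligner.extend_end_deletion_score = 0.0
        return aligner


#: maximal-segment variant used for local scans: a zero-cost mismatch
#: would let local alignments grow without bound, so mismatches are
#: penalised symmetrically to the match reward.
LOCAL_SCHEME = ScoringScheme(mismatch=-1.9)

DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    identity_pct: float
    score: float
    identical_columns: int
    alignment_length: int
    segment: Optional[tuple[int, int]] = None  # 1-based inclusive, on a

    def __post_init__(self):
        assert 0.0 <= self.identity_pct <= 100.0


def _alignment_strings(alignment) -> tuple[str, str]:
    text = alignment.format("fasta").strip().splitlines()
    # fasta format: >target / seq / >query / seq (possibly wrapped)
    seqs, cur = [], []
    for line in text:
        if line.startswith(">"):
            if cur:
                seqs.append("".join(cur))
            cur = []
        else:
            cur.append(line)
    seqs.append("".join(cur))
    return seqs[0], seqs[1]


def _identity(
    aligned_a: str, aligned_b: str, scheme: ScoringScheme
) -> tuple[int, int]:
    """(identical columns, denominator length)."""
    n = len(aligned_a)
    start, end = 0, n
    if not scheme.count_terminal_gaps_in_identity:
        while start < n and ("-" in (aligned_a[start], aligned_b[start])):
            if aligned_a[start] != "-" and aligned_b[start] != "-":
                break
            start += 1
        while end > start and ("-" in (aligned_a[end - 1], aligned_b[end - 1])):
            if aligned_a[end - 1] != "-" and aligned_b[end - 1] != "-":
                break
            end -= 1
    ident = sum(
        1
        for i in range(start, end)
        if aligned_a[i] == aligned_b[i] and aligned_a[i] != "-"
    )
    length = max(end - start, 1)
    return ident, length


def global_identity(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> AlignmentResult:
    """Affine-gap global alignment identity between two DNA sequences."""
    a = _validate(a, "first sequence")
    b = _validate(b, "second sequence")
    aligner = scheme.aligner("global")
    alignment = aligner.align(a, b)[0]
    aligned_a, aligned_b = _alignment_strings(alignment)
    ident, length = _identity(aligned_a, aligned_b, scheme)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        identity_pct=100.0 * ident / length,
        score=float(alignment.score),
        identical_columns=ident,
        alignment_length=length,
    )


@dataclass
class IdentityTable:
    table: pd.DataFrame  # columns: gene, identity_pct

    @property
    def min(self) -> float:
        return float(self.table["identity_pct"].min())

    @property
    def max(self) -> float:
        return float(self.table["identity_pct"].max())

    @property
    def mean(self) -> float:
        return float(self.table["identity_pct"].mean())


def identity_table(
    genes_a: Mapping[str, str],
    genes_b: Mapping[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> IdentityTable:
    """Per-gene global identity over the shared gene names.

    The summary mean is the unweighted average of per-gene identities.
    """
    shared = sorted(set(genes_a) & set(genes_b))
    if not shared:
        raise ValueError("no shared gene names between the two sets")
    rows = [
        {
            "gene": gene,
            "identity_pct": global_identity(
                genes_a[gene], genes_b[gene], scheme
            ).identity_pct,
        }
        for gene in shared
    ]
    return IdentityTable(table=pd.DataFrame(rows))


@dataclass(frozen=True)
class ParalogRanking:
    ranking: tuple[tuple[str, float], ...]  # (candidate, mean identity) desc

    @property
    def likely_original(self) -> str:
        return self.ranking[0][0]


def classify_paralog(
    candidates: Mapping[str, str],
    orthologs: Mapping[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> ParalogRanking:
    """Rank candidate paralog copies by mean identity to orthologs from
    other taxa; the top-ranked candidate is the likely original copy."""
    if not candidates or not orthologs:
        raise ValueError("need at least one candidate and one ortholog")
    means = []
    for name in sorted(candidates):
        idents = [
            global_identity(candidates[name], seq, scheme).identity_pct
            for _, seq in sorted(orthologs.items())
        ]
        means.append((name, float(np.mean(idents))))
    means.sort(key=lambda t: (-t[1], t[0]))
    return ParalogRanking(ranking=tuple(means))


@dataclass(frozen=True)
class DegenerateHit:
    gene: str
    segment: tuple[int, int]  # 1-based inclusive on the reference
    identity_pct: float
    identical_bp: int
    alignment_length: int


def degenerate_scan(
    ncs: str,
    reference_genes: Mapping[str, str],
    min_identity: float = 50.0,
    min_length: int = 30,
    scheme: ScoringScheme = LOCAL_SCHEME,
) -> list[DegenerateHit]:
    """Scan a non-coding sequence against full-length reference genes.

    The best local alignment against each reference is reported when it
    passes both the identity and length thresholds, with 1-based
    inclusive reference coordinates.
    """
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must be in (0, 100]")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    ncs = _validate(ncs, "non-coding sequence")
    aligner = scheme.aligner("local")
    hits = []
    for gene in sorted(reference_genes):
        ref = _validate(reference_genes[gene], f"reference {gene}")
        alignments = aligner.align(ref, ncs)
        if len(alignments) == 0:
            continue
        best = alignments[0]
        aligned_ref, aligned_ncs = _alignment_strings(best)
        ident = sum(
            1
            for x, y in zip(aligned_ref, aligned_ncs)
            if x == y and x != "-"
        )
        length = len(aligned_ref)
        identity = 100.0 * ident / length if length else 0.0
        ref_start = int(best.coordinates[0][0]) + 1
        ref_end = int(best.coordinates[0][-1])
        if length >= min_length and identity >= min_identity:
            hits.append(
                DegenerateHit(
                    gene=gene,
                    segment=(ref_start, ref_end),
                    identity_pct=identity,
                    identical_bp=ident,
                    alignment_length=length,
                )
            )
    hits.sort(key=lambda h: (-h.identity_pct * h.alignment_length, h.gene))
    return hits
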