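"""Conserved AT-rich / GC-rich motif discovery in non-coding regions.

The non-coding regions flanking minichromosome coding regions carry a
hallmark AT-rich motif upstream and a GC-rich motif downstream.  Motifs
are recovered by exact k-mer seeding followed by greedy gapless
consensus extension: the maximal window whose per-copy identity to the
majority consensus stays above a threshold in a sufficient fraction of
minichromosomes.

Deterministic given the inputs: minichromosome labels are processed in
sorted order and seed ties break lexicographically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional

from .alignment_identity import IUPAC_EXPANSIONS, SequenceAlphabetError

__all__ = ["MotifOccurrence", "MotifReport", "composition", "find_conserved_motif"]


def composition(seq: str) -> tuple[float, float]:
    """(AT%, GC%) of a sequence; ambiguity codes apportioned fractionally."""
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise SequenceAlphabetError("empty sequence")
    at = gc = 0.0
    for ch in seq:
        try:
            exp = IUPAC_EXPANSIONS[ch]
        except KeyError:
            raise SequenceAlphabetError(
                f"non-IUPAC character {ch!r}"
            ) from None
        at += sum(1 for b in exp if b in "AT") / len(exp)
        gc += sum(1 for b in exp if b in "GC") / len(exp)
    n = len(seq)
    return 100.0 * at / n, 100.0 * gc / n


@dataclass(frozen=True)
class MotifOccurrence:
    minichromosome: str
    offset: int  # 0-based start of the window within the NCR
    identity_pct: float  # identity of this copy to the consensus


@dataclass(frozen=True)
class MotifReport:
    consensus: str
    length: int
    composition_pct: float  # AT% if AT-rich else GC%
    rich: str  # "AT" | "GC"
    position_class: str  # "upstream" | "downstream"
    occurrences: tuple[MotifOccurrence, ...]
    coverage: float  # fraction of minichromosomes containing the motif

    def __post_init__(self):
        at, gc = composition(self.consensus)
        expected = at if self.rich == "AT" else gc
        assert abs(expected - self.composition_pct) < 1e-9


def _column_consensus(chars: list[str]) -> str:
    counts = Counter(chars)
    # deterministic: majority, ties by base order A<C<G<T
    return max(sorted(counts), key=lambda b: counts[b])


def _window_stats(
    seqs: dict[str, str], offsets: dict[str, int], length: int
) -> tuple[str, dict[str, float]]:
    """Consensus and per-copy identity for aligned gapless windows."""
    members = sorted(offsets)
    columns = []
    for i in range(length):
        columns.append(
            _column_consensus([seqs[m][offsets[m] + i] for m in members])
        )
    consensus = "".join(columns)
    idents = {}
    for m in members:
        window = seqs[m][offsets[m] : offsets[m] + length]
        same = sum(1 for a, b in zip(window, consensus) if a == b)
        idents[m] = 100.0 * same / length
    return consensus, idents


def find_conserved_motif(
    ncrs: Mapping[str, str],
    position_class: str = "upstream",
    min_coverage: float = 0.8,
    min_identity: float = 70.0,
    k: int = 8,
    min_length: int = 16,
) -> Optional[MotifReport]:
    """Find a conserved motif shared across NCR sequences.

    Returns ``None`` when no window of at least ``min_length`` passes
    both thresholds, which is a legitimate outcome (some species show no
    conserved AT-rich motif).
    """
    if len(ncrs) < 2:
        raise ValueError("need at least two NCR sequences")
    seqs = {
        label: seq.upper().replace("U", "T") for label, seq in ncrs.items()
    }
    for label, seq in seqs.items():
        bad = set(seq) - set(IUPAC_EXPANSIONS)
        if bad:
            raise SequenceAlphabetError(
                f"{label}: non-IUPAC characters {sorted(bad)}"
            )
    n = len(seqs)
    need = max(2, int(min_coverage * n + 1e-9))
    core_need = max(2, min(3, n))

    # --- seed: most widespread exact k-mer ------------------------------
    kmer_members: dict[str, set[str]] = {}
    for label in sorted(seqs):
        seq = seqs[label]
        for i in range(len(seq) - k + 1):
            kmer_members.setdefault(seq[i : i + k], set()).add(label)
    candidates = [
        (len(members), kmer) for kmer, members in kmer_members.items()
        if len(members) >= core_need
    ]
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-t[0], t[1]))
    seed = candidates[0][1]

    offsets = {
        label: seqs[label].index(seed)
        for label in sorted(kmer_members[seed])
    }
    length = k

    # --- snap: re-align every copy against an extended seed context -----
    # AT-rich motifs are repetitive, so the same k-mer can occur at
    # several positions within one motif copy; first occurrences may be
    # mutually misaligned.  A consensus over a +/- k context around the
    # seed disambiguates, and also recruits copies whose seed k-mer was
    # itself disrupted by noise.
    margin = k
    ext_cols: list[str] = []
    left_used = 0
    for i in range(-margin, k + margin):
        chars = [
            seqs[m][offsets[m] + i]
            for m in offsets
            if 0 <= offsets[m] + i < len(seqs[m])
        ]
        if len(chars) < 2:
            if i < 0:
                continue
            break
        if i < 0:
            left_used += 1
        ext_cols.append(_column_consensus(chars))
    ext_consensus = "".join(ext_cols)
    realigned: dict[str, int] = {}
    for label in sorted(seqs):
        seq = seqs[label]
        if len(seq) < len(ext_consensus):
            continue
        best_off, best_same = 0, -1
        for i in range(len(seq) - len(ext_consensus) + 1):
            same = sum(
                1
                for a, b in zip(seq[i : i + len(ext_consensus)], ext_consensus)
                if a == b
            )
            if same > best_same:
                best_off, best_same = i, same
        if 100.0 * best_same / len(ext_consensus) >= min_identity:
            realigned[label] = best_off + left_used
    if len(realigned) >= max(core_need, len(offsets)):
        offsets = realigned

    # --- greedy extension over the seed-sharing core --------------------
    # a new column is accepted only if it is itself conserved: the
    # fraction of core copies agreeing with the column consensus must
    # reach the identity threshold, which keeps the window from bleeding
    # into unconserved flanking sequence.
    def try_extend(offs: dict[str, int], length: int, left: bool, step: int):
        if left:
            new_offs = {m: o - step for m, o in offs.items() if o - step >= 0}
            new_cols = range(step)
        else:
            new_offs = {
                m: o for m, o in offs.items()
                if o + length + step <= len(seqs[m])
            }
            new_cols = range(length, length + step)
        new_len = length + step
        if len(new_offs) < core_need:
            return None
        agrees = []
        for col in new_cols:
            chars = [seqs[m][new_offs[m] + col] for m in sorted(new_offs)]
            consensus_char = _column_consensus(chars)
            agrees.append(
                sum(1 for c in chars if c == consensus_char) / len(chars)
            )
        if 100.0 * sum(agrees) / len(agrees) < min_identity:
            return None
        _, idents = _window_stats(seqs, new_offs, new_len)
        if sum(1 for v in idents.values() if v >= min_identity) < core_need:
            return None
        return new_offs, new_len

    improved = True
    while improved:
        improved = False
        for left in (True, False):
            # a single unconserved column must not truncate the motif:
            # fall back to a two-column lookahead before giving up
            out = try_extend(offsets, length, left, 1) or try_extend(
                offsets, length, left, 2
            )
            if out is not None:
                offsets, length = out
                improved = True

    if length < min_length:
        return None
    consensus, _ = _window_stats(seqs, offsets, length)

    # --- recruit every sequence against the consensus -------------------
    # copies that lack the exact seed k-mer (noise) can still carry the
    # motif; slide the consensus over each NCR and keep the best match.
    members: dict[str, int] = {}
    for label in sorted(seqs):
        seq = seqs[label]
        if len(seq) < length:
            continue
        best_off, best_same = 0, -1
        for i in range(len(seq) - length + 1):
            same = sum(
                1 for a, b in zip(seq[i : i + length], consensus) if a == b
            )
            if same > best_same:
                best_off, best_same = i, same
        if 100.0 * best_same / length >= min_identity:
            members[label] = best_off
    if len(members) < need:
        return None
    consensus, idents = _window_stats(seqs, members, length)
    members = {m: o for m, o in members.items() if idents[m] >= min_identity}
    if len(members) < need:
        return None
    consensus, idents = _window_stats(seqs, members, length)
    at, gc = composition(consensus)
    rich = "AT" if at > 50.0 else "GC"
    occurrences = tuple(
        MotifOccurrence(
            minichromosome=m, offset=members[m], identity_pct=idents[m]
        )
        for m in sorted(members)
    )
    return MotifReport(
        consensus=consensus,
        length=length,
        composition_pct=at if rich == "AT" else gc,
        rich=rich,
        position_class=position_class,
        occurrences=occurrences,
        coverage=len(members) / n,
    )
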