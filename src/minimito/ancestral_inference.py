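"""Ancestral karyotype inference by two-clause parsimony.

Karyotype structure is decomposed into *minichromosomal characters*:

* oriented adjacencies — an ordered pair of genes consecutive on one
  minichromosome, with their transcription orientations;
* co-membership blocks — an unordered set of genes on one
  minichromosome (gene pairs plus each whole observed gene complement).

Each character carries a ternary per-taxon support vector: ``present``,
``absent``, or ``missing`` when any constituent gene was not identified
in that taxon (missingness never counts as absence).

A character is inferred ancestral to a clade iff

1. it is present in at least one ingroup taxon *and* in the karyotype of
   the most recent common ancestor of the enclosing clade, or
2. it is present in every ingroup taxon in which it is scorable
   (taxa excluded for missingness do not enter the denominator; at
   least ``min_scorable`` scorable taxa are required).

Qualifying characters are assembled into maximal consistent
minichromosomes; genes supported by no qualifying character are
reported as unplaced.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .karyotype_model import (
    FORWARD,
    Gene,
    Karyotype,
    KaryotypeError,
    Minichromosome,
    REVERSE,
    TRNA_GENES,
)

__all__ = [
    "KaryotypeCharacter",
    "AncestralKaryotype",
    "AncestralConflictError",
    "extract_characters",
    "infer_ancestral",
]

PRESENT = "present"
ABSENT = "absent"
MISSING = "missing"


class AncestralConflictError(KaryotypeError):
    """Two qualifying characters place the same gene on two minichromosomes."""


def _norm_tag(tag: str, relax_variant_tags: bool) -> str:
    """Numeric paralog tags (W1/W2) always distinguish genes; opaque
    variant tags such as ``*`` are ignored when relaxed."""
    if relax_variant_tags:
        return "".join(ch for ch in tag if ch.isdigit())
    return tag


def gene_key(gene: Gene, relax_variant_tags: bool = True) -> tuple[str, str]:
    return (gene.base_name, _norm_tag(gene.paralog_tag, relax_variant_tags))


@dataclass
class KaryotypeCharacter:
    """A testable unit of karyotype structure."""

    kind: str  # "adjacency" | "block"
    genes: tuple[Gene, ...]
    support: dict[str, str] = field(default_factory=dict)

    @property
    def label(self) -> str:
        joiner = "-" if self.kind == "adjacency" else "+"
        return joiner.join(g.name for g in self.genes)

    def keys(self, relax: bool = True) -> tuple[tuple[str, str], ...]:
        return tuple(gene_key(g, relax) for g in self.genes)

    def identity(self, relax: bool = True):
        """Hashable identity used to deduplicate characters across taxa."""
        if self.kind == "adjacency":
            return (
                "adjacency",
                self.keys(relax),
                tuple(g.orientation for g in self.genes),
            )
        return ("block", frozenset(self.keys(relax)))

    def presence_count(self) -> int:
        return sum(1 for v in self.support.values() if v == PRESENT)

    def scorable_taxa(self) -> list[str]:
        return [t for t, v in self.support.items() if v != MISSING]


def _chrom_keys(chrom: Minichromosome, relax: bool) -> list[tuple[str, str]]:
    return [gene_key(g, relax) for g in chrom.genes]


def _score_block(karyotype: Karyotype, keys: frozenset, relax: bool) -> str:
    if any(base in karyotype.missing_genes for base, _ in keys):
        return MISSING
    for chrom in karyotype.minichromosomes:
        if keys <= set(_chrom_keys(chrom, relax)):
            return PRESENT
    return ABSENT


def _score_adjacency(
    karyotype: Karyotype,
    keys: Sequence[tuple[str, str]],
    orientations: Sequence[str],
    relax: bool,
) -> str:
    if any(base in karyotype.missing_genes for base, _ in keys):
        return MISSING
    want = list(zip(keys, orientations))
    for chrom in karyotype.minichromosomes:
        have = [
            (gene_key(g, relax), g.orientation) for g in chrom.genes
        ]
        for i in range(len(have) - len(want) + 1):
            if have[i : i + len(want)] == want:
                return PRESENT
    return ABSENT


def _observed_characters(
    karyotypes: Sequence[Karyotype], relax: bool
) -> list[KaryotypeCharacter]:
    """All characters observed in at least one of the given karyotypes,
    deduplicated on relaxed identity (first-seen printed form kept)."""
    chars: dict = {}

    def add(kind: str, genes: tuple[Gene, ...]) -> None:
        char = KaryotypeCharacter(kind=kind, genes=genes)
        chars.setdefault(char.identity(relax), char)

    for karyotype in karyotypes:
        for chrom in karyotype.minichromosomes:
            genes = chrom.genes
            for gene in genes:
                add("block", (gene,))
            for a, b in zip(genes, genes[1:]):
                add("adjacency", (a, b))
            for a, b in itertools.combinations(sorted(genes), 2):
                add("block", (a, b))
            if len(genes) > 2:
                add("block", tuple(sorted(genes)))
    return list(chars.values())


def _score(
    char: KaryotypeCharacter, karyotype: Karyotype, relax: bool
) -> str:
    if char.kind == "adjacency":
        return _score_adjacency(
            karyotype,
            char.keys(relax),
            [g.orientation for g in char.genes],
            relax,
        )
    return _score_block(karyotype, frozenset(char.keys(relax)), relax)


def extract_characters(
    karyotypes: Sequence[Karyotype], relax_variant_tags: bool = True
) -> list[KaryotypeCharacter]:
    """Extract all blocks and oriented adjacencies observed in >=1 taxon,
    each scored present/absent/missing against every input taxon."""
    if len(karyotypes) < 2:
        raise ValueError("need at least two karyotypes")
    chars = _observed_characters(karyotypes, relax_variant_tags)
    for char in chars:
        for karyotype in karyotypes:
            char.support[karyotype.taxon] = _score(
                char, karyotype, relax_variant_tags
            )
    key = lambda c: (c.kind, c.label)
    return sorted(chars, key=key)


@dataclass
class AncestralKaryotype:
    """Inferred ancestral karyotype for a named clade."""

    clade: str
    minichromosomes: tuple[Minichromosome, ...]
    unplaced_genes: frozenset[str]  # gene names (base + paralog tag)
    rule_trace: list[dict] = field(default_factory=list)

    @property
    def unplaced_base_names(self) -> frozenset[str]:
        from .karyotype_model import parse_gene_token

        return frozenset(
            parse_gene_token(name).base_name for name in self.unplaced_genes
        )

    def to_karyotype(self) -> Karyotype:
        """View as a Karyotype; unplaced genes become missing genes
        (their position could not be inferred)."""
        placed = {
            g.base_name
            for c in self.minichromosomes
            for g in c.genes
        }
        return Karyotype(
            taxon=self.clade,
            minichromosomes=self.minichromosomes,
            missing_genes=self.unplaced_base_names - placed,
            source="ancestral inference",
        )

    def __len__(self) -> int:
        return len(self.minichromosomes)


class _DSU:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def infer_ancestral(
    ingroup: Sequence[Karyotype],
    outgroup_mrca: Optional[Karyotype],
    clade: str = "ancestor",
    relax_variant_tags: bool = True,
    min_scorable: int = 2,
) -> AncestralKaryotype:
    """Infer the ancestral karyotype of ``clade`` from its ingroup taxa
    and the previously inferred MRCA karyotype of the enclosing clade."""
    if not ingroup:
        raise ValueError("empty ingroup")
    relax = relax_variant_tags
    n = len(ingroup)
    min_scorable = min(min_scorable, n)

    chars = _observed_characters(list(ingroup), relax)
    for char in chars:
        for karyotype in ingroup:
            char.support[karyotype.taxon] = _score(char, karyotype, relax)

    mrca_present: dict = {}
    for char in chars:
        if outgroup_mrca is None:
            mrca_present[id(char)] = False
        else:
            mrca_present[id(char)] = (
                _score(char, outgroup_mrca, relax) == PRESENT
            )

    trace: list[dict] = []
    qualifying: list[KaryotypeCharacter] = []
    for char in chars:
        present = char.presence_count()
        scorable = char.scorable_taxa()
        clause1 = present >= 1 and mrca_present[id(char)]
        clause2 = (
            present >= 1
            and len(scorable) >= min_scorable
            and all(char.support[t] == PRESENT for t in scorable)
        )
        if clause1 or clause2:
            qualifying.append(char)
            trace.append(
                {
                    "character": char.label,
                    "kind": char.kind,
                    "clause": 1 if clause1 else 2,
                    "clauses": [c for c, ok in ((1, clause1), (2, clause2)) if ok],
                    "present_in": [
                        t for t, v in char.support.items() if v == PRESENT
                    ],
                    "in_outgroup_mrca": mrca_present[id(char)],
                }
            )

    # --- gene universe and representative printed forms -----------------
    sources = list(ingroup) + ([outgroup_mrca] if outgroup_mrca else [])
    rep: dict[tuple[str, str], Gene] = {}
    # prefer the outgroup MRCA's printed form (tags, orientation), then
    # first ingroup occurrence
    ordered = ([outgroup_mrca] if outgroup_mrca else []) + list(ingroup)
    for karyotype in ordered:
        for chrom in karyotype.minichromosomes:
            for gene in chrom.genes:
                rep.setdefault(gene_key(gene, relax), gene)
    universe = set(rep)

    # --- anchor genes qualify by their singleton (presence) character ---
    def singleton_qualifies(key) -> Optional[int]:
        base = key[0]
        present_in = [
            k.taxon
            for k in ingroup
            if key in {gene_key(g, relax) for c in k.minichromosomes for g in c.genes}
        ]
        missing_in = [k.taxon for k in ingroup if base in k.missing_genes]
        scorable = [k.taxon for k in ingroup if k.taxon not in missing_in]
        in_mrca = bool(outgroup_mrca) and key in {
            gene_key(g, relax)
            for c in outgroup_mrca.minichromosomes
            for g in c.genes
        }
        if present_in and in_mrca:
            return 1
        if (
            present_in
            and len(scorable) >= min_scorable
            and all(t in present_in for t in scorable)
        ):
            return 2
        return None

    anchors = {k for k in universe if k[0] not in TRNA_GENES}
    placed_anchors = {k for k in anchors if singleton_qualifies(k) is not None}

    # --- assemble: union-find over qualifying multi-gene characters -----
    multi = [c for c in qualifying if len(c.genes) >= 2]
    multi.sort(key=lambda c: (-c.presence_count(), c.kind, c.label))

    # anchor pairs sanctioned to share a minichromosome
    sanctioned: set[frozenset] = set()
    for char in multi:
        keys = char.keys(relax)
        anchor_keys = [k for k in keys if k in placed_anchors]
        for a, b in itertools.combinations(anchor_keys, 2):
            sanctioned.add(frozenset((a, b)))

    dsu = _DSU()
    for k in placed_anchors:
        dsu.find(k)
    comp_anchors: dict = {dsu.find(k): {k} for k in placed_anchors}
    placed_by: dict[tuple[str, str], int] = {}  # key -> presence count of placing char
    contested: set = set()

    def component_anchors(root) -> set:
        return comp_anchors.get(root, set())

    for char in multi:
        keys = [k for k in char.keys(relax) if k[0] in TRNA_GENES or k in placed_anchors]
        if any(
            k[0] not in TRNA_GENES and k not in placed_anchors
            for k in char.keys(relax)
        ):
            # involves an anchor that did not itself qualify (e.g. nad6):
            # cannot be used for placement
            continue
        if len(keys) < 2:
            continue
        roots = {dsu.find(k) for k in keys}
        merged_anchors = set().union(*(component_anchors(r) for r in roots))
        ok = all(
            frozenset((a, b)) in sanctioned
            for a, b in itertools.combinations(sorted(merged_anchors), 2)
        )
        if not ok:
            # conflicting placement; the earlier (higher-presence) winner
            # stands, equal-presence ties leave the tRNA unplaced
            for k in keys:
                if k in placed_by and placed_by[k] == char.presence_count():
                    contested.add(k)
            trace.append(
                {
                    "character": char.label,
                    "kind": char.kind,
                    "conflict": True,
                    "note": "placement skipped: would join distinct anchors",
                }
            )
            continue
        first = keys[0]
        for k in keys[1:]:
            dsu.union(first, k)
        root = dsu.find(first)
        merged = set()
        for r in roots:
            merged |= comp_anchors.pop(r, set())
        comp_anchors[root] = merged
        for k in keys:
            placed_by.setdefault(k, char.presence_count())

    # collect components
    components: dict = {}
    for k in set(dsu.parent) | placed_anchors:
        if k in contested and k not in placed_anchors:
            continue
        components.setdefault(dsu.find(k), set()).add(k)
    # drop tRNA-only components not sanctioned as chromosomes of their own
    # (a component must contain a placed anchor or arise from a qualifying
    # whole-chromosome block)
    final_components = [
        comp
        for comp in components.values()
        if comp & placed_anchors or len(comp) >= 2
    ]

    # --- order genes within each component ------------------------------
    adjacency_chars = [c for c in qualifying if c.kind == "adjacency"]

    def order_component(comp: set) -> tuple[Gene, ...]:
        # follow the outgroup MRCA where a single MRCA minichromosome
        # contains the whole component
        if outgroup_mrca is not None:
            for chrom in outgroup_mrca.minichromosomes:
                keys = _chrom_keys(chrom, relax)
                if comp <= set(keys):
                    return tuple(
                        g for g in chrom.genes if gene_key(g, relax) in comp
                    )
        # otherwise follow the first ingroup minichromosome containing it
        for karyotype in ingroup:
            for chrom in karyotype.minichromosomes:
                keys = _chrom_keys(chrom, relax)
                if comp <= set(keys):
                    return tuple(
                        g for g in chrom.genes if gene_key(g, relax) in comp
                    )
        # fallback: chain qualifying adjacencies (partial order)
        succ: dict = {}
        for char in adjacency_chars:
            k = char.keys(relax)
            if set(k) <= comp:
                succ[k[0]] = k[1]
        start = next(
            (k for k in comp if k not in set(succ.values())), None
        )
        chain = []
        while start is not None and start not in chain:
            chain.append(start)
            start = succ.get(start)
        rest = sorted(comp - set(chain))
        return tuple(rep[k] for k in chain + rest)

    chroms = tuple(
        sorted(
            (Minichromosome(genes=order_component(c)) for c in final_components),
            key=lambda m: m.label,
        )
    )

    placed_keys = {gene_key(g, relax) for c in chroms for g in c.genes}
    unplaced = frozenset(
        rep[k].name for k in universe - placed_keys
    )

    result = AncestralKaryotype(
        clade=clade,
        minichromosomes=chroms,
        unplaced_genes=unplaced,
        rule_trace=trace,
    )
    # integrity: no gene on two inferred minichromosomes
    seen = set()
    for chrom in chroms:
        for gene in chrom.genes:
            k = gene_key(gene, relax)
            if k in seen:
                raise AncestralConflictError(
                    f"gene {gene.name} placed on two inferred minichromosomes"
                )
            seen.add(k)
    return result
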