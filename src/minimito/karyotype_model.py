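"""Data model for fragmented mitochondrial genomes.

A *minichromosome* is a small circular chromosome carrying an ordered,
oriented subset of the 37 canonical animal mitochondrial genes plus
flanking non-coding sequence.  A *karyotype* is the full complement of
minichromosomes of one taxon together with an explicit record of genes
that were not identified for that taxon.

The module also defines a plain-text karyotype format (one taxon per
file) with a parser and writer:

    #taxon lepidophthirus_macrorhini
    #missing nad3 nad4L nad6 C F G R S1 S2 Y
    atp8-atp6-N
    Q!-nad1!-T*!-W1
    ...

Genes on a minichromosome line are hyphen-separated in coding order
(upstream to downstream relative to the non-coding region).  A ``!``
suffix marks reverse transcription orientation; any trailing digits or
``*`` after the base gene name are kept verbatim as a paralog/variant
tag (``W1``, ``W2``, ``T*``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

__all__ = [
    "GENE_VOCABULARY",
    "PROTEIN_GENES",
    "RRNA_GENES",
    "TRNA_GENES",
    "Gene",
    "Minichromosome",
    "Karyotype",
    "KaryotypeDiff",
    "KaryotypeError",
    "KaryotypeFormatError",
    "KaryotypeIntegrityError",
    "parse_gene_token",
    "parse_karyotype",
    "write_karyotype",
    "karyotype_equal",
]

PROTEIN_GENES = frozenset(
    {
        "atp6",
        "atp8",
        "cob",
        "cox1",
        "cox2",
        "cox3",
        "nad1",
        "nad2",
        "nad3",
        "nad4",
        "nad4L",
        "nad5",
        "nad6",
    }
)
RRNA_GENES = frozenset({"rrnS", "rrnL"})
TRNA_GENES = frozenset(
    {
        "A",
        "C",
        "D",
        "E",
        "F",
        "G",
        "H",
        "I",
        "K",
        "L1",
        "L2",
        "M",
        "N",
        "P",
        "Q",
        "R",
        "S1",
        "S2",
        "T",
        "V",
        "W",
        "Y",
    }
)

#: The 37-gene vocabulary of bilaterian mitochondrial genomes.
GENE_VOCABULARY = PROTEIN_GENES | RRNA_GENES | TRNA_GENES

# Longest-first so that e.g. "nad4L" wins over "nad4" and "L1" over "L".
_VOCAB_BY_LENGTH = sorted(GENE_VOCABULARY, key=len, reverse=True)

FORWARD = "forward"
REVERSE = "reverse"

_TAG_CHARS = set("0123456789*")


class KaryotypeError(Exception):
    """Base class for karyotype model errors."""


class KaryotypeFormatError(KaryotypeError):
    """Raised when karyotype text cannot be parsed."""


class KaryotypeIntegrityError(KaryotypeError):
    """Raised when a karyotype violates a structural invariant."""


@dataclass(frozen=True, order=True)
class Gene:
    """A single mitochondrial gene occurrence.

    Equality is sensitive to ``base_name``, ``paralog_tag`` and
    ``orientation``.  Relaxed comparison (e.g. ignoring a ``*`` variant
    tag) is the business of character extraction, not of this type.
    """

    base_name: str
    paralog_tag: str = ""
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if self.base_name not in GENE_VOCABULARY:
            raise KaryotypeIntegrityError(
                f"unknown gene base name {self.base_name!r}"
            )
        if self.orientation not in (FORWARD, REVERSE):
            raise KaryotypeIntegrityError(
                f"bad orientation {self.orientation!r}"
            )
        if not set(self.paralog_tag) <= _TAG_CHARS:
            raise KaryotypeIntegrityError(
                f"bad paralog tag {self.paralog_tag!r}"
            )

    @property
    def category(self) -> str:
        if self.base_name in PROTEIN_GENES:
            return "protein"
        if self.base_name in RRNA_GENES:
            return "rRNA"
        return "tRNA"

    @property
    def is_anchor(self) -> bool:
        """Protein-coding and rRNA genes anchor rearrangement events."""
        return self.base_name not in TRNA_GENES

    @property
    def name(self) -> str:
        """Base name plus paralog tag, e.g. ``W1`` or ``T*``."""
        return self.base_name + self.paralog_tag

    @property
    def token(self) -> str:
        """Text-format token, with ``!`` appended for reverse genes."""
        return self.name + ("!" if self.orientation == REVERSE else "")

    def reversed_copy(self) -> "Gene":
        flip = REVERSE if self.orientation == FORWARD else FORWARD
        return replace(self, orientation=flip)


def parse_gene_token(token: str) -> Gene:
    """Parse one text-format token (``nad4L``, ``W1``, ``T*!``)."""
    raw = token
    orientation = FORWARD
    if token.endswith("!"):
        orientation = REVERSE
        token = token[:-1]
    base = next((v for v in _VOCAB_BY_LENGTH if token.startswith(v)), None)
    if base is None:
        raise KaryotypeFormatError(f"unknown gene token {raw!r}")
    tag = token[len(base) :]
    if tag and not set(tag) <= _TAG_CHARS:
        raise KaryotypeFormatError(f"unknown gene token {raw!r}")
    return Gene(base_name=base, paralog_tag=tag, orientation=orientation)


@dataclass(frozen=True)
class Minichromosome:
    """An ordered, oriented gene list plus optional flanking NCR sequence.

    ``genes`` run in coding order from the upstream (AT-motif) end.
    """

    genes: tuple[Gene, ...]
    ncr_upstream: Optional[str] = None
    ncr_downstream: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise KaryotypeIntegrityError("minichromosome with no genes")

    @property
    def label(self) -> str:
        """Canonical hyphen-joined name, e.g. ``Q-nad1-T*-W1``."""
        return "-".join(g.name for g in self.genes)

    @property
    def token_label(self) -> str:
        """Label including ``!`` reverse-orientation markers."""
        return "-".join(g.token for g in self.genes)

    @property
    def anchors(self) -> tuple[Gene, ...]:
        return tuple(g for g in self.genes if g.is_anchor)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_label(cls, label: str, **kwargs) -> "Minichromosome":
        tokens = label.split("-")
        if any(not t for t in tokens):
            raise KaryotypeFormatError(f"empty gene token in {label!r}")
        return cls(genes=tuple(parse_gene_token(t) for t in tokens), **kwargs)


@dataclass(frozen=True)
class Karyotype:
    """The set of minichromosomes of one taxon.

    ``missing_genes`` is first-class data: the base names of genes that
    were *not identified* for this taxon.  Absence from
    ``missing_genes`` and from the minichromosomes means the gene is
    positively absent, which is a different statement.
    """

    taxon: str
    minichromosomes: tuple[Minichromosome, ...]
    missing_genes: frozenset[str] = frozenset()
    source: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for chrom in self.minichromosomes:
            for gene in chrom.genes:
                key = (gene.base_name, gene.paralog_tag)
                if key in seen:
                    raise KaryotypeIntegrityError(
                        f"{self.taxon}: gene {gene.name} appears on both "
                        f"{seen[key]!r} and {chrom.label!r}"
                    )
                seen[key] = chrom.label
        bad = self.missing_genes - GENE_VOCABULARY
        if bad:
            raise KaryotypeIntegrityError(
                f"{self.taxon}: unknown missing genes {sorted(bad)}"
            )
        overlap = self.missing_genes & self.present_base_names
        if overlap:
            raise KaryotypeIntegrityError(
                f"{self.taxon}: genes both present and missing: "
                f"{sorted(overlap)}"
            )

    @property
    def present_base_names(self) -> frozenset[str]:
        return frozenset(
            g.base_name for c in self.minichromosomes for g in c.genes
        )

    @property
    def gene_count(self) -> int:
        """Number of distinct identified genes (paralogs count once)."""
        return len(self.present_base_names)

    def sorted_minichromosomes(self) -> tuple[Minichromosome, ...]:
        return tuple(sorted(self.minichromosomes, key=lambda c: c.label))

    def find(self, base_name: str, paralog_tag: str = "") -> Optional[Minichromosome]:
        for chrom in self.minichromosomes:
            for gene in chrom.genes:
                if (gene.base_name, gene.paralog_tag) == (base_name, paralog_tag):
                    return chrom
        return None

    def __iter__(self) -> Iterator[Minichromosome]:
        return iter(self.sorted_minichromosomes())

    def __len__(self) -> int:
        return len(self.minichromosomes)


def parse_karyotype(text: str) -> Karyotype:
    """Parse the karyotype text format into a :class:`Karyotype`."""
    taxon = ""
    missing: set[str] = set()
    source = ""
    chroms: list[Minichromosome] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#taxon"):
            taxon = line[len("#taxon") :].strip()
            continue
        if line.startswith("#missing"):
            for name in line[len("#missing") :].split():
                if name not in GENE_VOCABULARY:
                    raise KaryotypeFormatError(
                        f"line {lineno}: unknown gene token {name!r}"
                    )
                missing.add(name)
            continue
        if line.startswith("#source"):
            source = line[len("#source") :].strip()
            continue
        if line.startswith("#"):
            continue  # plain comment
        tokens = line.split("-")
        if any(not t.strip() for t in tokens):
            raise KaryotypeFormatError(
                f"line {lineno}: empty gene token in {line!r}"
            )
        genes = []
        for tok in tokens:
            try:
                genes.append(parse_gene_token(tok.strip()))
            except KaryotypeFormatError as exc:
                raise KaryotypeFormatError(f"line {lineno}: {exc}") from None
        chroms.append(Minichromosome(genes=tuple(genes)))
    return Karyotype(
        taxon=taxon,
        minichromosomes=tuple(chroms),
        missing_genes=frozenset(missing),
        source=source,
    )


def write_karyotype(karyotype: Karyotype) -> str:
    """Serialise a karyotype deterministically (lexicographic by label)."""
    lines = []
    if karyotype.taxon:
        lines.append(f"#taxon {karyotype.taxon}")
    if karyotype.missing_genes:
        lines.append("#missing " + " ".join(sorted(karyotype.missing_genes)))
    if karyotype.source:
        lines.append(f"#source {karyotype.source}")
    for chrom in karyotype.sorted_minichromosomes():
        lines.append(chrom.token_label)
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class KaryotypeDiff:
    """Difference report produced by :func:`karyotype_equal`."""

    equal: bool
    only_in_a: tuple[str, ...]
    only_in_b: tuple[str, ...]
    missing_only_in_a: tuple[str, ...]
    missing_only_in_b: tuple[str, ...]

    def __bool__(self) -> bool:
        return self.equal


def karyotype_equal(a: Karyotype, b: Karyotype) -> KaryotypeDiff:
    """Compare two karyotypes by their canonical minichromosome labels.

    Equality requires identical multisets of oriented labels; missing
    genes are compared separately and reported, not folded into the
    verdict.
    """
    from collections import Counter

    ca = Counter(c.token_label for c in a.minichromosomes)
    cb = Counter(c.token_label for c in b.minichromosomes)
    only_a = sorted((ca - cb).elements())
    only_b = sorted((cb - ca).elements())
    return KaryotypeDiff(
        equal=not only_a and not only_b,
        only_in_a=tuple(only_a),
        only_in_b=tuple(only_b),
        missing_only_in_a=tuple(sorted(a.missing_genes - b.missing_genes)),
        missing_only_in_b=tuple(sorted(b.missing_genes - a.missing_genes)),
    )
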