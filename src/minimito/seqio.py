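"""FASTA / GenBank flat-file readers.

GenBank records of annotated minichromosomes are converted to
:class:`Minichromosome` objects: genes come from the feature table (no
de-novo annotation), and the sequence outside the first/last gene
feature populates the upstream/downstream non-coding regions.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from Bio import SeqIO

from .karyotype_model import (
    GENE_VOCABULARY,
    Gene,
    KaryotypeFormatError,
    Minichromosome,
    parse_gene_token,
)

__all__ = [
    "read_fasta",
    "read_ncr_fasta",
    "map_feature_gene",
    "genbank_minichromosome",
    "genbank_gene_sequences",
]

# common GenBank spellings -> vocabulary base names
_ALIASES = {
    "ATP6": "atp6",
    "ATP8": "atp8",
    "COB": "cob",
    "CYTB": "cob",
    "COX1": "cox1",
    "COI": "cox1",
    "COX2": "cox2",
    "COII": "cox2",
    "COX3": "cox3",
    "COIII": "cox3",
    "ND1": "nad1",
    "ND2": "nad2",
    "ND3": "nad3",
    "ND4": "nad4",
    "ND4L": "nad4L",
    "ND5": "nad5",
    "ND6": "nad6",
    "12S": "rrnS",
    "S-RRNA": "rrnS",
    "RRNS": "rrnS",
    "16S": "rrnL",
    "L-RRNA": "rrnL",
    "RRNL": "rrnL",
}


def read_fasta(path) -> dict[str, str]:
    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


def read_ncr_fasta(path, position_class: str = "upstream") -> dict[str, str]:
    """Read NCR windows whose record IDs are ``<label>|up`` or
    ``<label>|down``; returns the requested class keyed by label."""
    suffix = "|up" if position_class == "upstream" else "|down"
    out = {}
    for rid, seq in read_fasta(path).items():
        if rid.endswith(suffix):
            out[rid[: -len(suffix)]] = seq
    return out


def map_feature_gene(name: str) -> str:
    """Map a GenBank gene/product spelling to a vocabulary token."""
    raw = name.strip()
    if raw in GENE_VOCABULARY:
        return raw
    upper = raw.upper()
    if upper in _ALIASES:
        return _ALIASES[upper]
    if upper.startswith("TRN"):
        rest = raw[3:]
        if rest in GENE_VOCABULARY:
            return rest
        if rest.upper() in GENE_VOCABULARY:
            return rest.upper()
        # keep paralog tags, e.g. trnW1
        base = rest.rstrip("0123456789*")
        tag = rest[len(base) :]
        if base.upper() in GENE_VOCABULARY:
            return base.upper() + tag
    if raw.lower() in {g.lower(): g for g in GENE_VOCABULARY}:
        return {g.lower(): g for g in GENE_VOCABULARY}[raw.lower()]
    raise KaryotypeFormatError(f"unrecognised gene name {name!r}")


def _gene_features(record):
    for feature in record.features:
        if feature.type not in {"gene", "CDS", "tRNA", "rRNA"}:
            continue
        quals = feature.qualifiers
        name = (quals.get("gene") or quals.get("product") or [None])[0]
        if name is None:
            continue
        yield feature, map_feature_gene(name)


def genbank_minichromosome(record) -> Minichromosome:
    """Build a Minichromosome from one annotated GenBank record."""
    seen: dict[tuple[int, int], tuple] = {}
    for feature, token in _gene_features(record):
        start = int(feature.location.start)
        end = int(feature.location.end)
        strand = feature.location.strand
        key = (start, end)
        if key not in seen:
            seen[key] = (start, end, strand, token)
    if not seen:
        raise KaryotypeFormatError(
            f"record {record.id}: no gene features"
        )
    ordered = sorted(seen.values())
    genes = []
    for start, end, strand, token in ordered:
        gene = parse_gene_token(token)
        if strand == -1:
            gene = gene.reversed_copy()
        genes.append(gene)
    first = ordered[0][0]
    last = ordered[-1][1]
    seq = str(record.seq).upper()
    return Minichromosome(
        genes=tuple(genes),
        ncr_upstream=seq[:first] or None,
        ncr_downstream=seq[last:] or None,
    )


def genbank_gene_sequences(records: Iterable) -> dict[str, str]:
    """Extract per-gene nucleotide sequences from GenBank records."""
    out: dict[str, str] = {}
    for record in records:
        seq = str(record.seq).upper()
        for feature, token in _gene_features(record):
            sub = str(feature.extract(record.seq)).upper()
            out.setdefault(token, sub)
    return out
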