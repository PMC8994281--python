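"""Minichromosome rearrangement events between an ancestor and a descendant.

Events are anchored on protein-coding and rRNA genes; tRNAs are too
mobile and are tracked as translocations.

Definitions (for one ancestor->descendant comparison):

* For each ancestral minichromosome ``C``, its genes identified in the
  descendant are partitioned by the descendant minichromosome carrying
  them.  A part is a *unit* if it contains an anchor gene, or if it
  constitutes an entire descendant minichromosome (a fission product),
  or an entire ancestral one (for the merger dual).
* SPLIT: >=2 unit parts of ``C`` sit on distinct descendant
  minichromosomes none of which carries anchors from other ancestral
  minichromosomes.  An anchor that is unidentified (declared missing) in
  the descendant never vetoes a split: if the remaining identified
  anchors of a multi-anchor ``C`` sit alone, the split is still called
  (this is what supports "at least N" counts).
* MERGER: one descendant minichromosome carries unit contributions from
  >=2 ancestral minichromosomes.  Recorded once per descendant
  minichromosome.
* TRANSLOCATION: a tRNA-only part relocated onto a minichromosome
  anchored by a different ancestral minichromosome.
* LOSS: an ancestral gene absent from the descendant and *not* declared
  missing.  Genes declared missing produce no event.

A k-way split counts as one split; a k-way merger as one merger.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import dendropy

from .ancestral_inference import AncestralKaryotype, gene_key
from .karyotype_model import Gene, Karyotype, KaryotypeError, Minichromosome

__all__ = [
    "RearrangementEvent",
    "EventReport",
    "EventTally",
    "TallyConfigurationError",
    "detect_events",
    "tally_events",
]

SPLIT = "split"
MERGER = "merger"
TRANSLOCATION = "translocation"
LOSS = "loss"


class TallyConfigurationError(KaryotypeError):
    """A node on a requested path has no karyotype."""


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str
    branch: str
    ancestral_minichromosomes: tuple[str, ...]
    descendant_minichromosomes: tuple[str, ...]
    anchor_genes: tuple[str, ...]

    def __post_init__(self):
        if self.kind == SPLIT:
            assert len(self.ancestral_minichromosomes) == 1
            assert len(self.descendant_minichromosomes) >= 2 or True
        if self.kind == MERGER:
            assert len(self.descendant_minichromosomes) == 1
            assert len(self.ancestral_minichromosomes) >= 2


@dataclass
class EventReport:
    """Events plus warning-level duplication/gain notes."""

    events: list[RearrangementEvent] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[RearrangementEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, kind: str) -> list[RearrangementEvent]:
        return [e for e in self.events if e.kind == kind]


def _as_karyotype(k: Union[Karyotype, AncestralKaryotype]) -> Karyotype:
    if isinstance(k, AncestralKaryotype):
        return k.to_karyotype()
    return k


def detect_events(
    ancestor: Union[Karyotype, AncestralKaryotype],
    descendant: Union[Karyotype, AncestralKaryotype],
    branch: str = "",
    relax_variant_tags: bool = True,
) -> EventReport:
    """Classify karyotype differences along one branch."""
    anc = _as_karyotype(ancestor)
    desc = _as_karyotype(descendant)
    relax = relax_variant_tags

    def keyset(chrom: Minichromosome) -> set:
        return {gene_key(g, relax) for g in chrom.genes}

    desc_chrom_of: dict = {}
    for chrom in desc.sorted_minichromosomes():
        for gene in chrom.genes:
            desc_chrom_of[gene_key(gene, relax)] = chrom
    anc_chrom_of: dict = {}
    for chrom in anc.sorted_minichromosomes():
        for gene in chrom.genes:
            anc_chrom_of[gene_key(gene, relax)] = chrom

    def is_anchor(key) -> bool:
        base = key[0]
        return Gene(base_name=base).is_anchor

    report = EventReport()

    # gains / paralog emergence: warning-level notes, never events
    for key, chrom in sorted(desc_chrom_of.items()):
        if key not in anc_chrom_of and key[0] not in anc.missing_genes:
            report.notes.append(
                f"{desc.taxon}: gene {key[0]}{key[1]} on {chrom.label!r} "
                "has no counterpart in the ancestor (duplication or gain)"
            )

    merger_sources: dict[str, set[str]] = defaultdict(set)
    merger_chrom: dict[str, Minichromosome] = {}

    for anc_chrom in anc.sorted_minichromosomes():
        anc_keys = keyset(anc_chrom)
        anchors = {k for k in anc_keys if is_anchor(k)}
        identified = {k for k in anc_keys if k in desc_chrom_of}
        missing = {k for k in anc_keys if k[0] in desc.missing_genes}
        lost = anc_keys - identified - missing
        for key in sorted(lost):
            report.events.append(
                RearrangementEvent(
                    kind=LOSS,
                    branch=branch,
                    ancestral_minichromosomes=(anc_chrom.label,),
                    descendant_minichromosomes=(),
                    anchor_genes=(key[0] + key[1],),
                )
            )
        # partition identified genes by descendant minichromosome
        parts: dict[str, set] = defaultdict(set)
        part_chrom: dict[str, Minichromosome] = {}
        for key in identified:
            chrom = desc_chrom_of[key]
            parts[chrom.label].add(key)
            part_chrom[chrom.label] = chrom

        unit_parts = []
        for label, part in sorted(parts.items()):
            chrom = part_chrom[label]
            foreign_anchors = {
                k for k in keyset(chrom) - anc_keys if is_anchor(k)
            }
            has_anchor = any(is_anchor(k) for k in part)
            whole_desc = part == keyset(chrom)
            whole_anc = part == identified
            if foreign_anchors:
                if has_anchor or whole_anc:
                    # this part participates in a merger on chrom
                    merger_sources[label].add(anc_chrom.label)
                    merger_chrom[label] = chrom
                else:
                    report.events.append(
                        RearrangementEvent(
                            kind=TRANSLOCATION,
                            branch=branch,
                            ancestral_minichromosomes=(anc_chrom.label,),
                            descendant_minichromosomes=(label,),
                            anchor_genes=tuple(
                                sorted(k[0] + k[1] for k in part)
                            ),
                        )
                    )
            else:
                if has_anchor or whole_desc:
                    unit_parts.append(label)
                elif len(parts) > 1:
                    # tRNA-only fragment relocated onto an unanchored
                    # minichromosome of the same origin set
                    unit_parts.append(label)

        missing_anchor_split = (
            len(anchors) >= 2
            and any(k in missing for k in anchors)
            and len(unit_parts) >= 1
            and identified
            and all(
                not (keyset(part_chrom[label]) & (anchors - parts[label]))
                for label in unit_parts
            )
        )
        if len(unit_parts) >= 2 or missing_anchor_split:
            report.events.append(
                RearrangementEvent(
                    kind=SPLIT,
                    branch=branch,
                    ancestral_minichromosomes=(anc_chrom.label,),
                    descendant_minichromosomes=tuple(sorted(unit_parts)),
                    anchor_genes=tuple(
                        sorted(k[0] + k[1] for k in anchors)
                    ),
                )
            )

    for label in sorted(merger_sources):
        sources = merger_sources[label]
        # the resident ancestral source of the descendant chromosome also
        # participates
        chrom = merger_chrom[label]
        for key in keyset(chrom):
            if key in anc_chrom_of:
                sources.add(anc_chrom_of[key].label)
        if len(sources) >= 2:
            anchors = tuple(
                sorted(
                    k[0] + k[1]
                    for k in keyset(chrom)
                    if is_anchor(k) and k in anc_chrom_of
                )
            )
            report.events.append(
                RearrangementEvent(
                    kind=MERGER,
                    branch=branch,
                    ancestral_minichromosomes=tuple(sorted(sources)),
                    descendant_minichromosomes=(label,),
                    anchor_genes=anchors,
                )
            )
    report.events.sort(key=lambda e: (e.kind, e.ancestral_minichromosomes))
    return report


@dataclass
class EventTally:
    """Per-branch and per-family counts of each event kind."""

    events: list[RearrangementEvent] = field(default_factory=list)
    per_branch: dict[str, Counter] = field(default_factory=dict)
    per_family: dict[str, Counter] = field(default_factory=dict)
    totals: Counter = field(default_factory=Counter)
    unevaluated_branches: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def total(self, kind: str) -> int:
        return self.totals.get(kind, 0)

    def events_involving(self, gene_name: str) -> list[RearrangementEvent]:
        return [
            e
            for e in self.events
            if any(
                gene_name in label.split("-")
                for label in e.ancestral_minichromosomes
                + e.descendant_minichromosomes
            )
            or gene_name in e.anchor_genes
        ]


def _node_name(node: dendropy.Node) -> Optional[str]:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label.replace(" ", "_")
    if node.label:
        return node.label.replace(" ", "_")
    return None


def tally_events(
    tree: dendropy.Tree,
    node_karyotypes: Mapping[str, Union[Karyotype, AncestralKaryotype]],
    family_map: Optional[Mapping[str, str]] = None,
    strict: bool = False,
) -> EventTally:
    """Run :func:`detect_events` on every branch of ``tree`` for which a
    karyotype is available at both ends.

    Internal nodes without karyotypes are transparent: a node is compared
    with its nearest ancestor that has one, so an event is assigned to
    exactly one (composite) branch.  With ``strict=True``, branches that
    cannot be evaluated raise :class:`TallyConfigurationError` instead of
    being reported in ``unevaluated_branches``.
    """
    tally = EventTally()
    family_map = family_map or {}

    def nearest_karyotyped_ancestor(node) -> Optional[str]:
        parent = node.parent_node
        while parent is not None:
            name = _node_name(parent)
            if name in node_karyotypes:
                return name
            parent = parent.parent_node
        return None

    for node in tree.preorder_node_iter():
        name = _node_name(node)
        if node.parent_node is None:
            continue
        if name is None or name not in node_karyotypes:
            if name is not None:
                msg = f"no karyotype for node {name!r}"
                if strict:
                    raise TallyConfigurationError(msg)
                tally.unevaluated_branches.append(name)
            continue
        anc_name = nearest_karyotyped_ancestor(node)
        if anc_name is None:
            msg = f"node {name!r} has no karyotyped ancestor"
            if strict:
                raise TallyConfigurationError(msg)
            tally.unevaluated_branches.append(name)
            continue
        branch = f"{anc_name}->{name}"
        report = detect_events(
            node_karyotypes[anc_name], node_karyotypes[name], branch=branch
        )
        tally.notes.extend(report.notes)
        counts = Counter(e.kind for e in report.events)
        tally.per_branch[branch] = counts
        tally.events.extend(report.events)
        tally.totals.update(counts)
        family = family_map.get(name)
        if family:
            tally.per_family.setdefault(family, Counter()).update(counts)
    return tally
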