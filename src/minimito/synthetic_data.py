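"""Ground-truthed simulator for karyotype and sequence evolution.

Karyotypes evolve along a rooted tree by Poisson-distributed split,
merger, tRNA-translocation and loss events; sequences diverge by a
single-parameter (Jukes-Cantor-like) substitution process; non-coding
regions are random with a planted motif of configurable length,
composition and per-copy noise.  Every simulation returns a
:class:`GroundTruth` whose event log replays exactly from the root to
each tip.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .karyotype_model import (
    Gene,
    Karyotype,
    Minichromosome,
    TRNA_GENES,
)

__all__ = [
    "MotifSpec",
    "SimulationConfig",
    "GroundTruth",
    "SimulationConfigError",
    "simulate_karyotypes",
    "replay_events",
    "simulate_gene_sequences",
    "plant_motif_ncrs",
    "simulate_sequences",
    "mutate_sequence",
    "mask_missing",
    "random_sequence",
]

BASES = "ACGT"


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MotifSpec:
    length: int = 56
    at_fraction: float = 0.85
    noise: float = 0.05  # per-site corruption probability per copy
    ncr_length: int = 300
    offset: Optional[int] = None  # fixed plant position; random if None


@dataclass
class SimulationConfig:
    tree: dendropy.Tree
    root_karyotype: Karyotype
    split_rate: float = 0.0  # expected events per branch
    merge_rate: float = 0.0
    trna_translocation_rate: float = 0.0
    loss_rate: float = 0.0
    substitution_rate: float = 0.0  # per site per unit branch length
    motif_spec: MotifSpec = field(default_factory=MotifSpec)
    anchor_split_bias: float = 1.0  # prob. of preferring anchor-balanced cuts
    rng_seed: int = 0

    def __post_init__(self):
        rates = (
            self.split_rate,
            self.merge_rate,
            self.trna_translocation_rate,
            self.loss_rate,
            self.substitution_rate,
        )
        if any(r < 0 for r in rates):
            raise SimulationConfigError("rates must be non-negative")
        if (
            self.merge_rate > 0
            and len(self.root_karyotype.minichromosomes) < 2
        ):
            raise SimulationConfigError(
                "merge_rate > 0 requires >=2 root minichromosomes"
            )


@dataclass
class GroundTruth:
    """Event log, true node karyotypes and planted-motif positions."""

    events: list[dict] = field(default_factory=list)
    node_karyotypes: dict[str, Karyotype] = field(default_factory=dict)
    motif_positions: dict[str, int] = field(default_factory=dict)
    motif_consensus: str = ""
    seed: int = 0

    def events_on(self, branch: str) -> list[dict]:
        return [e for e in self.events if e["branch"] == branch]


def _node_name(node: dendropy.Node, counter: list[int]) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label.replace(" ", "_")
    if node.label:
        return node.label.replace(" ", "_")
    counter[0] += 1
    name = f"node{counter[0]}"
    node.label = name
    return name


def _chrom_list(karyotype: Karyotype) -> list[tuple[Gene, ...]]:
    return [c.genes for c in karyotype.sorted_minichromosomes()]


def _to_karyotype(taxon: str, chroms: Sequence[tuple[Gene, ...]]) -> Karyotype:
    return Karyotype(
        taxon=taxon,
        minichromosomes=tuple(Minichromosome(genes=g) for g in chroms),
        source="simulated",
    )


def _label(genes: Sequence[Gene]) -> str:
    return "-".join(g.name for g in genes)


def _apply_event(chroms: list, event: dict) -> None:
    """Apply one logged event in place.  Chromosomes are addressed by
    label so that replay is independent of list bookkeeping."""
    labels = [_label(g) for g in chroms]
    kind = event["kind"]
    if kind == "split":
        i = labels.index(event["chromosome"])
        genes = chroms.pop(i)
        cut = event["cut"]
        chroms.append(genes[:cut])
        chroms.append(genes[cut:])
    elif kind == "merger":
        i = labels.index(event["first"])
        j = labels.index(event["second"])
        merged = chroms[i] + chroms[j]
        for idx in sorted((i, j), reverse=True):
            chroms.pop(idx)
        chroms.append(merged)
    elif kind == "translocation":
        i = labels.index(event["source"])
        j = labels.index(event["target"])
        genes = list(chroms[i])
        gene = next(
            g for g in genes if g.name == event["gene"]
        )
        genes.remove(gene)
        target = list(chroms[j])
        target.insert(event["position"], gene)
        chroms[i] = tuple(genes)
        chroms[j] = tuple(target)
        if not chroms[i]:
            chroms.pop(i)
    elif kind == "loss":
        i = labels.index(event["chromosome"])
        genes = [g for g in chroms[i] if g.name != event["gene"]]
        if genes:
            chroms[i] = tuple(genes)
        else:
            chroms.pop(i)
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {kind!r}")


def _draw_split(chroms, rng, bias) -> Optional[dict]:
    splittable = [i for i, g in enumerate(chroms) if len(g) >= 2]
    if not splittable:
        return None
    i = int(rng.choice(splittable))
    genes = chroms[i]
    cuts = list(range(1, len(genes)))
    balanced = [
        c
        for c in cuts
        if any(g.is_anchor for g in genes[:c])
        and any(g.is_anchor for g in genes[c:])
    ]
    if balanced and rng.random() < bias:
        cut = int(rng.choice(balanced))
    else:
        cut = int(rng.choice(cuts))
    return {"kind": "split", "chromosome": _label(genes), "cut": cut}


def _draw_merger(chroms, rng) -> Optional[dict]:
    if len(chroms) < 2:
        return None
    i, j = map(int, rng.choice(len(chroms), size=2, replace=False))
    return {
        "kind": "merger",
        "first": _label(chroms[i]),
        "second": _label(chroms[j]),
    }


def _draw_translocation(chroms, rng) -> Optional[dict]:
    if len(chroms) < 2:
        return None
    movable = [
        (i, g)
        for i, genes in enumerate(chroms)
        for g in genes
        if g.base_name in TRNA_GENES
    ]
    if not movable:
        return None
    i, gene = movable[int(rng.integers(len(movable)))]
    targets = [t for t in range(len(chroms)) if t != i]
    j = int(rng.choice(targets))
    position = int(rng.integers(len(chroms[j]) + 1))
    return {
        "kind": "translocation",
        "gene": gene.name,
        "source": _label(chroms[i]),
        "target": _label(chroms[j]),
        "position": position,
    }


def _draw_loss(chroms, rng) -> Optional[dict]:
    flat = [(i, g) for i, genes in enumerate(chroms) for g in genes]
    if not flat:
        return None
    i, gene = flat[int(rng.integers(len(flat)))]
    return {"kind": "loss", "chromosome": _label(chroms[i]), "gene": gene.name}


def simulate_karyotypes(
    cfg: SimulationConfig,
) -> tuple[dict[str, Karyotype], GroundTruth]:
    """Evolve the root karyotype along the tree; returns tip karyotypes
    and the ground truth (log + every internal node's true state)."""
    rng = np.random.default_rng(cfg.rng_seed)
    truth = GroundTruth(seed=cfg.rng_seed)
    counter = [0]
    tree = cfg.tree
    root = tree.seed_node
    root_name = _node_name(root, counter)
    states: dict[int, list] = {id(root): _chrom_list(cfg.root_karyotype)}
    truth.node_karyotypes[root_name] = _to_karyotype(
        root_name, states[id(root)]
    )

    tips: dict[str, Karyotype] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        name = _node_name(node, counter)
        chroms = copy.deepcopy(states[id(node.parent_node)])
        drawers = [
            ("split", cfg.split_rate, lambda c, r: _draw_split(c, r, cfg.anchor_split_bias)),
            ("merger", cfg.merge_rate, lambda c, r: _draw_merger(c, r)),
            (
                "translocation",
                cfg.trna_translocation_rate,
                lambda c, r: _draw_translocation(c, r),
            ),
            ("loss", cfg.loss_rate, lambda c, r: _draw_loss(c, r)),
        ]
        pending: list = []
        for kind, rate, drawer in drawers:
            if rate > 0:
                pending.extend([drawer] * int(rng.poisson(rate)))
        rng.shuffle(pending)
        for drawer in pending:
            event = drawer(chroms, rng)
            if event is None:
                continue
            event["branch"] = name
            _apply_event(chroms, event)
            truth.events.append(event)
        states[id(node)] = chroms
        truth.node_karyotypes[name] = _to_karyotype(name, chroms)
        if node.is_leaf():
            tips[name] = truth.node_karyotypes[name]
    return tips, truth


def replay_events(
    root_karyotype: Karyotype,
    truth: GroundTruth,
    tree: dendropy.Tree,
) -> dict[str, Karyotype]:
    """Re-derive every node karyotype from the root and the event log."""
    counter = [0]
    states: dict[int, list] = {
        id(tree.seed_node): _chrom_list(root_karyotype)
    }
    out: dict[str, Karyotype] = {}
    for node in tree.preorder_node_iter():
        name = _node_name(node, counter)
        if node.parent_node is not None:
            chroms = copy.deepcopy(states[id(node.parent_node)])
            for event in truth.events_on(name):
                _apply_event(chroms, event)
            states[id(node)] = chroms
        out[name] = _to_karyotype(name, states[id(node)])
    return out


def mask_missing(karyotype: Karyotype, genes: Sequence[str]) -> Karyotype:
    """Observationally mask genes (post hoc; the truth is unchanged)."""
    bases = set(genes)
    chroms = []
    for chrom in karyotype.minichromosomes:
        kept = tuple(g for g in chrom.genes if g.base_name not in bases)
        if kept:
            chroms.append(Minichromosome(genes=kept))
    return Karyotype(
        taxon=karyotype.taxon,
        minichromosomes=tuple(chroms),
        missing_genes=karyotype.missing_genes | bases,
        source=karyotype.source,
    )


# --------------------------------------------------------------------------
# sequences


def random_sequence(
    length: int, rng: np.random.Generator, at_fraction: float = 0.5
) -> str:
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    return "".join(
        rng.choice(list(BASES), size=length, p=[p_at, p_gc, p_gc, p_at])
    )


def mutate_sequence(seq: str, p: float, rng: np.random.Generator) -> str:
    """Point-mutate each site with probability ``p`` to a different base."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hits:
        out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


def _evolve(seq: str, t: float, rate: float, rng: np.random.Generator) -> str:
    """Poisson substitution events per site; each event resamples the
    base uniformly (so two sequences at total path length d share a site
    with probability exp(-d) + (1-exp(-d))/4)."""
    lam = rate * t
    if lam <= 0:
        return seq
    out = list(seq)
    n_events = rng.poisson(lam, size=len(seq))
    for i in np.nonzero(n_events > 0)[0]:
        out[i] = rng.choice(list(BASES))
    return "".join(out)


def simulate_gene_sequences(
    tree: dendropy.Tree,
    root_genes: Mapping[str, str],
    substitution_rate: float,
    rng: np.random.Generator,
) -> dict[str, dict[str, str]]:
    """Evolve each root gene sequence along the tree; per-node output."""
    counter = [0]
    states: dict[int, dict[str, str]] = {
        id(tree.seed_node): dict(root_genes)
    }
    out: dict[str, dict[str, str]] = {}
    for node in tree.preorder_node_iter():
        name = _node_name(node, counter)
        if node.parent_node is not None:
            t = node.edge.length if node.edge.length is not None else 1.0
            parent = states[id(node.parent_node)]
            states[id(node)] = {
                gene: _evolve(seq, t, substitution_rate, rng)
                for gene, seq in parent.items()
            }
        out[name] = states[id(node)]
    return out


def plant_motif_ncrs(
    labels: Sequence[str],
    spec: MotifSpec,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, int], str]:
    """Random NCRs with the consensus motif planted in each copy.

    Returns (ncrs, true offsets, motif consensus)."""
    consensus = random_sequence(spec.length, rng, at_fraction=spec.at_fraction)
    ncrs: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for label in labels:
        backdrop = random_sequence(spec.ncr_length, rng, at_fraction=0.5)
        if spec.offset is None:
            off = int(rng.integers(0, spec.ncr_length - spec.length + 1))
        else:
            off = spec.offset
        copy_seq = mutate_sequence(consensus, spec.noise, rng)
        ncrs[label] = backdrop[:off] + copy_seq + backdrop[off + spec.length :]
        offsets[label] = off
    return ncrs, offsets, consensus


def simulate_sequences(
    cfg: SimulationConfig,
    genes: Optional[Mapping[str, str]] = None,
    gene_length: int = 300,
) -> tuple[dict[str, dict[str, str]], dict[str, str], GroundTruth]:
    """Per-tip gene sequences plus NCRs with planted motifs."""
    rng = np.random.default_rng(cfg.rng_seed)
    if genes is None:
        genes = {
            f"gene{i}": random_sequence(gene_length, rng) for i in range(5)
        }
    per_node = simulate_gene_sequences(
        cfg.tree, genes, cfg.substitution_rate, rng
    )
    tip_names = {
        (n.taxon.label if n.taxon else n.label).replace(" ", "_")
        for n in cfg.tree.leaf_node_iter()
    }
    tips = {name: seqs for name, seqs in per_node.items() if name in tip_names}
    labels = [f"ncr{i}" for i in range(len(tips) or 1)]
    ncrs, offsets, consensus = plant_motif_ncrs(labels, cfg.motif_spec, rng)
    truth = GroundTruth(
        seed=cfg.rng_seed,
        motif_positions=offsets,
        motif_consensus=consensus,
    )
    return tips, ncrs, truth
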