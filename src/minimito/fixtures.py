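"""Loaders for the packaged karyotype / tree / family-map fixtures.

The karyotype files transcribe published minichromosome organisations of
five seal louse species, the gorilla louse and reference taxa, plus the
inferred ancestral karyotypes used as outgroup states.
"""

from __future__ import annotations

from importlib import resources

import dendropy
import yaml

from .karyotype_model import Karyotype, parse_karyotype

SEAL_LICE = (
    "antarctophthirus_carlinii",
    "antarctophthirus_lobodontis",
    "antarctophthirus_microchir",
    "lepidophthirus_macrorhini",
    "proechinophthirus_fluctus",
)

FOCAL_TAXA = SEAL_LICE + ("pthirus_gorillae",)

#: Published minichromosome / identified-gene counts for the focal taxa.
PUBLISHED_COUNTS = {
    "antarctophthirus_carlinii": (9, 30),
    "antarctophthirus_lobodontis": (9, 30),
    "antarctophthirus_microchir": (12, 20),
    "lepidophthirus_macrorhini": (11, 27),
    "proechinophthirus_fluctus": (10, 22),
    "pthirus_gorillae": (17, 36),
}


def _read_text(name: str) -> str:
    return (resources.files("minimito") / "fixtures" / name).read_text()


def load_karyotype(name: str) -> Karyotype:
    """Load a packaged karyotype by taxon name (without extension)."""
    return parse_karyotype(_read_text(f"{name}.kt"))


def seal_louse_karyotypes() -> list[Karyotype]:
    return [load_karyotype(name) for name in SEAL_LICE]


def sucking_louse_mrca() -> Karyotype:
    """Ancestral sucking-louse karyotype taken from prior work."""
    return load_karyotype("anoplura_mrca")


def load_tree() -> dendropy.Tree:
    return dendropy.Tree.get(
        data=_read_text("anoplura.nwk"),
        schema="newick",
        suppress_internal_node_taxa=False,
    )


def load_family_map() -> dict[str, str]:
    return yaml.safe_load(_read_text("families.yaml"))


def event_tally_karyotypes() -> dict[str, Karyotype]:
    """Node->karyotype map for the lineages whose split/merger history is
    explicitly encoded (internal-node states come from ancestral
    inference in prior work or this package)."""
    names = (
        "anoplura_mrca",
        "sealice_mrca",
        "primate_mrca",
        "haematopinus_apri",
        "pedicinus_obtusus",
        "pthirus_pubis",
        "pthirus_gorillae",
        "proechinophthirus_fluctus",
    )
    return {name: load_karyotype(name) for name in names}
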