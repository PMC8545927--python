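"""Bipartite protein-miRNA targeting networks and hub identification.

Builds the two-sided network linking proteins (e.g. the backbone of a
protein-interaction network) to the miRNAs reported to target their
transcripts, restricted to a disease-associated miRNA set.  *Hub
proteins* are targeted by many distinct miRNAs; *hub miRNAs* target
many distinct proteins.

miRNA names arrive in inconsistent spellings across curated sources
("hsa-miR-155-5p", "miR-155-5p", "mir-181a"); they are canonicalized
by case-folding, stripping the species prefix and applying a small
editable alias table for known misspellings.  Names without a -5p/-3p
arm suffix are deliberately kept distinct from suffixed forms, because
merging them silently changes degree counts; an opt-in merge mode
exists for exploratory use.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "DEFAULT_ALIASES",
    "BipartiteNetwork",
    "HubThresholds",
    "canonicalize_mirna",
    "load_alias_table",
    "intersect_mirna_sets",
    "bipartite_degrees",
    "find_hubs",
]

# Known misspellings in curated association tables.  The packaged
# editable copy lives in data/mirna_aliases.tsv; only entries applied
# by default appear here.
DEFAULT_ALIASES: dict[str, str] = {
    "leg-7g-3p": "let-7g-3p",
    "leg-7g-5p": "let-7g-5p",
    "leg-7g": "let-7g",
}

_ARM_RE = re.compile(r"-(5p|3p)$")


def canonicalize_mirna(
    raw: str, aliases: Mapping[str, str] | None = None
) -> str:
    """Normalize a miRNA name: case-fold, strip "hsa-", fix aliases.

    Idempotent: canonicalizing a canonical name returns it unchanged.
    Raises ``ValueError`` on an empty string.
    """
    name = str(raw).strip().lower()
    if not name:
        raise ValueError("empty miRNA name")
    if name.startswith("hsa-"):
        name = name[4:]
    table = DEFAULT_ALIASES if aliases is None else aliases
    return table.get(name, name)


def merge_arm(name: str) -> str:
    """Drop a trailing -5p/-3p arm suffix (opt-in merge mode only)."""
    return _ARM_RE.sub("", name)


def load_alias_table(path=None) -> dict[str, str]:
    """Read an alias TSV (``wrong<TAB>right``; # comments allowed).

    Without a path, loads the packaged default table.  Aliases are
    applied to already case-folded, prefix-stripped names.
    """
    if path is None:
        text = (
            resources.files("comorbnet") / "data" / "mirna_aliases.tsv"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        wrong, right = line.split("\t")[:2]
        table[wrong.strip().lower()] = right.strip().lower()
    return table


@dataclass
class BipartiteNetwork:
    """Protein and miRNA node sets plus (protein, mirna) edges.

    Proteins with no surviving edges are retained as isolated nodes so
    that zero degrees are reported rather than dropped.
    """

    proteins: set[str]
    mirnas: set[str]
    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = [e for e in self.edges if e[0] not in self.proteins or e[1] not in self.mirnas]
        if bad:
            raise ValueError(f"edges reference undeclared nodes: {bad[:5]}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.proteins), side="protein")
        g.add_nodes_from(sorted(self.mirnas), side="mirna")
        g.add_edges_from(sorted(self.edges))
        return g

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    @classmethod
    def from_edge_list(
        cls,
        edges: Iterable[tuple[str, str]],
        isolated_proteins: Iterable[str] = (),
    ) -> "BipartiteNetwork":
        edges = set(edges)
        return cls(
            proteins={p for p, _ in edges} | set(isolated_proteins),
            mirnas={m for _, m in edges},
            edges=edges,
        )


@dataclass(frozen=True)
class HubThresholds:
    """Minimum partner counts for hub calls on each side.

    The defaults encode "targeted by more than 10 miRNAs" for proteins
    and "targets more than 12 proteins" for miRNAs.
    """

    protein_hub_min_mirnas: int = 11
    mirna_hub_min_proteins: int = 13

    def __post_init__(self) -> None:
        if self.protein_hub_min_mirnas < 1 or self.mirna_hub_min_proteins < 1:
            raise ValueError("hub thresholds must be >= 1")


def intersect_mirna_sets(
    disease_set: Iterable[str],
    target_map: Mapping[str, Iterable[str]],
    aliases: Mapping[str, str] | None = None,
) -> BipartiteNetwork:
    """Restrict a protein→miRNA target map to a disease miRNA set.

    Both sides are canonicalized before matching.  An edge (p, m) is
    kept iff m belongs to the disease set; every protein of the map is
    retained even if all of its targeting miRNAs are filtered out.
    """
    disease = {canonicalize_mirna(m, aliases) for m in disease_set}
    edges: set[tuple[str, str]] = set()
    proteins: set[str] = set()
    for protein, mirnas in target_map.items():
        proteins.add(protein)
        for m in mirnas:
            cm = canonicalize_mirna(m, aliases)
            if cm in disease:
                edges.add((protein, cm))
    return BipartiteNetwork(
        proteins=proteins, mirnas={m for _, m in edges}, edges=edges
    )


def bipartite_degrees(
    net: BipartiteNetwork,
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-node partner counts: (protein → #miRNAs, miRNA → #proteins)."""
    pdeg = {p: 0 for p in net.proteins}
    mdeg = {m: 0 for m in net.mirnas}
    for p, m in net.edges:
        pdeg[p] += 1
        mdeg[m] += 1
    return pdeg, mdeg


def find_hubs(
    net: BipartiteNetwork, t: HubThresholds = HubThresholds()
) -> tuple[set[str], set[str]]:
    """Hub proteins and hub miRNAs by partner-count thresholds."""
    pdeg, mdeg = bipartite_degrees(net)
    return (
        {p for p, d in pdeg.items() if d >= t.protein_hub_min_mirnas},
        {m for m, d in mdeg.items() if d >= t.mirna_hub_min_proteins},
    )
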