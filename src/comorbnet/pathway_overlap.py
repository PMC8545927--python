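"""Set-overlap annotation of node sets against pathway member lists.

Given a set of proteins (e.g. a network backbone) and a collection of
named pathway membership lists, reports the membership overlap per
pathway: the count and the sorted member list.  Pathway lists are
static files (packaged transcriptions or user-supplied GMT); no
database service is queried, so runs are reproducible offline.  This
is plain set intersection, not an enrichment statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["PathwaySet", "read_gmt", "write_gmt", "annotate"]


@dataclass(frozen=True)
class PathwaySet:
    """One named pathway and its member gene/protein symbols."""

    pathway_id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id} has no members")


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


def read_gmt(path: str | Path) -> list[PathwaySet]:
    """Read GMT lines ``pathway_id<TAB>description<TAB>member...``."""
    sets = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(
            PathwaySet(
                pathway_id=fields[0].strip(),
                description=fields[1].strip(),
                members=frozenset(_norm(m) for m in fields[2:] if m.strip()),
            )
        )
    return sets


def write_gmt(pathways: Iterable[PathwaySet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ps in pathways:
            fh.write(
                "\t".join([ps.pathway_id, ps.description, *sorted(ps.members)])
                + "\n"
            )


def annotate(
    nodes: Iterable[str], pathways: Sequence[PathwaySet]
) -> pd.DataFrame:
    """Overlap of a node set with each pathway's member list.

    Symbols are matched after uppercasing both sides.  Returns a frame
    with ``pathway_id, description, n_overlap, members`` (members as a
    sorted tuple).  Duplicate pathway ids are a validation error.
    """
    node_set = {_norm(n) for n in nodes}
    if not node_set or not pathways:
        raise ValueError("both the node set and the pathway list must be nonempty")
    ids = [ps.pathway_id for ps in pathways]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate pathway ids: {sorted(dupes)}")
    rows = []
    for ps in pathways:
        hit = sorted(node_set & ps.members)
        rows.append(
            {
                "pathway_id": ps.pathway_id,
                "description": ps.description,
                "n_overlap": len(hit),
                "members": tuple(hit),
            }
        )
    return pd.DataFrame(rows)
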