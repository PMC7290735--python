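"""Pathway knowledge base: gene sets with signed activator/repressor roles.

A pathway is modelled as a flat membership list in which every member gene
carries a signed role weight (ARR): positive for activators of the pathway,
negative for repressors.  Topology beyond membership and role is deliberately
out of scope — the activation score downstream only consumes (gene, role)
pairs.

Two on-disk dialects are supported:

``long-TSV``
    Header ``pathway_id  pathway_name  branch  gene_id  role``; one member
    per line.  ``role`` is ``activator``/``repressor``, ``+``/``-``, or a
    signed number (graded weights such as ``-0.5`` are honoured).

``role-annotated GMT``
    One pathway per line: ``pathway_id<TAB>description<TAB>gene+  gene-...``;
    each gene token ends in ``+`` or ``-``, optionally followed by a
    magnitude (``Tp53+0.5``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneRole",
    "Pathway",
    "PathwayDB",
    "load_pathway_db",
    "write_pathway_db",
    "jaccard_similarity",
    "similarity_matrix",
]


@dataclass(frozen=True)
class GeneRole:
    """A pathway member with its signed activator/repressor role (ARR)."""

    gene_id: str
    arr: float

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.arr == 0:
            raise ValueError(f"ARR for gene {self.gene_id!r} must be nonzero")


@dataclass(frozen=True)
class Pathway:
    """A named gene set with signed member roles."""

    pathway_id: str
    name: str
    members: tuple[GeneRole, ...]
    branch: str | None = None
    _roles: Mapping[str, float] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")
        roles: dict[str, float] = {}
        for m in self.members:
            if m.gene_id in roles:
                raise ValueError(
                    f"gene {m.gene_id!r} listed twice in pathway {self.pathway_id!r}"
                )
            roles[m.gene_id] = m.arr
        object.__setattr__(self, "_roles", roles)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._roles)

    @property
    def roles(self) -> Mapping[str, float]:
        """Mapping gene_id -> signed ARR weight."""
        return self._roles

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PathwayDB:
    """An ordered collection of pathways with unique ids."""

    pathways: tuple[Pathway, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pathways:
            if p.pathway_id in seen:
                raise ValueError(f"duplicate pathway id {p.pathway_id!r}")
            seen.add(p.pathway_id)

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    @property
    def gene_universe(self) -> frozenset[str]:
        return frozenset(g for p in self.pathways for g in p.genes)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)


_ROLE_WORDS = {"activator": 1.0, "repressor": -1.0, "+": 1.0, "-": -1.0}


def _parse_role(token: str, where: str) -> float:
    token = token.strip()
    if token.lower() in _ROLE_WORDS:
        return _ROLE_WORDS[token.lower()]
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"unparseable role {token!r} at {where}") from None
    if value == 0:
        raise ValueError(f"role must be nonzero at {where}")
    return value


def _parse_gmt_token(token: str, where: str) -> GeneRole:
    # gene token: name followed by '+'/'-' and an optional magnitude
    for i in range(len(token) - 1, -1, -1):
        if token[i] in "+-":
            gene, sign, mag = token[:i], token[i], token[i + 1 :]
            if not gene:
                break
            magnitude = 1.0
            if mag:
                try:
                    magnitude = float(mag)
                except ValueError:
                    raise ValueError(f"unparseable role suffix in {token!r} at {where}") from None
                if magnitude <= 0:
                    raise ValueError(f"role magnitude must be positive in {token!r} at {where}")
            return GeneRole(gene, magnitude if sign == "+" else -magnitude)
    raise ValueError(f"gene token {token!r} lacks a +/- role suffix at {where}")


def load_pathway_db(
    path: str | Path,
    format: str = "long-TSV",
    alias_map: Mapping[str, str] | None = None,
) -> PathwayDB:
    """Load a pathway knowledge base from disk.

    Gene identifiers are matched exactly and case-sensitively; pass
    ``alias_map`` (alias -> canonical id) to reconcile naming schemes
    explicitly rather than by silent case folding.
    """
    path = Path(path)
    if format == "long-TSV":
        pathways = _load_long_tsv(path)
    elif format == "role-annotated-GMT":
        pathways = _load_gmt(path)
    else:
        raise ValueError(f"unknown pathway file format {format!r}")
    if alias_map:
        pathways = [
            Pathway(
                p.pathway_id,
                p.name,
                tuple(GeneRole(alias_map.get(m.gene_id, m.gene_id), m.arr) for m in p.members),
                p.branch,
            )
            for p in pathways
        ]
    if not pathways:
        raise ValueError(f"no pathways found in {path}")
    return PathwayDB(tuple(pathways))


def _load_long_tsv(path: Path) -> list[Pathway]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["pathway_id", "pathway_name", "branch", "gene_id", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    pathways: list[Pathway] = []
    for (pid,), rows in df.groupby(["pathway_id"], sort=False):
        names = rows["pathway_name"].unique()
        if len(names) > 1:
            raise ValueError(
                f"{path}: pathway id {pid!r} appears with conflicting names {list(names)}"
            )
        branches = [b for b in rows["branch"].unique() if pd.notna(b)]
        members = tuple(
            GeneRole(str(r.gene_id), _parse_role(str(r.role), f"{path} line {i + 2}"))
            for i, r in zip(rows.index, rows.itertuples())
        )
        pathways.append(
            Pathway(str(pid), str(names[0]), members, branches[0] if branches else None)
        )
    return pathways


def _load_gmt(path: Path) -> list[Pathway]:
    pathways = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: expected id, description, genes")
            pid, desc, *tokens = fields
            members = tuple(
                _parse_gmt_token(t, f"{path} line {lineno}") for t in tokens if t
            )
            pathways.append(Pathway(pid, desc, members))
    return pathways


def write_pathway_db(db: PathwayDB, path: str | Path, format: str = "long-TSV") -> None:
    """Write a knowledge base in a dialect :func:`load_pathway_db` reads back."""
    path = Path(path)
    if format == "long-TSV":
        rows = [
            {
                "pathway_id": p.pathway_id,
                "pathway_name": p.name,
                "branch": p.branch if p.branch is not None else "",
                "gene_id": m.gene_id,
                "role": repr(m.arr) if m.arr not in (1.0, -1.0) else ("activator" if m.arr > 0 else "repressor"),
            }
            for p in db.pathways
            for m in p.members
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif format == "role-annotated-GMT":
        with open(path, "w", encoding="utf-8") as fh:
            for p in db.pathways:
                tokens = []
                for m in p.members:
                    sign = "+" if m.arr > 0 else "-"
                    mag = "" if abs(m.arr) == 1.0 else repr(abs(m.arr))
                    tokens.append(f"{m.gene_id}{sign}{mag}")
                fh.write("\t".join([p.pathway_id, p.name, *tokens]) + "\n")
    else:
        raise ValueError(f"unknown pathway file format {format!r}")


def jaccard_similarity(a: Pathway, b: Pathway) -> float:
    """Jaccard coefficient of two pathways' gene sets (roles ignored).

    |A ∩ B| / |A ∪ B|; 1.0 iff the gene sets are identical, 0.0 iff disjoint.
    """
    ga, gb = a.genes, b.genes
    return len(ga & gb) / len(ga | gb)


def similarity_matrix(db: PathwayDB) -> pd.DataFrame:
    """Symmetric pathway-by-pathway Jaccard similarity matrix."""
    n = len(db)
    ids = db.pathway_ids
    mat = np.eye(n)
    for (i, a), (j, b) in itertools.combinations(enumerate(db.pathways), 2):
        mat[i, j] = mat[j, i] = jaccard_similarity(a, b)
    return pd.DataFrame(mat, index=ids, columns=ids)
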