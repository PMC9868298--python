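"""Rooted, rank-labelled taxonomies and lineage / lowest-common-ancestor queries.

The taxonomy is the coordinate system for every downstream rollup: each
peptide is placed on a node of this tree and abundances are accumulated
towards the root.  Two on-disk dialects are supported: a simple lineage
table (``taxon_id, parent_id, rank, name``) and the NCBI ``nodes.dmp`` /
``names.dmp`` dump format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Controlled rank vocabulary, ordered root-first.  "superkingdom" (NCBI
#: dumps) and "domain" are treated as aliases; unrecognized ranks are kept
#: as NO_RANK so that their abundance still participates in rollups.
RANK_ORDER: tuple[str, ...] = (
    "root",
    "domain",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

NO_RANK = "no-rank"

_RANK_ALIASES = {
    "superkingdom": "domain",
    "no rank": NO_RANK,
    "no_rank": NO_RANK,
    "norank": NO_RANK,
}


def normalize_rank(rank: str) -> str:
    """Map a free-form rank string onto the controlled vocabulary.

    Matching is case-insensitive; unknown ranks collapse to ``no-rank``.
    """
    key = rank.strip().lower()
    key = _RANK_ALIASES.get(key, key)
    if key in RANK_ORDER or key == NO_RANK:
        return key
    return NO_RANK


class TaxonomyError(ValueError):
    """Structural problem in a taxonomy source (cycle, orphan, duplicate)."""


@dataclass(frozen=True)
class TaxonNode:
    """A single taxon: identifier, parent link, rank and display name."""

    taxon_id: str
    parent_id: str
    rank: str
    name: str

    @property
    def is_root(self) -> bool:
        return self.taxon_id == self.parent_id


class TaxonomyTree:
    """Validated rooted taxonomy with parent pointers and child lists.

    Children are ordered lexicographically by taxon id so that traversals
    (and therefore every file this package writes) are deterministic.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[str, TaxonNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise TaxonomyError(f"duplicate taxon_id {node.taxon_id!r}")
            self.nodes[node.taxon_id] = node

        roots = [n for n in self.nodes.values() if n.is_root]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root node, found {len(roots)}"
            )
        self.root_id: str = roots[0].taxon_id
        if roots[0].rank != "root":
            raise TaxonomyError(
                f"root node {self.root_id!r} must carry rank 'root', "
                f"got {roots[0].rank!r}"
            )

        self.children: dict[str, tuple[str, ...]] = {}
        kids: dict[str, list[str]] = {tid: [] for tid in self.nodes}
        for node in self.nodes.values():
            if node.is_root:
                continue
            if node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"orphan taxon {node.taxon_id!r}: unknown parent "
                    f"{node.parent_id!r}"
                )
            kids[node.parent_id].append(node.taxon_id)
        self.children = {tid: tuple(sorted(c)) for tid, c in kids.items()}

        self._depth: dict[str, int] = {}
        self._validate_reachability()

    # -- construction helpers -------------------------------------------------

    def _validate_reachability(self) -> None:
        for tid in self.nodes:
            self._depth_of(tid)

    def _depth_of(self, taxon_id: str) -> int:
        """Depth from root (root = 0); walking up also detects cycles."""
        if taxon_id in self._depth:
            return self._depth[taxon_id]
        path = []
        cur = taxon_id
        seen = set()
        while cur not in self._depth and cur != self.root_id:
            if cur in seen:
                raise TaxonomyError(f"cycle detected at taxon {cur!r}")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur].parent_id
        base = self._depth.get(cur, 0)
        self._depth.setdefault(self.root_id, 0)
        for i, tid in enumerate(reversed(path), start=1):
            self._depth[tid] = base + i
        return self._depth[taxon_id]

    # -- queries --------------------------------------------------------------

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def depth(self, taxon_id: str) -> int:
        self._require(taxon_id)
        return self._depth[taxon_id]

    def parent(self, taxon_id: str) -> str:
        self._require(taxon_id)
        return self.nodes[taxon_id].parent_id

    def _require(self, taxon_id: str) -> None:
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon_id {taxon_id!r}")

    def lineage(self, taxon_id: str) -> list[tuple[str, str]]:
        """Root-to-taxon path as ``(rank, taxon_id)`` pairs."""
        self._require(taxon_id)
        path = []
        cur = taxon_id
        while True:
            node = self.nodes[cur]
            path.append((node.rank, cur))
            if node.is_root:
                break
            cur = node.parent_id
        path.reverse()
        return path

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor: the deepest node on every root-path."""
        ids = list(taxa)
        if not ids:
            raise ValueError("lca of an empty taxon set is undefined")
        for tid in ids:
            self._require(tid)
        cur = ids[0]
        for other in ids[1:]:
            cur = self._lca2(cur, other)
            if cur == self.root_id:
                break
        return cur

    def _lca2(self, a: str, b: str) -> str:
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self.nodes[a].parent_id
            da -= 1
        while db > da:
            b = self.nodes[b].parent_id
            db -= 1
        while a != b:
            a = self.nodes[a].parent_id
            b = self.nodes[b].parent_id
        return a

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        """True if ``ancestor`` lies on the root-path of ``descendant``
        (every node is an ancestor of itself)."""
        self._require(ancestor)
        self._require(descendant)
        cur = descendant
        while True:
            if cur == ancestor:
                return True
            node = self.nodes[cur]
            if node.is_root:
                return False
            cur = node.parent_id

    def postorder(self) -> list[str]:
        """Children-before-parent traversal covering every node once."""
        order: list[str] = []
        stack = [(self.root_id, False)]
        while stack:
            tid, expanded = stack.pop()
            if expanded:
                order.append(tid)
            else:
                stack.append((tid, True))
                for child in reversed(self.children[tid]):
                    stack.append((child, False))
        return order

    def at_rank(self, rank: str) -> list[str]:
        """All taxa whose (normalized) rank equals ``rank``, sorted by id.

        Nodes of rank ``no-rank`` never appear in rank reports but still
        carry abundance in rollups.
        """
        rank = normalize_rank(rank)
        return sorted(
            tid for tid, n in self.nodes.items() if n.rank == rank
        )

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """The unique ancestor (or self) of ``taxon_id`` at ``rank``."""
        rank = normalize_rank(rank)
        for r, tid in self.lineage(taxon_id):
            if r == rank:
                return tid
        return None


# -- readers / writers --------------------------------------------------------


def load_taxonomy(
    source: str | Path | tuple[str | Path, str | Path],
) -> TaxonomyTree:
    """Load a taxonomy from a lineage TSV or an NCBI dump pair.

    ``source`` is either the path of a lineage table (columns ``taxon_id``,
    ``parent_id``, ``rank``, ``name``) or a ``(nodes.dmp, names.dmp)`` pair.
    """
    if isinstance(source, tuple):
        nodes_path, names_path = source
        return read_ncbi_dump(nodes_path, names_path)
    return read_lineage_table(source)


def read_lineage_table(path: str | Path) -> TaxonomyTree:
    """Read the native lineage TSV dialect (header required, UTF-8)."""
    nodes = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["taxon_id", "parent_id", "rank", "name"]
        if header[: len(required)] != required:
            raise TaxonomyError(
                f"lineage table {path}: expected header {required}, "
                f"got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TaxonomyError(
                    f"lineage table {path}: ragged row at line {lineno}"
                )
            tid, pid, rank, name = fields[:4]
            nodes.append(TaxonNode(tid, pid, normalize_rank(rank), name))
    return TaxonomyTree(nodes)


def write_lineage_table(tree: TaxonomyTree, path: str | Path) -> None:
    """Write the lineage TSV; ``read_lineage_table`` round-trips it."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\tparent_id\trank\tname\n")
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            fh.write(f"{n.taxon_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")


def read_ncbi_dump(
    nodes_path: str | Path, names_path: str | Path
) -> TaxonomyTree:
    """Read the NCBI ``nodes.dmp`` / ``names.dmp`` dialect.

    Fields are separated by ``\\t|\\t`` and rows are terminated by
    ``\\t|``; only scientific names are taken from ``names.dmp``.
    """
    names: dict[str, str] = {}
    with open(names_path, encoding="utf-8") as fh:
        for line in fh:
            fields = _split_dmp(line)
            if len(fields) >= 4 and fields[3] == "scientific name":
                names.setdefault(fields[0], fields[1])
    nodes = []
    with open(nodes_path, encoding="utf-8") as fh:
        for line in fh:
            fields = _split_dmp(line)
            if len(fields) < 3:
                continue
            tid, pid, rank = fields[0], fields[1], fields[2]
            rank = normalize_rank(rank)
            if tid == pid:
                rank = "root"
            nodes.append(TaxonNode(tid, pid, rank, names.get(tid, tid)))
    return TaxonomyTree(nodes)


def _split_dmp(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return [f.strip() for f in line.split("\t|\t")]


def write_ncbi_dump(
    tree: TaxonomyTree, nodes_path: str | Path, names_path: str | Path
) -> None:
    """Write the NCBI dump dialect (used to test dialect equivalence)."""
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            fh.write(f"{n.taxon_id}\t|\t{n.parent_id}\t|\t{n.rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for tid in sorted(tree.nodes):
            n = tree.nodes[tid]
            fh.write(
                f"{n.taxon_id}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n"
            )
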