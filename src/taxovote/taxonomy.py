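"""NCBI-style taxonomy handling: loading, rank backbone, lineage and LCA queries.

The consensus voter operates on a *simplified* taxonomy that keeps only the
root and the seven standard ranks (superkingdom, phylum, class, order,
family, genus, species).  Classifier output frequently refers to nodes
outside that backbone — strains, "no rank" clades, merged or deleted IDs —
so this module also provides the remapping and rank-lifting needed to land
every vote on a backbone node before voting starts.

Conventions used throughout the package:

* taxon ID ``0`` is a reserved sentinel meaning "unclassified" and is never
  a node of any tree;
* taxon ID ``1`` is the root, its own parent, with the artificial rank
  ``root``.
"""

from __future__ import annotations

import io
import logging
from enum import IntEnum
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from .errors import FormatError, TaxonomyError, UnknownTaxonError

logger = logging.getLogger(__name__)

UNCLASSIFIED = 0
ROOT_TAXON = 1


class Rank(IntEnum):
    """The eight levels of the backbone, totally ordered root < ... < species."""

    ROOT = 0
    SUPERKINGDOM = 1
    PHYLUM = 2
    CLASS = 3
    ORDER = 4
    FAMILY = 5
    GENUS = 6
    SPECIES = 7

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "Rank | None":
        """Resolve a dump rank string to a standard rank, or None.

        Matching is case-insensitive and tolerant of the hyphenated
        "super-kingdom" spelling; anything unrecognized (including
        "no rank", "strain", "subspecies", ...) maps to None and is
        treated as non-standard.
        """
        key = name.strip().lower().replace("-", "").replace(" ", "")
        return _RANK_BY_KEY.get(key)


_RANK_BY_KEY = {r.label: r for r in Rank}

#: The seven reporting levels, shallowest first.
STANDARD_RANKS: tuple[Rank, ...] = tuple(r for r in Rank if r is not Rank.ROOT)


class TaxonomyTree:
    """A rooted, rank-annotated taxonomy.

    Parameters
    ----------
    parent
        Map taxid -> parent taxid.  Must contain the root (1 -> 1).
    rank
        Map taxid -> :class:`Rank` or ``None`` for non-standard ranks.
    rank_name
        Raw rank strings from the source dump (used when writing back).
    name
        Optional map taxid -> scientific name.
    merged
        Map of retired taxid -> current taxid.
    deleted
        Set of taxids known to have been deleted from the source taxonomy.
    standard_only
        True for the simplified backbone; enables the strict
        rank-monotonicity invariant.
    """

    def __init__(
        self,
        parent: Mapping[int, int],
        rank: Mapping[int, "Rank | None"],
        rank_name: Mapping[int, str] | None = None,
        name: Mapping[int, str] | None = None,
        merged: Mapping[int, int] | None = None,
        deleted: Iterable[int] = (),
        standard_only: bool = False,
    ):
        self.parent: dict[int, int] = dict(parent)
        self.rank: dict[int, Rank | None] = dict(rank)
        self.rank_name: dict[int, str] = dict(rank_name or {})
        self.name: dict[int, str] = dict(name or {})
        self.merged: dict[int, int] = dict(merged or {})
        self.deleted: frozenset[int] = frozenset(deleted)
        self.standard_only = standard_only
        self._lineages: dict[int, tuple[int, ...]] = {ROOT_TAXON: (ROOT_TAXON,)}
        self._children: dict[int, tuple[int, ...]] | None = None
        self._validate()

    # -- construction-time checks -------------------------------------------

    def _validate(self) -> None:
        if ROOT_TAXON not in self.parent:
            raise TaxonomyError("taxonomy has no root node (taxid 1)")
        if self.parent[ROOT_TAXON] != ROOT_TAXON:
            raise TaxonomyError("root (taxid 1) must be its own parent")
        self.rank[ROOT_TAXON] = Rank.ROOT
        self.rank_name.setdefault(ROOT_TAXON, "root")
        if UNCLASSIFIED in self.parent:
            raise TaxonomyError("taxid 0 is the unclassified sentinel, not a node")
        for t, p in self.parent.items():
            if p not in self.parent:
                raise TaxonomyError(f"node {t} has parent {p} which is absent")
        # Acyclicity: every node must reach the root.
        state: dict[int, int] = {ROOT_TAXON: 1}  # 1 = reaches root
        for t in self.parent:
            path = []
            cur = t
            while state.get(cur, 0) != 1:
                if cur in path or (cur != ROOT_TAXON and cur == self.parent[cur]):
                    raise TaxonomyError(f"cycle in taxonomy at node {cur}")
                path.append(cur)
                cur = self.parent[cur]
            for n in path:
                state[n] = 1
        if self.standard_only:
            for t, p in self.parent.items():
                if t == ROOT_TAXON:
                    continue
                r, pr = self.rank.get(t), self.rank.get(p)
                if r is None or r is Rank.ROOT:
                    raise TaxonomyError(
                        f"node {t} has non-standard rank in simplified tree"
                    )
                if pr is None or r <= pr:
                    raise TaxonomyError(
                        f"rank of {t} ({r.label}) does not deepen from its "
                        f"parent {p}"
                    )

    # -- basic queries -------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    @property
    def nodes(self) -> Iterator[int]:
        return iter(self.parent)

    def resolve(self, taxid: int) -> int:
        """Follow the merged-ID table (transitively) to the current taxid."""
        seen = set()
        while taxid in self.merged:
            if taxid in seen:
                raise TaxonomyError(f"merged-taxid cycle at {taxid}")
            seen.add(taxid)
            taxid = self.merged[taxid]
        return taxid

    def children(self, taxid: int) -> tuple[int, ...]:
        if self._children is None:
            kids: dict[int, list[int]] = {t: [] for t in self.parent}
            for t, p in self.parent.items():
                if t != ROOT_TAXON:
                    kids[p].append(t)
            self._children = {t: tuple(sorted(c)) for t, c in kids.items()}
        try:
            return self._children[taxid]
        except KeyError:
            raise UnknownTaxonError(taxid) from None

    def lineage(self, taxid: int) -> tuple[int, ...]:
        """Root-first path ``(1, ..., taxid)``."""
        cached = self._lineages.get(taxid)
        if cached is not None:
            return cached
        if taxid not in self.parent:
            raise UnknownTaxonError(taxid)
        path = []
        cur = taxid
        while cur not in self._lineages:
            path.append(cur)
            cur = self.parent[cur]
        base = self._lineages[cur]
        for i in range(len(path) - 1, -1, -1):
            base = base + (path[i],)
            self._lineages[path[i]] = base
        return self._lineages[taxid]

    def depth(self, taxid: int) -> int:
        return len(self.lineage(taxid)) - 1

    def lca(self, a: int, b: int) -> int:
        """Lowest common ancestor; commutative, lca(a, root) == root."""
        la, lb = self.lineage(a), self.lineage(b)
        n = min(len(la), len(lb))
        i = 0
        while i < n and la[i] == lb[i]:
            i += 1
        return la[i - 1]

    def lca_many(self, taxa: Iterable[int]) -> int:
        it = iter(taxa)
        try:
            acc = next(it)
        except StopIteration:
            raise ValueError("lca_many of an empty collection") from None
        for t in it:
            acc = self.lca(acc, t)
        return acc

    def ancestor_at(self, taxid: int, level: Rank) -> int | None:
        """The node of rank ``level`` on lineage(taxid), or None.

        Returns None both when the lineage stops above the level and when
        the level is skipped by a rank gap.
        """
        for node in self.lineage(taxid):
            r = self.rank.get(node)
            if r is None:
                continue
            if r == level:
                return node
            if r > level:
                return None
        return None


# -- dump parsing ------------------------------------------------------------


def _open_lines(source) -> tuple[str, Iterable[str], "IO | None"]:
    """Accept a path, str path, file-like or iterable of lines."""
    if isinstance(source, (str, Path)):
        fh = open(source, "r", encoding="utf-8")
        return str(source), fh, fh
    name = getattr(source, "name", "<stream>")
    return str(name), source, None


def _iter_dmp_rows(source, what: str) -> Iterator[tuple[int, list[str]]]:
    """Yield (lineno, fields) from the NCBI dump dialect.

    Fields are separated by ``\\t|\\t`` and rows are terminated ``\\t|``;
    a bare-pipe fallback keeps hand-written fixtures easy to author.
    """
    src, lines, fh = _open_lines(source)
    try:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            fields = line.split("\t|\t")
            if len(fields) == 1 and "|" in line:
                fields = [f.strip("\t ") for f in line.split("|")]
                if fields and fields[-1] == "":
                    fields.pop()
            if len(fields) == 1:
                raise FormatError(
                    f"malformed {what} row (no field separators): {line!r}",
                    source=src,
                    line=lineno,
                )
            yield lineno, fields
    finally:
        if fh is not None:
            fh.close()


def _parse_taxid(text: str, src: str, lineno: int) -> int:
    try:
        v = int(text.strip())
    except ValueError:
        raise FormatError(f"non-integer taxid {text!r}", source=src, line=lineno)
    if v < 0:
        raise FormatError(f"negative taxid {v}", source=src, line=lineno)
    return v


def load_taxonomy(
    nodes_source,
    names_source=None,
    merged_source=None,
    deleted_source=None,
) -> TaxonomyTree:
    """Load a full taxonomy from NCBI-dump-style tables.

    Only columns (taxid, parent, rank) of ``nodes.dmp`` and the
    "scientific name" rows of ``names.dmp`` are consumed; ``merged.dmp``
    and ``delnodes.dmp`` are optional.  The returned tree keeps every node
    of the dump, whatever its rank; use :func:`simplify` to obtain the
    standard-rank backbone.
    """
    parent: dict[int, int] = {}
    rank: dict[int, Rank | None] = {}
    rank_name: dict[int, str] = {}
    src = str(nodes_source) if isinstance(nodes_source, (str, Path)) else "nodes"
    for lineno, fields in _iter_dmp_rows(nodes_source, "nodes"):
        if len(fields) < 3:
            raise FormatError(
                f"nodes row needs >=3 fields, got {len(fields)}",
                source=src,
                line=lineno,
            )
        t = _parse_taxid(fields[0], src, lineno)
        p = _parse_taxid(fields[1], src, lineno)
        if t in parent:
            raise FormatError(f"duplicate node {t}", source=src, line=lineno)
        parent[t] = p
        raw_rank = fields[2].strip()
        rank_name[t] = raw_rank
        rank[t] = Rank.from_name(raw_rank)

    name: dict[int, str] = {}
    if names_source is not None:
        for lineno, fields in _iter_dmp_rows(names_source, "names"):
            if len(fields) < 2:
                raise FormatError(
                    "names row needs >=2 fields", source="names", line=lineno
                )
            name_class = fields[3].strip() if len(fields) >= 4 else "scientific name"
            if name_class != "scientific name":
                continue
            t = _parse_taxid(fields[0], "names", lineno)
            name[t] = fields[1].strip()

    merged: dict[int, int] = {}
    if merged_source is not None:
        for lineno, fields in _iter_dmp_rows(merged_source, "merged"):
            old = _parse_taxid(fields[0], "merged", lineno)
            new = _parse_taxid(fields[1], "merged", lineno)
            merged[old] = new

    deleted: set[int] = set()
    if deleted_source is not None:
        for lineno, fields in _iter_dmp_rows(deleted_source, "delnodes"):
            deleted.add(_parse_taxid(fields[0], "delnodes", lineno))

    return TaxonomyTree(
        parent, rank, rank_name=rank_name, name=name, merged=merged, deleted=deleted
    )


def simplify(tree: TaxonomyTree) -> TaxonomyTree:
    """Reduce a full tree to root + standard-rank nodes.

    Each retained node is reparented onto its nearest retained ancestor, so
    rank gaps in the source (e.g. a "no rank" clade between superkingdom
    and phylum) collapse without losing the nodes below them.  Idempotent.
    """
    keep = {ROOT_TAXON} | {
        t for t, r in tree.rank.items() if r is not None and r is not Rank.ROOT
    }
    parent: dict[int, int] = {ROOT_TAXON: ROOT_TAXON}
    for t in keep:
        if t == ROOT_TAXON:
            continue
        cur = tree.parent[t]
        while cur not in keep:
            cur = tree.parent[cur]
        parent[t] = cur
    return TaxonomyTree(
        parent,
        {t: tree.rank[t] for t in keep},
        rank_name={t: tree.rank_name.get(t, "") for t in keep},
        name={t: n for t, n in tree.name.items() if t in keep},
        merged=tree.merged,
        deleted=tree.deleted,
        standard_only=True,
    )


def lift_to_standard(full: TaxonomyTree, simplified: TaxonomyTree, taxid: int) -> int:
    """Map an arbitrary classifier-reported taxid onto the backbone.

    Merged IDs are remapped first; a taxid absent from every table degrades
    to the unclassified sentinel 0 with a warning (one stale ID must not
    kill a run).  Otherwise returns the taxid itself if it is already a
    backbone node, else its nearest backbone ancestor (root at worst).
    """
    if taxid == UNCLASSIFIED:
        raise ValueError("taxid 0 is the unclassified sentinel; nothing to lift")
    t = full.resolve(taxid)
    if t in simplified:
        return t
    if t not in full:
        kind = "deleted" if t in full.deleted or taxid in full.deleted else "unknown"
        logger.warning("taxid %d is %s in this taxonomy; treating as unclassified",
                       taxid, kind)
        return UNCLASSIFIED
    cur = t
    while cur not in simplified:
        cur = full.parent[cur]
    return cur


def lineage(simplified: TaxonomyTree, taxid: int) -> tuple[int, ...]:
    """Functional alias for :meth:`TaxonomyTree.lineage`."""
    return simplified.lineage(taxid)


def lca(simplified: TaxonomyTree, a: int, b: int) -> int:
    """Functional alias for :meth:`TaxonomyTree.lca`."""
    return simplified.lca(a, b)


def write_dump(
    tree: TaxonomyTree,
    nodes_sink,
    names_sink=None,
    merged_sink=None,
) -> None:
    """Serialize a tree back to the dump dialect it was read from."""

    def _sink(target):
        if isinstance(target, (str, Path)):
            return open(target, "w", encoding="utf-8"), True
        return target, False

    fh, close = _sink(nodes_sink)
    try:
        for t in sorted(tree.parent):
            r = tree.rank_name.get(t) or (
                tree.rank[t].label if tree.rank.get(t) is not None else "no rank"
            )
            fh.write(f"{t}\t|\t{tree.parent[t]}\t|\t{r}\t|\n")
    finally:
        if close:
            fh.close()
    if names_sink is not None:
        fh, close = _sink(names_sink)
        try:
            for t in sorted(tree.name):
                fh.write(f"{t}\t|\t{tree.name[t]}\t|\t\t|\tscientific name\t|\n")
        finally:
            if close:
                fh.close()
    if merged_sink is not None:
        fh, close = _sink(merged_sink)
        try:
            for old in sorted(tree.merged):
                fh.write(f"{old}\t|\t{tree.merged[old]}\t|\n")
        finally:
            if close:
                fh.close()
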