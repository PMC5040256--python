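"""Reading and writing the per-read votes CSV and the decisions table.

The canonical interchange format is a plain CSV with one row per read: the
read identifier followed by exactly N taxon-ID fields, one per classifier,
where 0 means "that tool did not classify the read".  Adapters from the
common per-read output formats (Kraken-style 5-column TSV, BLAST tabular)
are conveniences that *produce* this table; tool order in the columns is
positional and carries no meaning for the vote itself.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .errors import ConsistencyError, FormatError, UnsupportedFormatError
from .taxonomy import TaxonomyTree, UNCLASSIFIED, lift_to_standard

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadVotes:
    """One read's identifier plus one candidate taxon per tool (0 allowed)."""

    read_id: str
    taxa: tuple[int, ...]

    def __post_init__(self):
        if not self.taxa:
            raise ValueError("a votes row needs at least one tool field")
        if any((not isinstance(t, int)) or t < 0 for t in self.taxa):
            raise ValueError(f"taxa must be non-negative integers: {self.taxa}")
        object.__setattr__(self, "taxa", tuple(self.taxa))

    @property
    def n_tools(self) -> int:
        return len(self.taxa)


def _open_text(source, mode="r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def read_votes_csv(source, expected_n: int | None = None) -> list[ReadVotes]:
    """Parse the votes CSV; order-preserving, validates a constant N.

    Raises :class:`FormatError` (with line number) on ragged rows,
    duplicate read IDs, or non-integer / negative taxon fields.
    """
    fh, close = _open_text(source)
    src = str(source) if close else getattr(source, "name", "<stream>")
    rows: list[ReadVotes] = []
    seen: set[str] = set()
    n: int | None = expected_n
    try:
        for lineno, fields in enumerate(csv.reader(fh), start=1):
            if not fields or (len(fields) == 1 and not fields[0].strip()):
                continue
            if len(fields) < 2:
                raise FormatError(
                    "votes row needs a read id and at least one taxon field",
                    source=src,
                    line=lineno,
                )
            read_id = fields[0].strip()
            if read_id in seen:
                raise FormatError(
                    f"duplicate read id {read_id!r}", source=src, line=lineno
                )
            seen.add(read_id)
            width = len(fields) - 1
            if n is None:
                n = width
            elif width != n:
                raise FormatError(
                    f"expected {n} taxon fields, found {width}",
                    source=src,
                    line=lineno,
                )
            taxa = []
            for f in fields[1:]:
                f = f.strip()
                if not f.isdigit():
                    raise FormatError(
                        f"taxon field {f!r} is not a non-negative integer",
                        source=src,
                        line=lineno,
                    )
                taxa.append(int(f))
            rows.append(ReadVotes(read_id, tuple(taxa)))
    finally:
        if close:
            fh.close()
    return rows


def write_votes_csv(rows: Iterable[ReadVotes], sink) -> None:
    fh, close = _open_text(sink, "w")
    try:
        for row in rows:
            fh.write(",".join([row.read_id, *map(str, row.taxa)]) + "\n")
    finally:
        if close:
            fh.close()


DECISIONS_HEADER = ("read_id", "C", "A", "score", "taxon")


def write_decisions(decisions, sink) -> None:
    """Write the decisions TSV: read_id, C, A, score (6 dp), taxon.

    Byte-deterministic for identical input.
    """
    fh, close = _open_text(sink, "w")
    try:
        fh.write("\t".join(DECISIONS_HEADER) + "\n")
        for d in decisions:
            fh.write(
                f"{d.read_id}\t{d.n_classified}\t{d.n_support}\t"
                f"{float(d.score):.6f}\t{d.taxon}\n"
            )
    finally:
        if close:
            fh.close()


def read_decisions(source):
    """Read a decisions TSV back into records.

    Scores come back as exact 6-decimal rationals (the file's precision).
    A record with taxon 0 but C > 0 is a min-support-suppressed decision
    and is flagged as such.
    """
    from fractions import Fraction

    from .decision import DecisionRecord

    fh, close = _open_text(source)
    src = str(source) if close else getattr(source, "name", "<stream>")
    out = []
    try:
        lines = iter(enumerate(fh, start=1))
        try:
            _, header = next(lines)
        except StopIteration:
            raise FormatError("empty decisions file (no header)", source=src)
        if tuple(header.rstrip("\n").split("\t")) != DECISIONS_HEADER:
            raise FormatError("unexpected decisions header", source=src, line=1)
        for lineno, line in lines:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"expected 5 columns, found {len(fields)}",
                    source=src,
                    line=lineno,
                )
            read_id, c, a, score, taxon = fields
            c, a, taxon = int(c), int(a), int(taxon)
            out.append(
                DecisionRecord(
                    read_id=read_id,
                    taxon=taxon,
                    n_classified=c,
                    n_support=a,
                    score=Fraction(score),
                    below_min_support=(taxon == UNCLASSIFIED and c > 0),
                )
            )
    finally:
        if close:
            fh.close()
    return out


# -- classifier-output adapters ----------------------------------------------


def adapt_kraken(source) -> dict[str, int]:
    """Kraken-style per-read output -> {read_id: taxid}.

    Consumes the first three of the five tab-separated columns
    (status C/U, read id, taxid); U rows map to 0.
    """
    fh, close = _open_text(source)
    src = str(source) if close else getattr(source, "name", "<stream>")
    out: dict[str, int] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    "per-read row needs >=3 tab-separated columns",
                    source=src,
                    line=lineno,
                )
            status, read_id, taxid = fields[0].strip(), fields[1].strip(), fields[2].strip()
            if status not in ("C", "U"):
                raise FormatError(
                    f"status column must be C or U, got {status!r}",
                    source=src,
                    line=lineno,
                )
            if read_id in out:
                raise FormatError(
                    f"duplicate read id {read_id!r}", source=src, line=lineno
                )
            if status == "U":
                out[read_id] = UNCLASSIFIED
            else:
                if not taxid.isdigit():
                    raise FormatError(
                        f"taxid column {taxid!r} is not an integer",
                        source=src,
                        line=lineno,
                    )
                out[read_id] = int(taxid)
    finally:
        if close:
            fh.close()
    return out


def adapt_blast_tabular(
    source,
    taxid_column: int,
    tree: TaxonomyTree | None = None,
    read_universe: Iterable[str] | None = None,
) -> dict[str, int]:
    """BLAST tabular (outfmt 6) -> {query: taxid}, keeping the top hit.

    Per query the FIRST row encountered wins (the top hit under
    ``-max_target_seqs 1``).  A multi-taxid cell ("9;12") resolves to the
    LCA of the listed taxids when a simplified tree containing them all is
    supplied, else to the first listed taxid.  When a read universe is
    given, queries with no hits map to 0.
    """
    fh, close = _open_text(source)
    src = str(source) if close else getattr(source, "name", "<stream>")
    out: dict[str, int] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if taxid_column >= len(fields) or taxid_column < 0:
                raise FormatError(
                    f"taxid column index {taxid_column} out of range "
                    f"(row has {len(fields)} columns)",
                    source=src,
                    line=lineno,
                )
            query = fields[0].strip()
            if query in out:
                continue  # top-hit rule: first row per query wins
            cell = fields[taxid_column].strip()
            ids = []
            for part in cell.split(";"):
                part = part.strip()
                if not part.isdigit():
                    raise FormatError(
                        f"taxid cell {cell!r} is not ';'-separated integers",
                        source=src,
                        line=lineno,
                    )
                ids.append(int(part))
            if not ids:
                raise FormatError("empty taxid cell", source=src, line=lineno)
            if len(ids) > 1 and tree is not None and all(i in tree for i in ids):
                out[query] = tree.lca_many(ids)
            else:
                out[query] = ids[0]
    finally:
        if close:
            fh.close()
    if read_universe is not None:
        full = {r: UNCLASSIFIED for r in read_universe}
        full.update({r: t for r, t in out.items() if r in full})
        return full
    return out


def adapt_metaphlan(*args, **kwargs):
    """Marker-based clade-ID output is not convertible here.

    That format maps reads to clade numbers distinct from taxonomy IDs and
    requires the upstream tool's external clade->taxid lookup table, which
    this package does not ship.
    """
    raise UnsupportedFormatError(
        "clade-ID per-read output requires an external clade-to-taxid lookup "
        "table; convert it upstream and supply the votes CSV instead"
    )


def assemble_votes(
    tool_maps: Sequence[Mapping[str, int]],
    read_ids: Sequence[str] | None = None,
) -> list[ReadVotes]:
    """Column-bind per-tool {read: taxid} maps into a votes table.

    Read order follows ``read_ids`` when given, else first appearance
    across the tool maps.  A read missing from a tool's map votes 0 there.
    """
    if not tool_maps:
        raise ValueError("need at least one tool map")
    if read_ids is None:
        order: dict[str, None] = {}
        for m in tool_maps:
            for r in m:
                order.setdefault(r)
        read_ids = list(order)
    return [
        ReadVotes(r, tuple(m.get(r, UNCLASSIFIED) for m in tool_maps))
        for r in read_ids
    ]


def lift_votes(
    rows: Iterable[ReadVotes],
    full: TaxonomyTree,
    simplified: TaxonomyTree,
) -> tuple[list[ReadVotes], dict[str, int]]:
    """Remap merged IDs and lift every nonzero vote onto the backbone.

    Returns the lifted table plus counters: ``lifted`` (votes moved to an
    ancestor), ``unknown`` (votes degraded to 0).
    """
    stats = {"lifted": 0, "unknown": 0}
    out: list[ReadVotes] = []
    for row in rows:
        taxa = []
        for t in row.taxa:
            if t == UNCLASSIFIED:
                taxa.append(t)
                continue
            lifted = lift_to_standard(full, simplified, t)
            if lifted == UNCLASSIFIED:
                stats["unknown"] += 1
            elif lifted != t:
                stats["lifted"] += 1
            taxa.append(lifted)
        out.append(ReadVotes(row.read_id, tuple(taxa)))
    return out, stats
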