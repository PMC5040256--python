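"""Per-rank relative-abundance profiles from per-read decisions.

Counting is *cumulative over clades*: a read decided at a species supports
that species' genus, family, and so on, so at each reporting level the
read contributes to the level-``l`` ancestor of its decision taxon
whenever its decision lineage reaches that level.  Reads decided above
the level, at the root, or unclassified contribute nothing at that level.

Two normalizations are provided:

* genomic-based (default): counts divided by n, the total number of reads —
  appropriate for classifiers meant to annotate every read;
* marker-based: counts divided by n_c, the number of classified reads
  (taxon not 0 and not root) — the convention of marker-gene profilers
  that only ever annotate reads hitting their curated database.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .decision import DecisionRecord
from .errors import UndefinedMetricError
from .taxonomy import ROOT_TAXON, Rank, STANDARD_RANKS, TaxonomyTree, UNCLASSIFIED

GENOMIC = "genomic"
MARKER = "marker"
MODES = (GENOMIC, MARKER)


@dataclass(frozen=True)
class AbundanceProfile:
    level: Rank
    mode: str
    n_reads: int
    n_classified: int
    counts: Mapping[int, int]
    abundance: Mapping[int, float]


def count_at_level(
    decisions: Iterable[DecisionRecord],
    simplified: TaxonomyTree,
    level: Rank,
) -> dict[int, int]:
    """Reads per taxon at ``level``, via lineage truncation (cumulative)."""
    counts: Counter[int] = Counter()
    for d in decisions:
        if d.taxon in (UNCLASSIFIED, ROOT_TAXON):
            continue
        node = simplified.ancestor_at(d.taxon, level)
        if node is not None:
            counts[node] += 1
    return dict(counts)


def n_classified(decisions: Sequence[DecisionRecord]) -> int:
    """Reads carrying standard-rank information (taxon not 0, not root)."""
    return sum(1 for d in decisions if d.taxon not in (UNCLASSIFIED, ROOT_TAXON))


def profile(
    decisions: Sequence[DecisionRecord],
    simplified: TaxonomyTree,
    level: Rank,
    mode: str = GENOMIC,
) -> AbundanceProfile:
    """Relative abundances at one rank under the chosen normalization."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    n = len(decisions)
    if n < 1:
        raise UndefinedMetricError("cannot profile an empty decision table")
    n_c = n_classified(decisions)
    counts = count_at_level(decisions, simplified, level)
    if mode == MARKER:
        if n_c == 0:
            raise UndefinedMetricError(
                "marker-based profile undefined: no classified reads"
            )
        denom = n_c
    else:
        denom = n
    return AbundanceProfile(
        level=level,
        mode=mode,
        n_reads=n,
        n_classified=n_c,
        counts=counts,
        abundance={t: k / denom for t, k in counts.items()},
    )


def all_profiles(
    decisions: Sequence[DecisionRecord],
    simplified: TaxonomyTree,
    mode: str = GENOMIC,
) -> list[AbundanceProfile]:
    """One profile per standard rank, shallowest first."""
    return [profile(decisions, simplified, level, mode) for level in STANDARD_RANKS]


def write_profiles(
    profiles: Iterable[AbundanceProfile],
    sink,
    simplified: TaxonomyTree | None = None,
) -> None:
    """Stacked TSV: level, taxid, name, count, relative_abundance."""
    close = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8") if close else sink
    try:
        fh.write("level\ttaxid\tname\tcount\trelative_abundance\n")
        for p in profiles:
            for taxid in sorted(p.counts):
                name = simplified.name.get(taxid, "") if simplified else ""
                fh.write(
                    f"{p.level.label}\t{taxid}\t{name}\t{p.counts[taxid]}\t"
                    f"{p.abundance[taxid]:.6f}\n"
                )
    finally:
        if close:
            fh.close()
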