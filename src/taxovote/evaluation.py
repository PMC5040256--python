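"""Scoring predicted decisions against a read-level truth table.

Per rank ``l``, both the true and the predicted taxon of each read are
truncated to their ancestor at ``l``:

* P_l   — reads whose *truth* reaches the level;
* TP_l  — reads where both reach it and the truncated taxa agree;
* FP_l  — reads whose *prediction* reaches it but is wrong there (either
  the truth stops above the level, or the taxa differ).

``sensitivity(l) = TP_l / P_l`` and ``precision(l) = TP_l / (TP_l + FP_l)``.
A prediction that stops above the level is an abstention — neither TP nor
FP — which is exactly how a consensus that retreats to a safe ancestor
differs from a classifier that guesses wrong.

Profile deviation is measured by the Hellinger distance

    H = sqrt( sum_x (sqrt(P_x) - sqrt(T_x))^2 / 2 )

over the union of taxa in the two profiles (missing taxa at abundance 0);
H = 0 for identical profiles, H = 1 for disjoint unit-mass profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .abundance import GENOMIC, MARKER, AbundanceProfile, profile
from .decision import DecisionRecord
from .errors import ConsistencyError, FormatError, UndefinedMetricError
from .taxonomy import ROOT_TAXON, Rank, STANDARD_RANKS, TaxonomyTree, UNCLASSIFIED


@dataclass(frozen=True)
class LevelCounts:
    level: Rank
    p: int
    tp: int
    fp: int

    def __post_init__(self):
        if min(self.p, self.tp, self.fp) < 0 or self.tp > self.p:
            raise ValueError(f"inconsistent level counts: {self}")


def _truncate(simplified: TaxonomyTree, taxid: int, level: Rank) -> int | None:
    if taxid in (UNCLASSIFIED, ROOT_TAXON):
        return None
    return simplified.ancestor_at(taxid, level)


def level_counts(
    truth: Mapping[str, int],
    decisions: Iterable[DecisionRecord],
    simplified: TaxonomyTree,
    level: Rank,
) -> LevelCounts:
    """Tally P/TP/FP at one rank; every decided read must appear in truth."""
    p = tp = fp = 0
    for d in decisions:
        if d.read_id not in truth:
            raise ConsistencyError(f"read {d.read_id!r} missing from truth table")
        t_node = _truncate(simplified, truth[d.read_id], level)
        p_node = _truncate(simplified, d.taxon, level)
        if t_node is not None:
            p += 1
        if p_node is not None:
            if p_node == t_node:
                tp += 1
            else:
                fp += 1
    return LevelCounts(level=level, p=p, tp=tp, fp=fp)


def sensitivity(counts: LevelCounts) -> float:
    if counts.p == 0:
        raise UndefinedMetricError(
            f"sensitivity undefined at {counts.level.label}: no truth reads there"
        )
    return counts.tp / counts.p


def precision(counts: LevelCounts) -> float:
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError(
            f"precision undefined at {counts.level.label}: no predictions there"
        )
    return counts.tp / (counts.tp + counts.fp)


def hellinger(predicted, truth) -> float:
    """Hellinger distance between two same-level abundance profiles.

    Accepts :class:`AbundanceProfile` objects or plain taxid->abundance
    mappings; symmetric; 0 <= H <= 1 whenever each profile sums to <= 1.
    """
    p = predicted.abundance if isinstance(predicted, AbundanceProfile) else predicted
    t = truth.abundance if isinstance(truth, AbundanceProfile) else truth
    if (
        isinstance(predicted, AbundanceProfile)
        and isinstance(truth, AbundanceProfile)
        and predicted.level is not truth.level
    ):
        raise ValueError(
            f"profiles are at different levels: {predicted.level.label} vs "
            f"{truth.level.label}"
        )
    acc = 0.0
    for x in set(p) | set(t):
        px, tx = p.get(x, 0.0), t.get(x, 0.0)
        if px < 0 or tx < 0:
            raise ValueError(f"negative abundance for taxon {x}")
        acc += (math.sqrt(px) - math.sqrt(tx)) ** 2
    return math.sqrt(acc / 2.0)


# -- whole-table evaluation --------------------------------------------------


@dataclass(frozen=True)
class EvaluationRow:
    level: Rank
    counts: LevelCounts
    sensitivity: float | None
    precision: float | None
    hellinger_genomic: float
    hellinger_marker: float | None


def _truth_decisions(truth: Mapping[str, int], n_tools: int) -> list[DecisionRecord]:
    from fractions import Fraction

    one = Fraction(1)
    return [
        DecisionRecord(r, t, n_tools, n_tools, one) for r, t in truth.items()
    ]


def evaluate_decisions(
    truth: Mapping[str, int],
    decisions: Sequence[DecisionRecord],
    simplified: TaxonomyTree,
) -> list[EvaluationRow]:
    """Per-rank report over all seven standard ranks.

    Undefined sensitivity/precision cells (zero denominators) are reported
    as None; the per-metric functions raise instead, so empty-level bugs
    can still be caught where a value is demanded.
    """
    decided_ids = {d.read_id for d in decisions}
    truth = {r: t for r, t in truth.items() if r in decided_ids}
    truth_recs = _truth_decisions(truth, n_tools=1)
    rows: list[EvaluationRow] = []
    for level in STANDARD_RANKS:
        counts = level_counts(truth, decisions, simplified, level)
        sens = sensitivity(counts) if counts.p else None
        prec = precision(counts) if counts.tp + counts.fp else None
        h_gen = hellinger(
            profile(decisions, simplified, level, GENOMIC),
            profile(truth_recs, simplified, level, GENOMIC),
        )
        try:
            h_mark = hellinger(
                profile(decisions, simplified, level, MARKER),
                profile(truth_recs, simplified, level, MARKER),
            )
        except UndefinedMetricError:
            h_mark = None
        rows.append(
            EvaluationRow(level, counts, sens, prec, h_gen, h_mark)
        )
    return rows


def read_truth(source) -> dict[str, int]:
    """Two-column TSV read_id -> taxid, order-preserving."""
    close = isinstance(source, (str, Path))
    fh = open(source, "r", encoding="utf-8") if close else source
    src = str(source) if close else getattr(source, "name", "<stream>")
    truth: dict[str, int] = {}
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"truth row needs 2 columns, found {len(fields)}",
                    source=src,
                    line=lineno,
                )
            read_id, taxid = fields[0].strip(), fields[1].strip()
            if read_id in truth:
                raise FormatError(
                    f"duplicate read id {read_id!r}", source=src, line=lineno
                )
            if not taxid.isdigit():
                raise FormatError(
                    f"taxid {taxid!r} is not a non-negative integer",
                    source=src,
                    line=lineno,
                )
            truth[read_id] = int(taxid)
    finally:
        if close:
            fh.close()
    return truth


def write_report(rows: Iterable[EvaluationRow], sink) -> None:
    """Report TSV: level, P, TP, FP, sensitivity, precision, H columns."""

    def fmt(v):
        return "NA" if v is None else f"{v:.6f}"

    close = isinstance(sink, (str, Path))
    fh = open(sink, "w", encoding="utf-8") if close else sink
    try:
        fh.write(
            "level\tP\tTP\tFP\tsensitivity\tprecision\t"
            "hellinger_genomic\thellinger_marker\n"
        )
        for row in rows:
            c = row.counts
            fh.write(
                f"{row.level.label}\t{c.p}\t{c.tp}\t{c.fp}\t"
                f"{fmt(row.sensitivity)}\t{fmt(row.precision)}\t"
                f"{fmt(row.hellinger_genomic)}\t{fmt(row.hellinger_marker)}\n"
            )
    finally:
        if close:
            fh.close()
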