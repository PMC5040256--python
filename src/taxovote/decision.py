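"""The weighted-voting consensus core.

For each read, the nonzero votes are laid onto the simplified taxonomy:
every node receives a weight equal to the number of tools whose reported
taxon's lineage passes through it (so the root's weight is C, the number
of tools that classified the read).  The consensus taxon is the node that

* has weight strictly greater than ``floor(C / 2)``, and
* maximizes the summed weight along its root-to-node path,

with ties at the maximum resolved to the lowest common ancestor of all
tied nodes.  The confidence score is ``A/N`` when all C classifying tools
support the decision (A == C), and ``A/N - 1/(m*N)`` otherwise, where the
penalty constant m > 1 (default 2) controls how strongly disagreement
among classifying tools is penalized; with m = 2 the penalized score sits
exactly mid-way between ``(A-1)/N`` and ``A/N``.  A read no tool
classified gets taxon 0 with score 1 and A reported as N.

Scores are exact rationals internally; serialization rounds to 6 decimals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Sequence

from .errors import TaxovoteError, UnknownTaxonError
from .taxonomy import ROOT_TAXON, TaxonomyTree, UNCLASSIFIED
from .votes_io import ReadVotes


@dataclass(frozen=True)
class VotingParams:
    """Ensemble-wide voting parameters.

    n_tools
        N, the number of classifiers in the pipeline (>= 1).
    m
        Disagreement penalty constant, > 1; default 2.
    """

    n_tools: int
    m: Fraction = Fraction(2)

    def __post_init__(self):
        if self.n_tools < 1:
            raise ValueError(f"n_tools must be >= 1, got {self.n_tools}")
        m = self.m if isinstance(m_val := self.m, Rational) else Fraction(str(m_val))
        object.__setattr__(self, "m", Fraction(m))
        if self.m <= 1:
            raise ValueError(f"penalty constant m must be > 1, got {self.m}")


@dataclass(frozen=True)
class DecisionRecord:
    """Per-read consensus output.

    ``n_classified`` is C (tools with a nonzero vote), ``n_support`` is A
    (tools whose vote's lineage contains the decision taxon); N >= C >= A
    except in the C == 0 sentinel case, where A is reported as N.
    """

    read_id: str
    taxon: int
    n_classified: int
    n_support: int
    score: Fraction
    below_min_support: bool = False


@dataclass(frozen=True)
class WeightedTree:
    """Per-read sparse weight map over backbone nodes.

    ``weight[v]`` counts the vote taxa whose lineage contains v; only nodes
    with weight >= 1 are present.  ``n_classified`` is C.
    """

    weight: dict[int, int]
    n_classified: int

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.weight


def build_weighted_tree(
    simplified: TaxonomyTree, vote_taxa: Sequence[int]
) -> WeightedTree:
    """Accumulate lineage weights for a read's nonzero votes.

    Every taxon must already be a backbone node (lifting is the caller's
    job); 0 is rejected.
    """
    weight: Counter[int] = Counter()
    for t in vote_taxa:
        if t == UNCLASSIFIED:
            raise ValueError("vote taxon 0 cannot enter the weighted tree")
        weight.update(simplified.lineage(t))  # raises UnknownTaxonError if absent
    return WeightedTree(dict(weight), n_classified=len(vote_taxa))


def root_to_taxon(wtree: WeightedTree, simplified: TaxonomyTree, v: int) -> int:
    """Summed weight along the path root -> v, excluding the root itself.

    The root weighs C for every candidate alike, so leaving it out cannot
    change any argmax or tie set; what remains is a depth-times-support
    score.
    """
    if v not in wtree.weight:
        raise UnknownTaxonError(v)
    return sum(wtree.weight[n] for n in simplified.lineage(v)[1:])


def decide_read(
    votes: ReadVotes, simplified: TaxonomyTree, params: VotingParams
) -> DecisionRecord:
    """Run the per-read decision scheme (see module docstring)."""
    if votes.n_tools != params.n_tools:
        raise TaxovoteError(
            f"read {votes.read_id!r} has {votes.n_tools} votes but the "
            f"pipeline is configured for N={params.n_tools}"
        )
    n = params.n_tools
    nonzero = [t for t in votes.taxa if t != UNCLASSIFIED]
    c = len(nonzero)
    if c == 0:
        # Sentinel branch: unclassified read, score 1, A reported as N.
        return DecisionRecord(votes.read_id, UNCLASSIFIED, 0, n, Fraction(1))

    wtree = build_weighted_tree(simplified, nonzero)
    threshold = c // 2
    best: int | None = None
    best_rtt = -1
    for node, w in wtree.weight.items():
        if w <= threshold:
            continue
        rtt = root_to_taxon(wtree, simplified, node)
        if best is None or rtt > best_rtt:
            best, best_rtt = node, rtt
        elif rtt == best_rtt:
            # Tie at the running maximum: fold into the LCA.  Ties only
            # arise between incomparable nodes (path sums strictly grow
            # along a lineage), so the fold is order-independent.
            best = simplified.lca(node, best)
    assert best is not None  # root always passes: weight(root)=C > floor(C/2)
    a = wtree.weight[best]
    if a == c:
        score = Fraction(a, n)
    else:
        score = Fraction(a, n) - 1 / (params.m * n)
    return DecisionRecord(votes.read_id, best, c, a, score)


def decide_all(
    votes_table: Iterable[ReadVotes],
    simplified: TaxonomyTree,
    params: VotingParams,
) -> list[DecisionRecord]:
    """Order-preserving map of :func:`decide_read` over a votes table.

    Each row is decided independently, so results do not depend on row
    order or batching; row-level errors are re-raised with the read id.
    """
    out: list[DecisionRecord] = []
    for row in votes_table:
        try:
            out.append(decide_read(row, simplified, params))
        except (UnknownTaxonError, ValueError) as exc:
            raise TaxovoteError(f"read {row.read_id!r}: {exc}") from exc
    return out


def apply_min_support(
    decisions: Iterable[DecisionRecord], min_support: int
) -> list[DecisionRecord]:
    """Suppress decisions supported by fewer than ``min_support`` tools.

    A classified record (C > 0) with A < min_support becomes unclassified
    (taxon 0) but keeps its A and score for audit, and is flagged.
    Raising the threshold trades sensitivity for precision.
    """
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    out: list[DecisionRecord] = []
    for d in decisions:
        if d.n_classified > 0 and d.n_support < min_support:
            out.append(replace(d, taxon=UNCLASSIFIED, below_min_support=True))
        else:
            out.append(d)
    return out
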