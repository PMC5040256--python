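"""Toy taxonomies and simulated per-tool votes with controllable errors.

Nothing here touches read sequences: upstream classifiers are emulated at
the *annotation* level, which is all the voting consensus ever sees.  Each
simulated tool draws, independently per read given the true species:

* with probability ``1 - p_classify``: no call (vote 0);
* else with probability ``p_correct_species``: the true species;
* else an error drawn from ``rank_escalation``, a distribution over
  (rank, kind) pairs where kind ``"ancestor"`` emits the true lineage's
  ancestor at that rank (a conservative, under-resolved call) and kind
  ``"sibling"`` emits a uniformly random wrong sibling at that rank (a
  false positive).  A sibling draw at a rank with no siblings falls back
  to the ancestor call.

This is enough to reproduce the characteristic contrast between
similarity-search classifiers (classify nearly everything, errors are
mostly wrong species) and k-mer classifiers (abstain more, but precise),
and hence to exercise the consensus, abundance and evaluation machinery
end to end.  All randomness flows through one ``random.Random(seed)`` per
simulation call; no global state.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .taxonomy import (
    ROOT_TAXON,
    Rank,
    STANDARD_RANKS,
    TaxonomyTree,
    simplify,
)
from .votes_io import ReadVotes, write_votes_csv

logger = logging.getLogger(__name__)

#: Per-rank child counts superkingdom..species used by default fixtures.
DEFAULT_BRANCHING = (2, 2, 2, 1, 2, 3, 4)


@dataclass(frozen=True)
class ToolErrorModel:
    """Annotation-level error model for one simulated classifier."""

    name: str
    p_classify: float
    p_correct_species: float
    rank_escalation: Mapping[tuple[Rank, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.p_classify <= 1.0:
            raise ValueError(f"p_classify out of [0,1]: {self.p_classify}")
        if not 0.0 <= self.p_correct_species <= 1.0:
            raise ValueError(
                f"p_correct_species out of [0,1]: {self.p_correct_species}"
            )
        esc = dict(self.rank_escalation)
        for (rank, kind), mass in esc.items():
            if rank not in STANDARD_RANKS:
                raise ValueError(f"rank_escalation rank must be standard: {rank}")
            if kind not in ("ancestor", "sibling"):
                raise ValueError(f"rank_escalation kind must be ancestor|sibling: {kind}")
            if mass < 0:
                raise ValueError(f"negative escalation mass for ({rank}, {kind})")
        total = sum(esc.values())
        if self.p_classify > 0 and self.p_correct_species < 1:
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"rank_escalation masses must sum to 1, got {total}"
                )
        object.__setattr__(self, "rank_escalation", esc)


@dataclass(frozen=True)
class SyntheticDataset:
    full: TaxonomyTree
    simplified: TaxonomyTree
    truth: dict[str, int]
    votes: list[ReadVotes]
    models: tuple[ToolErrorModel, ...]


def default_models() -> list[ToolErrorModel]:
    """One sensitive-but-noisy tool plus two precise-but-conservative ones.

    The first emulates a similarity-search classifier: it calls 98% of
    reads and, when wrong, mostly reports a wrong sibling species (a false
    positive).  The other two emulate k-mer classifiers: they abstain on
    20% of reads but are right 97% of the time when they call, with the
    remaining errors split between under-resolved ancestor calls and the
    occasional wrong species.
    """
    similarity = ToolErrorModel(
        name="similarity",
        p_classify=0.98,
        p_correct_species=0.80,
        rank_escalation={
            (Rank.SPECIES, "sibling"): 0.70,
            (Rank.GENUS, "sibling"): 0.10,
            (Rank.GENUS, "ancestor"): 0.10,
            (Rank.FAMILY, "ancestor"): 0.10,
        },
    )
    kmer_escalation = {
        (Rank.SPECIES, "sibling"): 0.40,
        (Rank.GENUS, "ancestor"): 0.40,
        (Rank.FAMILY, "ancestor"): 0.20,
    }
    return [
        similarity,
        ToolErrorModel("kmer-a", 0.80, 0.97, kmer_escalation),
        ToolErrorModel("kmer-b", 0.80, 0.97, kmer_escalation),
    ]


def make_toy_taxonomy(
    branching: Sequence[int] = DEFAULT_BRANCHING,
    seed: int = 0,
    strains_per_species: int = 0,
) -> TaxonomyTree:
    """Complete 8-level tree: root plus ``branching[i]`` children per node
    at each standard rank, superkingdom first.

    ``strains_per_species`` > 0 additionally hangs that many "no rank"
    strain children below every species in the returned (full) tree; they
    disappear under :func:`taxonomy.simplify`.  Construction is
    deterministic; ``seed`` is accepted for interface stability.
    """
    del seed  # structure is fully determined by branching
    if len(branching) != len(STANDARD_RANKS):
        raise ValueError(
            f"branching needs {len(STANDARD_RANKS)} per-rank counts, "
            f"got {len(branching)}"
        )
    if any(b < 1 for b in branching):
        raise ValueError("branching counts must all be >= 1")
    parent: dict[int, int] = {ROOT_TAXON: ROOT_TAXON}
    rank: dict[int, Rank | None] = {ROOT_TAXON: Rank.ROOT}
    rank_name: dict[int, str] = {ROOT_TAXON: "root"}
    name: dict[int, str] = {ROOT_TAXON: "root"}
    next_id = 2
    frontier = [ROOT_TAXON]
    for level, n_children in zip(STANDARD_RANKS, branching):
        new_frontier = []
        counter = 0
        for p in frontier:
            for _ in range(n_children):
                counter += 1
                t = next_id
                next_id += 1
                parent[t] = p
                rank[t] = level
                rank_name[t] = level.label
                name[t] = f"{level.label[:2]}{counter}"
                new_frontier.append(t)
        frontier = new_frontier
    if strains_per_species:
        for i, sp in enumerate(list(frontier), start=1):
            for j in range(1, strains_per_species + 1):
                t = next_id
                next_id += 1
                parent[t] = sp
                rank[t] = None
                rank_name[t] = "no rank"
                name[t] = f"{name[sp]}_strain{j}"
    return TaxonomyTree(parent, rank, rank_name=rank_name, name=name)


def species_nodes(simplified: TaxonomyTree) -> list[int]:
    return sorted(t for t, r in simplified.rank.items() if r is Rank.SPECIES)


def make_truth(
    simplified: TaxonomyTree,
    n_reads: int,
    seed: int = 0,
    read_prefix: str = "read",
) -> dict[str, int]:
    """Uniformly assign ``n_reads`` reads to species of the tree."""
    rng = random.Random(seed)
    species = species_nodes(simplified)
    if not species:
        raise ValueError("taxonomy has no species-rank nodes")
    width = len(str(max(n_reads, 1)))
    return {
        f"{read_prefix}{i:0{width}d}": rng.choice(species)
        for i in range(1, n_reads + 1)
    }


def _siblings_at(simplified: TaxonomyTree, node: int, level: Rank) -> list[int]:
    anc = simplified.ancestor_at(node, level)
    if anc is None:
        return []
    return [
        c
        for c in simplified.children(simplified.parent[anc])
        if c != anc and simplified.rank[c] is level
    ]


def _draw_vote(
    rng: random.Random,
    simplified: TaxonomyTree,
    true_species: int,
    model: ToolErrorModel,
) -> int:
    if rng.random() >= model.p_classify:
        return 0
    if rng.random() < model.p_correct_species:
        return true_species
    choices = list(model.rank_escalation.items())
    keys = [k for k, _ in choices]
    level, kind = rng.choices(keys, weights=[w for _, w in choices])[0]
    anc = simplified.ancestor_at(true_species, level)
    if anc is None:  # rank gap in an exotic taxonomy; degrade to a no-call
        return 0
    if kind == "ancestor":
        return anc
    sibs = _siblings_at(simplified, true_species, level)
    if not sibs:
        logger.debug(
            "no %s-level siblings for taxon %d; falling back to ancestor",
            level.label,
            true_species,
        )
        return anc
    return rng.choice(sibs)


def simulate_votes(
    full: TaxonomyTree,
    truth: Mapping[str, int],
    models: Sequence[ToolErrorModel],
    seed: int = 0,
    simplified: TaxonomyTree | None = None,
) -> SyntheticDataset:
    """Simulate a votes table over ``truth`` for the given tool models.

    Votes stream in truth order; reproducible per seed.
    """
    if not truth:
        raise ValueError("truth table is empty")
    if not models:
        raise ValueError("need at least one tool model")
    if simplified is None:
        simplified = simplify(full)
    rng = random.Random(seed)
    votes = [
        ReadVotes(
            read_id,
            tuple(_draw_vote(rng, simplified, sp, m) for m in models),
        )
        for read_id, sp in truth.items()
    ]
    return SyntheticDataset(
        full=full,
        simplified=simplified,
        truth=dict(truth),
        votes=votes,
        models=tuple(models),
    )


def make_dataset(
    n_reads: int = 10_000,
    branching: Sequence[int] = DEFAULT_BRANCHING,
    models: Sequence[ToolErrorModel] | None = None,
    seed: int = 0,
    strains_per_species: int = 0,
) -> SyntheticDataset:
    """Taxonomy + truth + votes in one call (the standard study setup)."""
    if models is None:
        models = default_models()
    full = make_toy_taxonomy(
        branching, seed=seed, strains_per_species=strains_per_species
    )
    simplified = simplify(full)
    truth = make_truth(simplified, n_reads, seed=seed + 1)
    return simulate_votes(full, truth, models, seed=seed + 2, simplified=simplified)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Emit the dataset in the exact dialects the pipeline consumes.

    Writes ``taxonomy/nodes.dmp``, ``taxonomy/names.dmp``, ``votes.csv``
    and ``truth.tsv`` under ``outdir``; returns the paths.
    """
    from .taxonomy import write_dump

    outdir = Path(outdir)
    taxdir = outdir / "taxonomy"
    taxdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": taxdir / "nodes.dmp",
        "names": taxdir / "names.dmp",
        "votes": outdir / "votes.csv",
        "truth": outdir / "truth.tsv",
    }
    write_dump(dataset.full, paths["nodes"], names_sink=paths["names"])
    write_votes_csv(dataset.votes, paths["votes"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        for read_id, taxid in dataset.truth.items():
            fh.write(f"{read_id}\t{taxid}\n")
    return paths
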