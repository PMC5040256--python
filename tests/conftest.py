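import random

import pytest
from hypothesis import settings

import taxovote as tv
from taxovote.votes_io import ReadVotes

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chain_tree():
    """Single root-to-species chain: one node per rank (8 nodes)."""
    full = tv.make_toy_taxonomy((1,) * 7)
    return full, tv.simplify(full)


@pytest.fixture(scope="session")
def fixture_tree():
    """23-node complete taxonomy: 2 superkingdoms, 2 genera/family,
    2 species/genus (branching 2,1,1,1,1,2,2)."""
    full = tv.make_toy_taxonomy((2, 1, 1, 1, 1, 2, 2))
    return full, tv.simplify(full)


@pytest.fixture(scope="session")
def simp(fixture_tree):
    return fixture_tree[1]


def rank_nodes(tree, rank):
    return sorted(t for t, r in tree.rank.items() if r is rank)


def votes(*taxa, read_id="r"):
    return ReadVotes(read_id, tuple(taxa))


# -- independent brute-force referee for the decision scheme -----------------


def referee_decide(vote_taxa, tree, n_tools, m=2, include_root_weight=False):
    """Literal line-by-line re-statement of the decision scheme.

    Enumerates EVERY node of the tree, computes its weight by counting
    vote-lineage membership, then applies the thresholded root-to-node
    maximization with LCA tie-breaking and the two-branch scoring rule.
    Kept deliberately naive and independent of the package's weighted-tree
    data path.  ``include_root_weight`` switches whether the root's own
    weight joins the path sum (provably decision-neutral).
    """
    from fractions import Fraction

    nonzero = [t for t in vote_taxa if t != 0]
    c = len(nonzero)
    if c == 0:
        return (0, n_tools, Fraction(1))
    anc = {t: set(tree.lineage(t)) for t in set(nonzero)}
    weight = {}
    for node in tree.parent:
        w = sum(1 for t in nonzero if node in anc[t])
        if w > 0:
            weight[node] = w
    threshold = c // 2
    start = 0 if include_root_weight else 1
    max_weight = None
    max_taxon = None
    for node in weight:  # insertion order = tree enumeration order
        if weight[node] <= threshold:
            continue
        rtt = sum(weight.get(a, 0) for a in tree.lineage(node)[start:])
        if max_weight is None or rtt > max_weight:
            max_weight, max_taxon = rtt, node
        elif rtt == max_weight:
            max_taxon = tree.lca(node, max_taxon)
    a = weight[max_taxon]
    m = Fraction(m)
    score = Fraction(a, n_tools) if a == c else Fraction(a, n_tools) - 1 / (m * n_tools)
    return (max_taxon, a, score)


@pytest.fixture(scope="session")
def referee():
    return referee_decide
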