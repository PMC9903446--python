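import numpy as np
import pytest

from cmschimera import make_reference, published_design, simulate_survey
from cmschimera.phylo import Node, PhyloTree


@pytest.fixture(scope="session")
def ref():
    return make_reference(seed=11)


@pytest.fixture(scope="session")
def refs_dict(ref):
    return {
        "b_atp6": ref.b_atp6,
        "ds": ref.ds,
        "gsv_ref": ref.gsv,
        "coxii_prefix": ref.coxii_prefix,
    }


@pytest.fixture(scope="session")
def survey(ref):
    return simulate_survey(published_design(ref, seed=11), ref)


@pytest.fixture(scope="session")
def pop_map(survey):
    return {r.id: r.population for r in survey.bundle.records}


def balanced_six_taxon_tree():
    """A 6-taxon unrooted tree with informative internal branches."""
    return PhyloTree(
        Node(
            children=[
                Node(children=[Node("A", 0.12), Node("B", 0.15)], length=0.08),
                Node(children=[Node("C", 0.11), Node("D", 0.18)], length=0.09),
                Node(children=[Node("E", 0.20), Node("F", 0.10)], length=0.07),
            ]
        )
    )


def random_resolved_tree(labels, rng, blen=(0.05, 0.3)):
    """Random binary unrooted tree over the labels with uniform branch lengths."""
    nodes = [Node(l, float(rng.uniform(*blen))) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = Node(
            children=[nodes[i], nodes[j]], length=float(rng.uniform(*blen))
        )
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return PhyloTree(Node(children=nodes))


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
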