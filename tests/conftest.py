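"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from termspec import OntologyDAG, SyntheticSpec, build_dag, figure1_fixture, generate


def transitive_closure_oracle(dag: OntologyDAG) -> dict[str, dict[str, set[str]]]:
    """Ancestor/offspring sets by boolean matrix squaring.

    Independent of the package traversals: builds the child->parent adjacency
    matrix and squares ``(A | I)`` until fixpoint, then reads reachability
    off the closed matrix.
    """
    ids = sorted(t.term_id for t in dag.active_terms())
    idx = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for t in ids:
        for p in dag.terms[t].parents:
            adj[idx[t], idx[p]] = True
    closure = adj | np.eye(n, dtype=bool)
    while True:
        nxt = closure @ closure
        if (nxt == closure).all():
            break
        closure = nxt
    reach = closure & ~np.eye(n, dtype=bool)
    return {
        t: {
            "ancestors": {ids[j] for j in np.flatnonzero(reach[idx[t]])},
            "offspring": {ids[j] for j in np.flatnonzero(reach[:, idx[t]])},
        }
        for t in ids
    }


@pytest.fixture
def fig1():
    return figure1_fixture()


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    return build_dag([("Z", "X"), ("Z", "Y"), ("X", "R"), ("Y", "R")], root_id="R")


@pytest.fixture
def chain_dag() -> OntologyDAG:
    return build_dag([("A", "R"), ("B", "A")], root_id="R")


@pytest.fixture(params=[1, 7, 23, 101])
def seeded_instance(request):
    spec = SyntheticSpec(n_terms=50, max_parents_per_term=3, n_units=80, seed=request.param)
    return generate(spec)


IMPLEMENTATION_OBO = """\
format-version: 1.2

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0005488
name: binding
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0005515
name: protein binding
namespace: molecular_function
is_a: GO:0005488

[Term]
id: GO:0005518
name: collagen binding
namespace: molecular_function
is_a: GO:0005515

[Term]
id: GO:0070052
name: collagen V binding
namespace: molecular_function
is_a: GO:0005518
"""


@pytest.fixture
def implementation_dag():
    from termspec import parse_obo

    return parse_obo(IMPLEMENTATION_OBO)
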