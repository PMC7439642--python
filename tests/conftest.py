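"""Shared fixtures: toy instances and simulated instance batches."""

from __future__ import annotations

import pytest

from gtcons.gene_tree import read_labeled_gene_tree
from gtcons.simulate import SimulationParams, fig1_fixture, simulate_instance

TRANSFER_TOY_NHX = (
    "((a[&&NHX:S=A],b[&&NHX:S=B])[&&NHX:ev=S],c[&&NHX:S=C:xfer=1])[&&NHX:ev=T];"
)

# duplication root over two speciation subtrees encoding AB|C and BC|A
INCOMPATIBLE_TOY_NHX = (
    "(((a1[&&NHX:S=A],b1[&&NHX:S=B])[&&NHX:ev=S],c1[&&NHX:S=C])[&&NHX:ev=S],"
    "((b2[&&NHX:S=B],c2[&&NHX:S=C])[&&NHX:ev=S],a2[&&NHX:S=A])[&&NHX:ev=S])"
    "[&&NHX:ev=D];"
)


@pytest.fixture(scope="session")
def fig1():
    return fig1_fixture()


@pytest.fixture(scope="session")
def transfer_toy():
    return read_labeled_gene_tree(TRANSFER_TOY_NHX)


@pytest.fixture(scope="session")
def incompatible_toy():
    return read_labeled_gene_tree(INCOMPATIBLE_TOY_NHX)


def simulated_batch(count, seed0, **kw):
    """Deterministic list of simulated (gene tree, witness species tree)."""
    out = []
    for i in range(count):
        params = SimulationParams(seed=seed0 + i, **{
            k: (v(i) if callable(v) else v) for k, v in kw.items()
        })
        out.append(simulate_instance(params))
    return out


@pytest.fixture(scope="session")
def small_batch():
    """60 instances with 4-8 species for module-level property tests."""
    return simulated_batch(60, 9100, n_species=lambda i: 4 + i % 5)
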