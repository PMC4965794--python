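from __future__ import annotations

import textwrap

import pytest

from esnpo import ontology
from esnpo.synthdata import FixtureSpec, generate_fixture

TOY_OBO = textwrap.dedent(
    """\
    format-version: 1.2
    ontology: toy

    [Term]
    id: GO:0000001
    name: bp root
    namespace: biological_process

    [Term]
    id: GO:0000002
    name: mf root
    namespace: molecular_function

    [Term]
    id: T:1
    name: broad
    namespace: biological_process
    is_a: GO:0000001

    [Term]
    id: T:2
    name: left
    namespace: biological_process
    alt_id: T:OLD2
    is_a: T:1

    [Term]
    id: T:3
    name: right
    namespace: biological_process
    relationship: part_of T:1

    [Term]
    id: T:4
    name: diamond bottom
    namespace: biological_process
    is_a: T:2
    is_a: T:3

    [Term]
    id: T:5
    name: gone
    namespace: biological_process
    is_obsolete: true
    """
)


@pytest.fixture(scope="session")
def toy_obo_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("obo") / "toy.obo"
    path.write_text(TOY_OBO)
    return path


@pytest.fixture(scope="session")
def toy_graph(toy_obo_path):
    return ontology.read_obo(toy_obo_path)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle (seed 7), shared across the suite."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_fixture(FixtureSpec(seed=7), outdir)
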