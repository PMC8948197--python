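import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pathflux import (
    ExpressionMatrix,
    ExpressionProfile,
    Gene,
    KnowledgeNetwork,
    NetworkSpec,
    Participant,
    Pathway,
    Reaction,
    Species,
    generate_network,
    write_fixture_bundle,
)

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def build_tiny_network() -> KnowledgeNetwork:
    """Hand-built 3-gene network exercising every participant role class:
    plain substrate, enzyme, complex, inhibitor, constant compound, and
    one crosstalk link between a signaling and a metabolic pathway."""
    net = KnowledgeNetwork()
    for gid in ("G1", "G2", "G3"):
        net.genes[gid] = Gene(id=gid)
    net.species["RNA1"] = Species(id="RNA1", kind="rna", constituents=frozenset({"G1"}))
    net.species["ENZ"] = Species(id="ENZ", kind="protein", constituents=frozenset({"G2"}))
    net.species["CPX"] = Species(
        id="CPX", kind="complex", constituents=frozenset({"G1", "G2"})
    )
    net.species["INH"] = Species(id="INH", kind="protein", constituents=frozenset({"G3"}))
    net.species["WATER"] = Species(
        id="WATER", kind="compound", is_constant=True, constant_value=1.0
    )
    net.reactions["RX1"] = Reaction(id="RX1", participants=(Participant("RNA1", "s"),))
    net.reactions["RX2"] = Reaction(
        id="RX2",
        participants=(Participant("RNA1", "s"), Participant("ENZ", "e")),
    )
    net.reactions["RX3"] = Reaction(
        id="RX3",
        participants=(
            Participant("CPX", "s"),
            Participant("INH", "i"),
            Participant("WATER", "s"),
        ),
    )
    net.pathways["PW1"] = Pathway(
        id="PW1",
        name="signaling demo",
        klass="signaling_transduction",
        reaction_ids=frozenset({"RX1", "RX2"}),
        crosstalk_ids=frozenset({"PW2"}),
    )
    net.pathways["PW2"] = Pathway(
        id="PW2",
        name="metabolic demo",
        klass="energy_metabolism",
        reaction_ids=frozenset({"RX3"}),
    )
    net.validate()
    return net


@pytest.fixture
def tiny_network() -> KnowledgeNetwork:
    return build_tiny_network()


@pytest.fixture
def tiny_profile() -> ExpressionProfile:
    return ExpressionProfile("s1", {"G1": 2.0, "G2": 3.0, "G3": 1.0})


@pytest.fixture
def tiny_matrix(tiny_profile) -> ExpressionMatrix:
    df = pd.DataFrame(
        {
            "s1": pd.Series(tiny_profile.values),
            "s2": pd.Series({"G1": 1.0, "G2": 0.5, "G3": 4.0}),
            "s3": pd.Series({"G1": 0.0, "G2": 2.0, "G3": 0.0}),
        }
    )
    return ExpressionMatrix(df)


def random_network(rng: np.random.Generator):
    """A random small network (<= 50 reactions) plus a full-coverage
    random expression matrix, for oracle-equivalence checks."""
    spec = NetworkSpec(
        n_genes=int(rng.integers(5, 26)),
        n_pathways=int(rng.integers(2, 7)),
        reactions_per_pathway=int(rng.integers(1, 5)),
        genes_per_species=int(rng.integers(1, 4)),
        klass_fractions=(0.5, 0.5),
        crosstalk_density=float(rng.uniform(0, 0.5)),
        inhibitor_fraction=float(rng.uniform(0, 0.5)),
        seed=int(rng.integers(0, 2**31)),
    )
    net = generate_network(spec)
    n_samples = int(rng.integers(1, 5))
    data = pd.DataFrame(
        rng.uniform(0, 50, size=(len(net.genes), n_samples)),
        index=list(net.genes),
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return net, ExpressionMatrix(data)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(out)
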