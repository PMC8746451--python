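"""Shared fixtures: tiny hand-made objects plus one desk-scale synthetic
system reused by the slower model/evaluation tests."""

import numpy as np
import pytest

from ppibench.dataset_builder import (
    HeldOutConfig,
    RatioSpec,
    assign_heldout_bins,
    build_heldout_datasets,
)
from ppibench.io_formats import (
    AnnotationMap,
    InteractionSet,
    OntologyDAG,
    ProteinRecord,
    Proteome,
)
from ppibench.synthetic_fixtures import (
    SynthSpec,
    generate_proteome,
    generate_scalefree_interactome,
)


@pytest.fixture
def tiny_proteome():
    return Proteome([
        ProteinRecord("P1", "G1", "MKVLAAGICS" * 5),
        ProteinRecord("P2", "G2", "ACDEFGHIKL" * 5),
        ProteinRecord("P3", "G3", "WYVTSRQPNM" * 5),
        ProteinRecord("P4", "G4", "LIVMFWYACD" * 5),
    ])


@pytest.fixture
def toy_dag():
    """root -> {c1, c2}; c1 -> {d1}."""
    return OntologyDAG(
        parents={"root": set(), "c1": {"root"}, "c2": {"root"},
                 "d1": {"c1"}},
        namespace={t: "biological_process"
                   for t in ("root", "c1", "c2", "d1")})


@pytest.fixture
def toy_annotations():
    """4 proteins: 2 annotated c1, 2 annotated c2 (IC(c1) = ln 2)."""
    return AnnotationMap({"P1": {"c1"}, "P2": {"c1"},
                          "P3": {"c2"}, "P4": {"c2"}})


@pytest.fixture(scope="session")
def synth_system():
    """A shared scale-free system: 800 proteins, 4000 interactions."""
    spec = SynthSpec(n_proteins=800, n_interactions=4000, master_seed=42)
    proteome = generate_proteome(spec)
    interactions = generate_scalefree_interactome(proteome, spec)
    return spec, proteome, interactions


@pytest.fixture(scope="session")
def heldout_split(synth_system):
    """Protein-disjoint 1:1 train/test split over the shared system."""
    spec, proteome, interactions = synth_system
    bins = assign_heldout_bins(proteome, 6, rng_seed=7)
    cfg = HeldOutConfig(6, frozenset({0}), bins.bin_assignment)
    train, test = build_heldout_datasets(
        proteome, interactions, cfg,
        RatioSpec(0.5, 400), RatioSpec(0.5, "all"), rng_seed=9)
    return cfg, train, test


def random_sequences(n, min_len=31, max_len=200, seed=0):
    """Helper: n random standard-alphabet sequences."""
    rng = np.random.default_rng(seed)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    out = []
    for _ in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        out.append("".join(letters[i] for i in rng.integers(0, 20, L)))
    return out
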