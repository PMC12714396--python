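import numpy as np
import pytest

from metamda.mmd_graph import HeteroGraph, NodeRegistry
from metamda.synth import SynthConfig, generate


@pytest.fixture
def toy_registry():
    return NodeRegistry.build(["m1", "m2", "m3"], ["c1", "c2", "c3"], ["d1", "d2"])


@pytest.fixture
def toy_graph(toy_registry):
    """Small graph covering all five edge types.

    c1 touches two microbes, one metabolite and one drug; m3 has a
    same-type edge but no metabolite edges; c3 is isolated.
    """
    edges = {
        "ss": {("m1", "m2"): 0.9, ("m1", "m3"): 0.7},
        "sm": {("m1", "c1"): 1.0, ("m2", "c1"): 1.0, ("m2", "c2"): 1.0},
        "mm": {("c1", "c2"): 1.0},
        "dm": {("d1", "c1"): 1.0, ("d1", "c2"): 1.0},
        "dd": {("d1", "d2"): 0.7},
    }
    return HeteroGraph(toy_registry, edges)


@pytest.fixture(scope="session")
def small_synth():
    """A quick planted dataset shared by read-only tests."""
    return generate(SynthConfig(ns=12, nm=16, nd=12, n_groups=2, seed=11))


def random_hetero_graph(rng, ns=None, nm=None, nd=None):
    """Random typed graph for property tests (may contain isolated nodes)."""
    ns = ns or int(rng.integers(2, 6))
    nm = nm or int(rng.integers(2, 6))
    nd = nd or int(rng.integers(2, 6))
    microbes = [f"s{i}" for i in range(ns)]
    mets = [f"c{i}" for i in range(nm)]
    drugs = [f"d{i}" for i in range(nd)]
    reg = NodeRegistry.build(microbes, mets, drugs)
    edges = {t: {} for t in ("ss", "sm", "mm", "dm", "dd")}
    for i in range(ns):
        for j in range(i + 1, ns):
            if rng.random() < 0.4:
                edges["ss"][(microbes[i], microbes[j])] = float(rng.uniform(0.3, 1.0))
    for i in range(nd):
        for j in range(i + 1, nd):
            if rng.random() < 0.4:
                edges["dd"][(drugs[i], drugs[j])] = float(rng.uniform(0.3, 1.0))
    for i in range(nm):
        for j in range(i + 1, nm):
            if rng.random() < 0.3:
                edges["mm"][(mets[i], mets[j])] = 1.0
    for m in microbes:
        for c in mets:
            if rng.random() < 0.35:
                edges["sm"][(m, c)] = 1.0
    for d in drugs:
        for c in mets:
            if rng.random() < 0.35:
                edges["dm"][(d, c)] = 1.0
    return HeteroGraph(reg, edges)
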