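"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations, combinations_with_replacement

import networkx as nx
import pytest
from rdkit import Chem

from aromap import (
    HuckelBackend,
    Library,
    LibrarySpec,
    build_library,
    get_skeleton,
    load_skeleton_pool,
    load_substituents,
    run_backend,
)


@pytest.fixture(scope="session")
def substituents():
    return load_substituents()


@pytest.fixture(scope="session")
def skeleton_pool():
    return load_skeleton_pool()


@pytest.fixture(scope="session")
def benzene():
    return get_skeleton("benzene")


@pytest.fixture(scope="session")
def small_library(substituents) -> Library:
    """A compact mixed library: aromatics, a quinone, azulene and the
    deep-EA benzothiadiazole, mono-substituted only (fast to build)."""
    skeletons = tuple(
        get_skeleton(n)
        for n in ("benzene", "pyrrole", "benzoquinone", "benzothiadiazole", "azulene")
    )
    return build_library(
        LibrarySpec(skeletons=skeletons, substituents=tuple(substituents), max_substituents=1)
    )


@pytest.fixture(scope="session")
def small_records(small_library):
    records, errors = run_backend(small_library, HuckelBackend())
    assert not errors
    return records


# ---------------------------------------------------------------------------
# independent enumeration oracle: explicit placement over all site tuples,
# deduplicated by labelled-graph isomorphism (no canonical SMILES involved)


def _heavy_atom_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), el=atom.GetSymbol(), q=atom.GetFormalCharge())
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=str(bond.GetBondType())
        )
    return g


def _placement_graph(parent: Chem.Mol, placements) -> nx.Graph:
    """Graph of parent with substituent fragment graphs attached; built by
    node/edge surgery, independent of SMILES canonicalization."""
    g = _heavy_atom_graph(parent)
    offset = parent.GetNumAtoms()
    for site, sub in placements:
        frag = Chem.MolFromSmiles(sub.attachment_fragment)
        attach_to = None
        mapping = {}
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                continue
            mapping[atom.GetIdx()] = offset
            g.add_node(offset, el=atom.GetSymbol(), q=atom.GetFormalCharge())
            offset += 1
        for bond in frag.GetBonds():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            if a.GetAtomicNum() == 0 or b.GetAtomicNum() == 0:
                dummy, real = (a, b) if a.GetAtomicNum() == 0 else (b, a)
                attach_to = mapping[real.GetIdx()]
                continue
            g.add_edge(
                mapping[a.GetIdx()], mapping[b.GetIdx()], order=str(bond.GetBondType())
            )
        g.add_edge(site, attach_to, order="SINGLE")
    return g


def _node_match(a, b):
    return a["el"] == b["el"] and a["q"] == b["q"]


def _edge_match(a, b):
    return a["order"] == b["order"]


def _wl_hash(g: nx.Graph) -> str:
    h = nx.Graph()
    for n, d in g.nodes(data=True):
        h.add_node(n, label=f"{d['el']}{d['q']:+d}")
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, label=d["order"])
    return nx.weisfeiler_lehman_graph_hash(h, node_attr="label", edge_attr="label")


def brute_force_unique_count(skeleton, substituents, max_substituents, sites) -> int:
    """Count isomorphism classes over all explicit substituent placements."""
    parent = Chem.MolFromSmiles(skeleton.structure)
    graphs = [_placement_graph(parent, [])]
    if max_substituents >= 1:
        for sub in substituents:
            for s in sites:
                graphs.append(_placement_graph(parent, [(s, sub)]))
    if max_substituents >= 2:
        for sub_a, sub_b in combinations_with_replacement(substituents, 2):
            for s1, s2 in combinations(sites, 2):
                graphs.append(_placement_graph(parent, [(s1, sub_a), (s2, sub_b)]))
                if sub_a.name != sub_b.name:
                    graphs.append(_placement_graph(parent, [(s1, sub_b), (s2, sub_a)]))

    buckets: dict[str, list[nx.Graph]] = {}
    for g in graphs:
        buckets.setdefault(_wl_hash(g), []).append(g)
    n_unique = 0
    for group in buckets.values():
        reps: list[nx.Graph] = []
        for g in group:
            if not any(
                nx.is_isomorphic(g, r, node_match=_node_match, edge_match=_edge_match)
                for r in reps
            ):
                reps.append(g)
        n_unique += len(reps)
    return n_unique
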