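"""Radius-1 atom-environment (Morgan-style) fragment census.

Every heavy atom of every molecule contributes its radius-0 environment
(the atom itself) and its radius-1 environment (the atom plus all
immediate neighbours and connecting bonds).  Environments are keyed by
canonical fragment SMILES rather than hashed bit positions, which keeps
the census free of fold collisions and lets fragments be reported in
the same notation chemists read them in (``c[nH]c`` for a pyrrolic
nitrogen, ``nsn``/``nns`` for the two thiadiazole isomers, ``CC(C)=O``
for a quinone carbonyl).

The census filter keeps only radius-1 fragments with exactly three
heavy atoms in the ring system whose central atom is a heteroatom, or a
carbon bonded to a heteroatom that has no other heavy neighbour (a
carbonyl-like carbon, as in -C(=O)-).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from rdkit import Chem

from .chem_core import MoleculeEntry, StructureParseError, mol_from_smiles
from .enumeration import Library

logger = logging.getLogger(__name__)


def normalize_fragment_key(key: str) -> str:
    """Canonicalize a fragment SMILES without valence sanitization.

    Fragment SMILES such as ``c[nH]c`` are not complete molecules, so
    the usual parser would reject them; parsing with sanitization off
    and re-emitting canonical SMILES gives a deterministic, spelling-
    invariant key (``CC(=O)C`` and ``CC(C)=O`` collapse to one key).
    """
    mol = Chem.MolFromSmiles(key, sanitize=False)
    if mol is None:
        raise StructureParseError(key, "not a valid fragment SMILES")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Fragment:
    """One canonical atom environment, with the flags the filter needs."""

    key: str
    radius: int
    center_symbol: str
    center_is_heteroatom: bool
    center_is_carbonyl_like_carbon: bool
    n_ring_heavy_atoms: int

    def __post_init__(self):
        if self.radius not in (0, 1):
            raise ValueError("only radii 0 and 1 are supported")


def _center_is_carbonyl_like(atom: Chem.Atom) -> bool:
    """Carbon bonded to a heteroatom whose only heavy neighbour is that carbon."""
    if atom.GetAtomicNum() != 6:
        return False
    return any(
        n.GetAtomicNum() not in (1, 6) and n.GetDegree() == 1 for n in atom.GetNeighbors()
    )


def extract_fragments(entry: MoleculeEntry | str, radius: int = 1) -> dict[str, Fragment]:
    """All distinct radius-0..radius environments of one molecule.

    Returns a mapping key -> :class:`Fragment`; flags are evaluated in
    the context of the source molecule (ring membership is a molecule
    property, not a fragment-intrinsic one).
    """
    if radius not in (0, 1):
        raise ValueError("only radii 0 and 1 are supported")
    structure = entry if isinstance(entry, str) else entry.structure
    mol = mol_from_smiles(structure)

    out: dict[str, Fragment] = {}

    def add(key_smiles: str, center: Chem.Atom, atoms: list[int], rad: int) -> None:
        key = normalize_fragment_key(key_smiles)
        if key in out:
            return
        out[key] = Fragment(
            key=key,
            radius=rad,
            center_symbol=center.GetSymbol(),
            center_is_heteroatom=center.GetAtomicNum() not in (1, 6),
            center_is_carbonyl_like_carbon=_center_is_carbonyl_like(center),
            n_ring_heavy_atoms=sum(
                1 for i in atoms if mol.GetAtomWithIdx(i).IsInRing()
            ),
        )

    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        add(Chem.MolFragmentToSmiles(mol, atomsToUse=[idx]), atom, [idx], 0)
        if radius >= 1:
            env = Chem.FindAtomEnvironmentOfRadiusN(mol, 1, idx)
            if not env:
                continue
            atoms = {idx}
            for b in env:
                bond = mol.GetBondWithIdx(b)
                atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            add(
                Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), bondsToUse=list(env)),
                atom,
                sorted(atoms),
                1,
            )
    return out


@dataclass
class FragmentCensus:
    """Fragment -> molecule-set bookkeeping over a library."""

    fragments: dict[str, Fragment] = field(default_factory=dict)
    molecules: dict[str, set[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.molecules.items()}

    def __len__(self) -> int:
        return len(self.fragments)

    def keys(self) -> list[str]:
        return sorted(self.fragments)


def fragment_census(library: Library | Iterable[MoleculeEntry], radius: int = 1) -> FragmentCensus:
    """Union of per-molecule fragment sets, with molecule-id bookkeeping.

    Per-molecule parse failures are logged and skipped, never fatal.
    """
    census = FragmentCensus()
    for entry in library:
        try:
            frags = extract_fragments(entry, radius)
        except StructureParseError as exc:
            logger.warning("skipping %s: %s", entry.id, exc)
            continue
        for key, frag in frags.items():
            census.fragments.setdefault(key, frag)
            census.molecules.setdefault(key, set()).add(entry.id)
    return census


def filter_fragments(census: FragmentCensus) -> FragmentCensus:
    """Keep radius-1, three-ring-heavy-atom, heteroatom- or carbonyl-centred fragments."""
    kept = {
        k: f
        for k, f in census.fragments.items()
        if f.radius == 1
        and f.n_ring_heavy_atoms == 3
        and (f.center_is_heteroatom or f.center_is_carbonyl_like_carbon)
    }
    return FragmentCensus(
        fragments=kept, molecules={k: set(census.molecules[k]) for k in kept}
    )


def molecules_with_fragment(
    library: Library, fragment_key: str, census: FragmentCensus | None = None
) -> set[str]:
    """Ids of library molecules containing the given environment.

    The query key is normalized through the same canonicalizer as the
    census keys, so any SMILES spelling of the fragment works.  An
    environment absent from the library yields an empty set.
    """
    key = normalize_fragment_key(fragment_key)
    if census is None:
        census = fragment_census(library, radius=1)
    ids = census.molecules.get(key)
    if ids is None:
        logger.info("fragment %r not present in library", key)
        return set()
    return set(ids)
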