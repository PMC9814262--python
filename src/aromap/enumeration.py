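"""Combinatorial enumeration of the substituted molecular library.

Every skeleton hydrogen on an eligible site may be replaced by a
substituent; all placements of up to ``max_substituents`` groups
(combinations with repetition over the substituent set) are generated
and symmetry-equivalent duplicates are removed by canonical-SMILES
comparison.  Eligible sites are by default ring carbons carrying at
least one hydrogen — aromatic C-H plus the sp2 C-H of quinone rings;
heteroatom-bound hydrogens (N-H, O-H) are left untouched unless the
site policy is relaxed to ``"any_h"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement
from typing import Iterable, Sequence

from rdkit import Chem

from .chem_core import MoleculeEntry, Skeleton, StructureParseError, Substituent, count_aromatic_rings, mol_from_smiles

logger = logging.getLogger(__name__)

SITE_POLICIES = ("ring_carbon", "any_h")


@dataclass(frozen=True)
class LibrarySpec:
    """What to enumerate: skeletons x substituents, up to a multiset size."""

    skeletons: tuple[Skeleton, ...]
    substituents: tuple[Substituent, ...] = ()
    max_substituents: int = 2
    allowed_sites: str = "ring_carbon"

    def __post_init__(self):
        object.__setattr__(self, "skeletons", tuple(self.skeletons))
        object.__setattr__(self, "substituents", tuple(self.substituents))
        if self.max_substituents < 0:
            raise ValueError("max_substituents must be >= 0")
        if self.max_substituents > 0 and not self.substituents:
            raise ValueError("substituent list empty but max_substituents > 0")
        if self.allowed_sites not in SITE_POLICIES:
            raise ValueError(f"allowed_sites must be one of {SITE_POLICIES}")


@dataclass
class Library:
    """A deduplicated molecule library plus its generating spec."""

    entries: list[MoleculeEntry]
    spec: LibrarySpec | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self) -> dict[str, MoleculeEntry]:
        return {e.id: e for e in self.entries}

    def skeleton_entries(self) -> dict[str, MoleculeEntry]:
        """Map skeleton id -> its unsubstituted library entry."""
        return {e.skeleton_id: e for e in self.entries if not e.substituents}


def substitution_sites(mol: Chem.Mol, policy: str = "ring_carbon") -> list[int]:
    """Indices of atoms whose hydrogen may be replaced."""
    sites = []
    for atom in mol.GetAtoms():
        if atom.GetTotalNumHs() < 1:
            continue
        if policy == "any_h":
            sites.append(atom.GetIdx())
        else:
            sp2 = atom.GetIsAromatic() or atom.GetHybridization() == Chem.HybridizationType.SP2
            if atom.GetAtomicNum() == 6 and atom.IsInRing() and sp2:
                sites.append(atom.GetIdx())
    return sites


def attach(parent: Chem.Mol, placements: Sequence[tuple[int, Substituent]]) -> str:
    """Attach substituents at the given parent atom indices; return canonical SMILES."""
    mol = Chem.RWMol(parent)
    for site, sub in placements:
        frag = Chem.MolFromSmiles(sub.attachment_fragment)
        if frag is None:  # pragma: no cover - validated at Substituent construction
            raise StructureParseError(sub.attachment_fragment)
        offset = mol.GetNumAtoms()
        mol = Chem.RWMol(Chem.CombineMols(mol, frag))
        dummy = next(
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetIdx() >= offset and a.GetAtomicNum() == 0
        )
        attachment = mol.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
        mol.AddBond(site, attachment, Chem.BondType.SINGLE)
        mol.RemoveAtom(dummy)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def enumerate_substituted(
    skeleton: Skeleton,
    substituents: Sequence[Substituent],
    max_substituents: int = 2,
    allowed_sites: str = "ring_carbon",
) -> list[MoleculeEntry]:
    """All distinct molecules from 0..max_substituents placements on one skeleton.

    Distinctness is by canonical structure; the unsubstituted parent is
    always included.  Entry ids are assigned later by
    :func:`build_library`; here they are provisional canonical strings.
    """
    parent = mol_from_smiles(skeleton.structure)
    sites = substitution_sites(parent, allowed_sites)
    if max_substituents > 0 and not sites:
        warnings.warn(f"skeleton {skeleton.id!r} has no eligible substitution site")

    seen: dict[str, tuple[str, ...]] = {skeleton.structure: ()}
    if max_substituents >= 1:
        for sub in substituents:
            for s in sites:
                smi = attach(parent, [(s, sub)])
                seen.setdefault(smi, (sub.name,))
    if max_substituents >= 2:
        for sub_a, sub_b in combinations_with_replacement(substituents, 2):
            for s1, s2 in combinations(sites, 2):
                smi = attach(parent, [(s1, sub_a), (s2, sub_b)])
                seen.setdefault(smi, tuple(sorted((sub_a.name, sub_b.name))))
                if sub_a.name != sub_b.name:
                    smi = attach(parent, [(s1, sub_b), (s2, sub_a)])
                    seen.setdefault(smi, tuple(sorted((sub_a.name, sub_b.name))))
    if max_substituents > 2:
        raise NotImplementedError("library enumeration supports at most 2 substituents")

    return [
        MoleculeEntry(
            id=smi,
            structure=smi,
            skeleton_id=skeleton.id,
            substituents=subs,
            n_aromatic_rings=count_aromatic_rings(smi),
        )
        for smi, subs in seen.items()
    ]


def build_library(spec: LibrarySpec) -> Library:
    """Enumerate every skeleton and deduplicate globally.

    Two skeleton+substituent routes can reach the same molecule; the
    first-encountered skeleton (in spec order) is recorded as parent and
    collisions are logged.  Output ordering is deterministic: skeletons
    in spec order, entries by canonical structure, ids sequential.
    """
    seen: dict[str, MoleculeEntry] = {}
    for skeleton in spec.skeletons:
        for entry in sorted(
            enumerate_substituted(
                skeleton, spec.substituents, spec.max_substituents, spec.allowed_sites
            ),
            key=lambda e: e.structure,
        ):
            if entry.structure in seen:
                logger.info(
                    "duplicate across skeletons: %s reached from %s and %s",
                    entry.structure,
                    seen[entry.structure].skeleton_id,
                    entry.skeleton_id,
                )
            else:
                seen[entry.structure] = entry

    width = max(5, len(str(len(seen))))
    entries = [
        MoleculeEntry(
            id=f"mol_{i:0{width}d}",
            structure=e.structure,
            skeleton_id=e.skeleton_id,
            substituents=e.substituents,
            n_aromatic_rings=e.n_aromatic_rings,
        )
        for i, e in enumerate(seen.values())
    ]
    return Library(entries=entries, spec=spec)


def library_to_frame(library: Library):
    """Tidy DataFrame view of a library."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [e.id for e in library.entries],
            "smiles": [e.structure for e in library.entries],
            "skeleton_id": [e.skeleton_id for e in library.entries],
            "substituents": ["+".join(e.substituents) for e in library.entries],
            "n_substituents": [len(e.substituents) for e in library.entries],
            "n_aromatic_rings": [e.n_aromatic_rings for e in library.entries],
        }
    )
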