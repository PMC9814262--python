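"""Core domain types and structure handling.

Sign convention used throughout the package: ionisation potentials and
electron affinities are stored as their *negatives* (``minus_ip``,
``minus_ea``, in eV), i.e. as frontier-level-like quantities where
"deeper" means more negative.  The optical gap ``optical_gap`` is a
positive excitation energy.  Two derived quantities follow:

* fundamental gap  ``delta_f = minus_ea - minus_ip``  (= IP - EA)
* exciton binding  ``ebe     = delta_f - optical_gap``

Aromatic-ring counting deliberately uses a per-ring Hückel (4n+2)
perception, under which the individual 5- and 7-membered rings of
azulene are *not* aromatic (azulene derivatives count as zero aromatic
rings) even though the molecule as a whole is aromatic under the
default additive model used for canonicalisation and fragment flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

PROPERTY_NAMES = ("minus_ip", "minus_ea", "optical_gap")

#: substituent classes used for the donor/acceptor analyses
STRONG_ACCEPTORS = ("NO2", "CN", "SO3H", "CF3")
STRONG_DONORS = ("NH2", "NMe2", "OH", "OMe")


class StructureParseError(ValueError):
    """A structure string could not be parsed as a molecule."""

    def __init__(self, structure: str, detail: str = ""):
        self.structure = structure
        msg = f"could not parse structure {structure!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class PropertyTableError(ValueError):
    """A property table is malformed (missing columns or bad cells)."""


def mol_from_smiles(structure: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`StructureParseError` on failure."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureParseError(structure)
    return mol


def canonicalize(structure: str) -> str:
    """Return the canonical SMILES form of ``structure``.

    Deterministic, idempotent and invariant to input atom ordering;
    duplicate molecules are *defined* as molecules with equal canonical
    strings, everywhere in the package.
    """
    return Chem.MolToSmiles(mol_from_smiles(structure))


def count_aromatic_rings(structure: str) -> int:
    """Number of smallest rings whose atoms are all aromatic.

    Aromaticity is re-perceived ring-by-ring with RDKit's *simple*
    (per-ring Hückel) model, so fused systems that are only aromatic as
    a whole — azulene is the canonical case — count as zero rings.
    """
    mol = mol_from_smiles(structure)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    Chem.SetAromaticity(mol, Chem.AromaticityModel.AROMATICITY_SIMPLE)
    ring_info = mol.GetRingInfo()
    return sum(
        1
        for ring in ring_info.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )


def is_hydrocarbon(structure: str) -> bool:
    """True when every heavy atom is carbon."""
    return all(a.GetAtomicNum() == 6 for a in mol_from_smiles(structure).GetAtoms())


@dataclass(frozen=True)
class Skeleton:
    """An unsubstituted aromatic or quinone ring system."""

    id: str
    structure: str

    def __post_init__(self):
        object.__setattr__(self, "structure", canonicalize(self.structure))

    @property
    def is_hydrocarbon(self) -> bool:
        return is_hydrocarbon(self.structure)

    @property
    def n_heavy_atoms(self) -> int:
        return mol_from_smiles(self.structure).GetNumAtoms()


@dataclass(frozen=True)
class Substituent:
    """A functional group replacing one skeleton hydrogen.

    ``attachment_fragment`` is a SMILES fragment with a single dummy
    atom ``*`` marking the attachment point, e.g. ``*[N+](=O)[O-]``.
    """

    name: str
    attachment_fragment: str
    donor_acceptor_class: str = "other"

    def __post_init__(self):
        if self.attachment_fragment.count("*") != 1:
            raise ValueError(
                f"substituent {self.name!r} must have exactly one '*' "
                f"attachment point, got {self.attachment_fragment!r}"
            )
        if self.donor_acceptor_class not in ("strong_acceptor", "strong_donor", "other"):
            raise ValueError(f"unknown class {self.donor_acceptor_class!r}")


@dataclass(frozen=True)
class MoleculeEntry:
    """One member of the enumerated library."""

    id: str
    structure: str
    skeleton_id: str
    substituents: tuple[str, ...] = ()
    n_aromatic_rings: int | None = None

    def __post_init__(self):
        if len(self.substituents) > 2:
            raise ValueError("at most two substituents per molecule")
        object.__setattr__(self, "substituents", tuple(sorted(self.substituents)))


@dataclass(frozen=True)
class PropertyRecord:
    """Per-molecule -IP, -EA and optical gap at a named level of theory."""

    molecule_id: str
    minus_ip: float
    minus_ea: float
    optical_gap: float
    level: str = "cheap"

    def __post_init__(self):
        if not self.optical_gap > 0:
            raise ValueError(
                f"optical gap must be positive, got {self.optical_gap} "
                f"for {self.molecule_id!r}"
            )

    @property
    def fundamental_gap(self) -> float:
        """IP - EA, as the difference of the stored negatives."""
        return self.minus_ea - self.minus_ip

    @property
    def exciton_binding(self) -> float:
        return self.fundamental_gap - self.optical_gap

    def value(self, prop: str) -> float:
        if prop not in PROPERTY_NAMES:
            raise KeyError(f"unknown property {prop!r}")
        return getattr(self, prop)

    def with_value(self, prop: str, value: float, level: str | None = None) -> "PropertyRecord":
        if prop not in PROPERTY_NAMES:
            raise KeyError(f"unknown property {prop!r}")
        return replace(self, **{prop: value}, level=level or self.level)


# ---------------------------------------------------------------------------
# property-table I/O
#
# Dialect: UTF-8 CSV, header  id,smiles,minus_ip,minus_ea,optical_gap[,level]
# (smiles and level optional); energies in eV.

_REQUIRED_COLUMNS = ("id", "minus_ip", "minus_ea", "optical_gap")


def read_property_table(path: str | Path, strict: bool = True) -> list[PropertyRecord]:
    """Read a property-table CSV into records.

    Missing required columns raise :class:`PropertyTableError`
    immediately; rows with non-numeric or non-positive-gap cells are
    rejected with their (1-based, header-exclusive) row numbers —
    raising when ``strict`` and warning + skipping otherwise.
    """
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PropertyTableError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    level_col = df["level"] if "level" in df.columns else None

    records: list[PropertyRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            values = {c: float(row[c]) for c in _REQUIRED_COLUMNS[1:]}
            records.append(
                PropertyRecord(
                    molecule_id=str(row["id"]),
                    level=str(level_col.iloc[pos - 1]) if level_col is not None else "cheap",
                    **values,
                )
            )
        except (TypeError, ValueError) as exc:
            bad_rows.append((pos, str(exc)))
    if bad_rows:
        detail = "; ".join(f"row {i}: {m}" for i, m in bad_rows)
        if strict:
            raise PropertyTableError(f"{path}: malformed rows — {detail}")
        warnings.warn(f"{path}: skipped malformed rows — {detail}")
    return records


def write_property_table(records: Iterable[PropertyRecord], path: str | Path) -> None:
    """Write records in the package CSV dialect (full float precision)."""
    rows = [
        {
            "id": r.molecule_id,
            "minus_ip": repr(r.minus_ip),
            "minus_ea": repr(r.minus_ea),
            "optical_gap": repr(r.optical_gap),
            "level": r.level,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "minus_ip", "minus_ea", "optical_gap", "level"]).to_csv(
        path, index=False
    )


def records_to_frame(records: Sequence[PropertyRecord]) -> pd.DataFrame:
    """Tidy DataFrame view (one row per record, derived gaps included)."""
    return pd.DataFrame(
        {
            "id": [r.molecule_id for r in records],
            "minus_ip": [r.minus_ip for r in records],
            "minus_ea": [r.minus_ea for r in records],
            "optical_gap": [r.optical_gap for r in records],
            "fundamental_gap": [r.fundamental_gap for r in records],
            "exciton_binding": [r.exciton_binding for r in records],
            "level": [r.level for r in records],
        }
    )


def read_smiles_file(path: str | Path) -> list[Skeleton]:
    """Read a skeleton list: one SMILES per line, optional trailing id."""
    skeletons = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        smiles = parts[0]
        sid = parts[1] if len(parts) > 1 else f"skel_{lineno}"
        try:
            skeletons.append(Skeleton(id=sid, structure=smiles))
        except StructureParseError as exc:
            raise StructureParseError(smiles, f"line {lineno} of {path}") from exc
    return skeletons
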