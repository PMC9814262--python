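"""Per-molecule property backends.

Two backends implement the same contract (``compute(entry) ->
PropertyRecord``):

* :class:`HuckelBackend` — a topological Hückel π-electron model.  The
  secular matrix is built over the conjugated π system with on-site
  energies α_X = α + h_X·β and couplings β_XY = k_XY·β (α = 0,
  β = -1, so eigenvalues are in units of \\|β\\| with bonding levels
  negative).  Frontier levels are mapped to -IP / -EA / optical-gap
  proxies by a per-property affine map.  This is a deliberately cheap,
  fully deterministic stand-in for a semi-empirical engine: it orders
  chemistry qualitatively (donor substituents push the HOMO up,
  electron-poor rings pull the LUMO down) but makes no quantitative
  claim.

* :class:`TableBackend` — looks records up in an externally computed
  property table, for importing deposited data.

Heteroatom parameters default to the Van Catledge consensus Hückel
table (h/k in units of \\|β\\|), shipped as an editable YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np
import yaml
from rdkit import Chem

from .chem_core import MoleculeEntry, PropertyRecord, mol_from_smiles
from .enumeration import Library


class NoPiSystemError(ValueError):
    """The molecule has no conjugated π system to diagonalize."""


# Van Catledge, J. Org. Chem. 45 (1980): on-site shifts h_X keyed by
# (element, pi-electrons contributed); couplings k_XY keyed by the
# sorted pair of those keys.  Unlisted pairs fall back to 0.7.
DEFAULT_ONSITE = {
    ("C", 1): 0.0,
    ("N", 1): 0.51,
    ("N", 2): 1.37,
    ("O", 1): 0.97,
    ("O", 2): 2.09,
    ("S", 1): 0.46,
    ("S", 2): 1.11,
    ("F", 2): 2.71,
    ("Cl", 2): 1.48,
    ("Br", 2): 1.50,
}
DEFAULT_COUPLING = {
    (("C", 1), ("C", 1)): 1.00,
    (("C", 1), ("N", 1)): 1.02,
    (("C", 1), ("N", 2)): 0.89,
    (("C", 1), ("O", 1)): 1.06,
    (("C", 1), ("O", 2)): 0.66,
    (("C", 1), ("S", 1)): 0.81,
    (("C", 1), ("S", 2)): 0.69,
    (("C", 1), ("F", 2)): 0.52,
    (("C", 1), ("Cl", 2)): 0.62,
    (("C", 1), ("Br", 2)): 0.30,
    (("N", 1), ("N", 1)): 0.80,
    (("N", 1), ("N", 2)): 0.80,
    (("N", 1), ("O", 1)): 0.80,
    (("N", 1), ("S", 2)): 0.60,
    (("N", 1), ("O", 2)): 0.65,
}
FALLBACK_COUPLING = 0.70
FALLBACK_ONSITE = 0.50


@dataclass(frozen=True)
class EvMap:
    """Affine maps from frontier levels (units of \\|β\\|) to eV proxies.

    Defaults place benzene near (-IP, -EA, ΔO) = (-9.2, +0.5, 4.8) eV —
    illustrative anchoring only, never used as ground truth.
    """

    ip_slope: float = 2.2
    ip_offset: float = -7.0
    ea_slope: float = 2.2
    ea_offset: float = -1.7
    gap_slope: float = 2.0
    gap_offset: float = 0.8

    def __post_init__(self):
        if self.gap_slope <= 0:
            raise ValueError("gap slope must be positive")


@dataclass(frozen=True)
class HuckelParams:
    alpha_c: float = 0.0
    beta_cc: float = -1.0
    onsite: dict = field(default_factory=lambda: dict(DEFAULT_ONSITE))
    coupling: dict = field(default_factory=lambda: dict(DEFAULT_COUPLING))
    ev_map: EvMap = field(default_factory=EvMap)

    def __post_init__(self):
        if not self.beta_cc < 0:
            raise ValueError("beta_cc must be negative")
        if any(k <= 0 for k in self.coupling.values()):
            raise ValueError("couplings k_XY must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HuckelParams":
        """Load overrides from YAML (keys: onsite '<El>,<ne>', coupling
        '<El>,<ne>-<El>,<ne>', ev_map fields, alpha_c, beta_cc)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}

        def parse_key(s):
            el, ne = s.split(",")
            return (el.strip(), int(ne))

        onsite = dict(DEFAULT_ONSITE)
        for k, v in (raw.get("onsite") or {}).items():
            onsite[parse_key(k)] = float(v)
        coupling = dict(DEFAULT_COUPLING)
        for k, v in (raw.get("coupling") or {}).items():
            a, b = k.split("-")
            coupling[tuple(sorted((parse_key(a), parse_key(b))))] = float(v)
        ev_map = EvMap(**(raw.get("ev_map") or {}))
        return cls(
            alpha_c=float(raw.get("alpha_c", 0.0)),
            beta_cc=float(raw.get("beta_cc", -1.0)),
            onsite=onsite,
            coupling=coupling,
            ev_map=ev_map,
        )


# ---------------------------------------------------------------------------
# π-system perception

_PI_ELEMENTS = {"C", "N", "O", "S"}
_DONOR_ELEMENTS = {"N", "O", "S", "F", "Cl", "Br"}


def _pi_system(mol: Chem.Mol) -> tuple[list[int], dict[int, int]]:
    """Return (π-center atom indices, electrons contributed per center).

    Centers are aromatic atoms, atoms in C/N/O/S double bonds (this
    brings in quinone C=C / C=O and nitro N=O), and lone-pair-donor
    heteroatoms singly bonded to an existing center (amine N, phenol O,
    halogens) — one expansion pass, so saturated chains never join.
    """
    has_double = {
        a.GetIdx(): any(b.GetBondType() == Chem.BondType.DOUBLE for b in a.GetBonds())
        for a in mol.GetAtoms()
    }
    centers: set[int] = set()
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if atom.GetIsAromatic():
            centers.add(atom.GetIdx())
        elif sym in _PI_ELEMENTS and has_double[atom.GetIdx()]:
            for b in atom.GetBonds():
                if (
                    b.GetBondType() == Chem.BondType.DOUBLE
                    and b.GetOtherAtom(atom).GetSymbol() in _PI_ELEMENTS
                ):
                    centers.add(atom.GetIdx())
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        if i in centers or atom.GetSymbol() not in _DONOR_ELEMENTS or has_double[i]:
            continue
        if any(n.GetIdx() in centers for n in atom.GetNeighbors()):
            centers.add(i)

    electrons: dict[int, int] = {}
    for i in sorted(centers):
        atom = mol.GetAtomWithIdx(i)
        sym = atom.GetSymbol()
        if has_double[i]:
            electrons[i] = 1  # one electron of the localized π bond
        elif atom.GetIsAromatic():
            if sym == "C":
                electrons[i] = 1
            elif sym == "N":
                # pyrrolic (three σ connections incl. H) donates the pair
                electrons[i] = 2 if atom.GetTotalDegree() == 3 else 1
            else:  # aromatic O / S
                electrons[i] = 2
        else:
            electrons[i] = 2  # lone-pair donor
    return sorted(centers), electrons


def huckel_matrix(mol: Chem.Mol, params: HuckelParams) -> tuple[np.ndarray, list[int], int]:
    """Secular matrix over the π system; returns (H, centers, n_electrons)."""
    centers, electrons = _pi_system(mol)
    if not centers:
        raise NoPiSystemError("molecule has no conjugated π system")
    index = {a: i for i, a in enumerate(centers)}
    n = len(centers)
    h = np.zeros((n, n))
    keys = {}
    for a in centers:
        atom = mol.GetAtomWithIdx(a)
        key = (atom.GetSymbol(), electrons[a])
        keys[a] = key
        h_x = params.onsite.get(key, FALLBACK_ONSITE if key[0] != "C" else 0.0)
        h[index[a], index[a]] = params.alpha_c + h_x * params.beta_cc
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in index and b in index:
            pair = tuple(sorted((keys[a], keys[b])))
            k = params.coupling.get(pair, FALLBACK_COUPLING)
            h[index[a], index[b]] = h[index[b], index[a]] = k * params.beta_cc
    return h, centers, sum(electrons.values())


def huckel_levels(structure: str, params: HuckelParams | None = None) -> np.ndarray:
    """Ascending π orbital energies in units of \\|β\\| (bonding < 0)."""
    params = params or HuckelParams()
    h, _, _ = huckel_matrix(mol_from_smiles(structure), params)
    return np.linalg.eigvalsh(h)


def huckel_frontier(structure: str, params: HuckelParams | None = None) -> tuple[float, float]:
    """(HOMO, LUMO) energies by Aufbau filling of the π electrons."""
    params = params or HuckelParams()
    h, _, n_el = huckel_matrix(mol_from_smiles(structure), params)
    levels = np.linalg.eigvalsh(h)
    n_occ = n_el // 2
    if n_el % 2:  # singly occupied level acts as both frontier levels
        somo = levels[n_occ]
        return float(somo), float(somo)
    homo = float(levels[n_occ - 1]) if n_occ > 0 else float(levels[0])
    lumo = float(levels[n_occ]) if n_occ < len(levels) else homo
    return homo, lumo


#: floor for the optical-gap proxy (eV); keeps degenerate open-shell
#: cases from producing non-positive gaps
GAP_FLOOR = 0.05


def huckel_properties(entry: MoleculeEntry, params: HuckelParams | None = None) -> PropertyRecord:
    """Map frontier π levels to -IP / -EA / optical-gap proxies ("cheap" level)."""
    params = params or HuckelParams()
    homo, lumo = huckel_frontier(entry.structure, params)
    ev = params.ev_map
    return PropertyRecord(
        molecule_id=entry.id,
        minus_ip=ev.ip_slope * homo + ev.ip_offset,
        minus_ea=ev.ea_slope * lumo + ev.ea_offset,
        optical_gap=max(ev.gap_slope * (lumo - homo) + ev.gap_offset, GAP_FLOOR),
        level="cheap",
    )


# ---------------------------------------------------------------------------
# backend protocol + batch driver


class PropertyBackend(Protocol):
    name: str

    def compute(self, entry: MoleculeEntry) -> PropertyRecord: ...


@dataclass(frozen=True)
class HuckelBackend:
    params: HuckelParams = field(default_factory=HuckelParams)
    name: str = "huckel"

    def compute(self, entry: MoleculeEntry) -> PropertyRecord:
        return huckel_properties(entry, self.params)


class TableBackend:
    """Serve records from an imported property table, keyed by molecule id."""

    name = "table"

    def __init__(self, records: Iterable[PropertyRecord]):
        self._records = {r.molecule_id: r for r in records}

    @classmethod
    def from_csv(cls, path: str | Path) -> "TableBackend":
        from .chem_core import read_property_table

        return cls(read_property_table(path))

    def compute(self, entry: MoleculeEntry) -> PropertyRecord:
        try:
            return self._records[entry.id]
        except KeyError:
            raise KeyError(f"no property record for molecule {entry.id!r}") from None


def run_backend(
    library: Library, backend: PropertyBackend
) -> tuple[list[PropertyRecord], dict[str, str]]:
    """One record per library entry, order-aligned; per-molecule failures
    are collected into the error report instead of aborting the batch."""
    records: list[PropertyRecord] = []
    errors: dict[str, str] = {}
    for entry in library:
        try:
            records.append(backend.compute(entry))
        except (NoPiSystemError, KeyError, ValueError) as exc:
            errors[entry.id] = str(exc)
    return records, errors
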