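"""Bundled reference data: the 12-substituent table and a curated skeleton pool.

The substituent set pairs four strongly electron-withdrawing groups
(-NO2, -CN, -S(O2)OH, -CF3), four strongly electron-donating groups
(-NH2, -N(CH3)2, -OH, -OCH3) and four groups of intermediate character
(-F, -Cl, -CH3, -COOH).

The skeleton pool is a small curated stand-in for a full screening
library: plain aromatics (benzene, naphthalene), the non-aromatic-ring
aromatic azulene, two quinones, the common five- and six-membered
heteroaromatics, and the deep-EA benzothiadiazole / oxadiazole motifs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chem_core import Skeleton, Substituent, read_smiles_file


def _data_path(name: str):
    return resources.files("aromap").joinpath("data", name)


def load_substituents() -> list[Substituent]:
    """The 12 default substituents, with donor/acceptor class labels."""
    with resources.as_file(_data_path("substituents.csv")) as p:
        df = pd.read_csv(p)
    return [
        Substituent(
            name=row["name"],
            attachment_fragment=row["attachment_fragment"],
            donor_acceptor_class=row["donor_acceptor_class"],
        )
        for _, row in df.iterrows()
    ]


def load_skeleton_pool() -> list[Skeleton]:
    """The curated skeleton pool shipped with the package."""
    with resources.as_file(_data_path("skeletons.smi")) as p:
        return read_smiles_file(p)


#: CSV layout expected for a deposited raw-data table (cheap/reference
#: value pairs per molecule); spreadsheets must be exported to this form
DEPOSITED_COLUMNS = (
    "id",
    "smiles",
    "minus_ip_cheap",
    "minus_ea_cheap",
    "optical_gap_cheap",
    "minus_ip_ref",
    "minus_ea_ref",
    "optical_gap_ref",
)


def load_deposited_table(path):
    """Read an externally deposited cheap/reference raw-data table.

    Expects a UTF-8 CSV with the :data:`DEPOSITED_COLUMNS` header
    (energies in eV) and returns ``(cheap_records, reference_records)``
    id-aligned lists.
    """
    from .chem_core import PropertyRecord, PropertyTableError

    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in DEPOSITED_COLUMNS if c not in df.columns and c != "smiles"]
    if missing:
        raise PropertyTableError(f"{path}: missing column(s) {', '.join(missing)}")
    cheap, ref = [], []
    for _, row in df.iterrows():
        cheap.append(
            PropertyRecord(
                row["id"],
                float(row["minus_ip_cheap"]),
                float(row["minus_ea_cheap"]),
                float(row["optical_gap_cheap"]),
                "cheap",
            )
        )
        ref.append(
            PropertyRecord(
                row["id"],
                float(row["minus_ip_ref"]),
                float(row["minus_ea_ref"]),
                float(row["optical_gap_ref"]),
                "reference",
            )
        )
    return cheap, ref


def get_skeleton(name: str) -> Skeleton:
    """Fetch one pool skeleton by id (e.g. ``'benzene'``)."""
    for s in load_skeleton_pool():
        if s.id == name:
            return s
    raise KeyError(f"no skeleton named {name!r} in the bundled pool")
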