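"""Compute cheap-level (-IP, -EA, optical gap) proxies for the library.

Runs the Hückel π-electron surrogate backend over results/library.csv
and writes results/properties_cheap.csv.  The surrogate anchors benzene
near (-9.2, +0.5, 4.8) eV and orders heteroatom and substituent effects
qualitatively.
"""

from pathlib import Path

import pandas as pd

from aromap import HuckelBackend, MoleculeEntry, records_to_frame, run_backend, write_property_table
from aromap.enumeration import Library

OUT = Path(__file__).resolve().parent.parent / "results"


def load_library() -> Library:
    df = pd.read_csv(OUT / "library.csv", keep_default_na=False)
    entries = [
        MoleculeEntry(
            id=row["id"],
            structure=row["smiles"],
            skeleton_id=row["skeleton_id"],
            substituents=tuple(s for s in row["substituents"].split("+") if s),
            n_aromatic_rings=int(row["n_aromatic_rings"]),
        )
        for _, row in df.iterrows()
    ]
    return Library(entries=entries)


def main():
    library = load_library()
    records, errors = run_backend(library, HuckelBackend())
    write_property_table(records, OUT / "properties_cheap.csv")

    frame = records_to_frame(records)
    print(f"computed {len(records)} records, {len(errors)} failures")
    if errors:
        for mid, msg in list(errors.items())[:5]:
            print(f"  {mid}: {msg}")
    print("\nproperty ranges (eV):")
    print(frame[["minus_ip", "minus_ea", "optical_gap"]].describe().loc[["min", "mean", "max"]])
    print(f"\nwrote {OUT / 'properties_cheap.csv'}")


if __name__ == "__main__":
    main()
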