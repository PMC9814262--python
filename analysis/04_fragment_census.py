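"""Radius-1 atom-environment census and heteroatom fragment analysis.

Builds the fragment census over the library, applies the ring/heteroatom
filter, and compares the calibrated -EA distributions of molecules
containing selected heteroatom environments (pyrrolic nitrogen vs the
thiadiazole motifs).
"""

import importlib.util
from pathlib import Path

import numpy as np

from aromap import filter_fragments, fragment_census, normalize_fragment_key, read_property_table

OUT = Path(__file__).resolve().parent.parent / "results"

_spec = importlib.util.spec_from_file_location(
    "build_props", Path(__file__).with_name("02_compute_properties.py")
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_library = _mod.load_library


def main():
    library = load_library()
    census = fragment_census(library, radius=1)
    filtered = filter_fragments(census)

    for name, c in (("fragments.csv", census), ("fragments_filtered.csv", filtered)):
        rows = sorted(c.counts().items(), key=lambda kv: (-kv[1], kv[0]))
        with open(OUT / name, "w") as fh:
            fh.write("fragment,count\n")
            fh.writelines(f'"{k}",{n}\n' for k, n in rows)

    print(f"unique fragments: {len(census)}; after filter: {len(filtered)}\n")
    print("most common retained fragments:")
    for k, n in sorted(filtered.counts().items(), key=lambda kv: -kv[1])[:10]:
        print(f"  {k:<12}{n:>6}")

    records = {r.molecule_id: r for r in read_property_table(OUT / "properties_calibrated.csv")}
    print("\nmean calibrated -EA by heteroatom environment (eV):")
    for label, key in (
        ("pyrrolic N  (c[nH]c)", "c[nH]c"),
        ("thiophenic S (csc)", "csc"),
        ("thiadiazole (nsn)", "nsn"),
        ("quinone C=O (CC(=O)C)", "CC(=O)C"),
    ):
        ids = census.molecules.get(normalize_fragment_key(key), set())
        if ids:
            mean_ea = np.mean([records[i].minus_ea for i in ids if i in records])
            print(f"  {label:<24}{mean_ea:>8.2f}   (n={len(ids)})")
    print(f"\nwrote {OUT / 'fragments.csv'} and fragments_filtered.csv")


if __name__ == "__main__":
    main()
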