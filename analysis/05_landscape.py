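"""Map the optoelectronic property space of the calibrated library.

Substituent-shift analysis (donor vs acceptor, one vs two groups),
topographic most-prevalent-skeleton grid, ring-count trends, convex
hulls of molecule subsets, and the empty-region queries.
"""

import importlib.util
import json
from pathlib import Path

import numpy as np

from aromap import (
    TopographyConfig,
    convex_hull2d,
    load_substituents,
    read_property_table,
    region_count,
    ring_count_distributions,
    substituent_shifts,
    topography,
)
from aromap.pipeline import DEFAULT_REGION_QUERIES

OUT = Path(__file__).resolve().parent.parent / "results"

_spec = importlib.util.spec_from_file_location(
    "build_props", Path(__file__).with_name("02_compute_properties.py")
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_library = _mod.load_library


def main():
    library = load_library()
    records = read_property_table(OUT / "properties_calibrated.csv")
    classes = {s.name: s.donor_acceptor_class for s in load_substituents()}
    by_id = library.by_id()

    # substituent shifts
    shifts = substituent_shifts(library, records, classes)
    shifts.to_csv(OUT / "substituent_shifts.csv", index=False)
    print("mean property shift vs parent skeleton (eV):")
    for cls in ("strong_acceptor", "strong_donor"):
        sub = shifts[(shifts.classes == cls) & (shifts.n_substituents == 1)]
        print(
            f"  one {cls:<16} d(-IP) {sub.d_minus_ip.mean():+.2f}   "
            f"d(-EA) {sub.d_minus_ea.mean():+.2f}   (n={len(sub)})"
        )
    one = shifts[shifts.n_substituents == 1]
    two = shifts[shifts.n_substituents == 2]
    m1 = np.abs(np.concatenate([one.d_minus_ip, one.d_minus_ea])).mean()
    m2 = np.abs(np.concatenate([two.d_minus_ip, two.d_minus_ea])).mean()
    print(f"  mean |shift|: one substituent {m1:.2f}, two {m2:.2f} (ratio {m2 / m1:.2f}, < 2)")

    # topography
    topo = topography(records, library, TopographyConfig(0.5, 0.5))
    topo.to_frame().to_csv(OUT / "topography.csv", index=False)
    winners = topo.to_frame().groupby("skeleton_id").size().sort_values(ascending=False)
    print(f"\ntopography: {len(topo.cells)} occupied cells; cells won per skeleton:")
    print("  " + ", ".join(f"{s} ({n})" for s, n in winners.items()))

    # ring-count trends
    rings = ring_count_distributions(library, records)
    trend = rings.groupby("n_aromatic_rings")[["minus_ip", "minus_ea", "optical_gap"]].mean()
    print("\nmean properties by aromatic-ring count (0 = azulene/quinones):")
    print(trend.round(2).to_string())

    # convex hulls of subsets
    subsets = {
        "hydrocarbon_skeletons": [
            r
            for r in records
            if not by_id[r.molecule_id].substituents
            and by_id[r.molecule_id].skeleton_id in ("benzene", "naphthalene", "azulene")
        ],
        "all_skeletons": [r for r in records if not by_id[r.molecule_id].substituents],
        "all_molecules": records,
    }
    hulls = {}
    print("\nconvex hulls in the (-IP, -EA) plane:")
    for label, recs in subsets.items():
        hull = convex_hull2d(recs, subset_label=label)
        hulls[label] = {"vertices": hull.vertices.tolist(), "area": hull.area}
        print(f"  {label:<24} n={len(recs):>5}  area {hull.area:6.2f} eV^2")
    (OUT / "hulls.json").write_text(json.dumps(hulls, indent=2, sort_keys=True))

    # empty-region queries
    print("\nempty-region queries (count of molecules inside):")
    regions = {}
    for name, query in DEFAULT_REGION_QUERIES.items():
        regions[name] = region_count(records, query)
        print(f"  {name:<24} [{query}] -> {regions[name]}")
    (OUT / "region_counts.json").write_text(json.dumps(regions, indent=2, sort_keys=True))
    print(f"\nwrote shift table, topography, hulls and region counts under {OUT}")


if __name__ == "__main__":
    main()
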