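"""Build the substituted molecular library from the bundled skeleton pool.

Enumerates every skeleton with up to two of the twelve substituents,
removes symmetry-equivalent duplicates by canonical SMILES, and writes
the library table to results/library.csv.
"""

from pathlib import Path

from aromap import LibrarySpec, build_library, library_to_frame, load_skeleton_pool, load_substituents

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    skeletons = load_skeleton_pool()
    substituents = load_substituents()
    spec = LibrarySpec(
        skeletons=tuple(skeletons), substituents=tuple(substituents), max_substituents=2
    )
    library = build_library(spec)
    df = library_to_frame(library)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "library.csv", index=False)

    print(f"skeletons: {len(skeletons)}, substituents: {len(substituents)}")
    print(f"library size after global dedup: {len(library)}")
    print("\nmolecules per skeleton:")
    print(df.groupby("skeleton_id").size().sort_values(ascending=False).to_string())
    print("\nby substituent count:")
    print(df.groupby("n_substituents").size().to_string())
    print(f"\nwrote {OUT / 'library.csv'}")


if __name__ == "__main__":
    main()
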