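"""End-to-end pipeline: enumerate -> properties -> calibrate -> fragments -> map.

A :class:`RunConfig` describes one fully deterministic run: the library
spec, the property backend, the synthetic reference relation, and the
landscape settings.  :func:`run_pipeline` executes the stages in
dependency order, writes every stage's table under ``out_dir`` and ends
with a JSON run manifest (inputs, config hash, seed, package version).
Re-running with the same config and seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .backends import HuckelBackend, HuckelParams, TableBackend, run_backend
from .calibrate import apply_calibration, fit_all
from .chem_core import read_smiles_file, records_to_frame, write_property_table
from .datasets import load_skeleton_pool, load_substituents
from .enumeration import Library, LibrarySpec, build_library, library_to_frame
from .fragments import filter_fragments, fragment_census
from .landscape import (
    TopographyConfig,
    convex_hull2d,
    region_count,
    topography,
)
from .synth_data import SynthConfig, simulate_reference_from_cheap

#: the empty-region queries reported by every run, in the stored
#: sign convention (eV)
DEFAULT_REGION_QUERIES = {
    "shallow_ip_deep_ea": "minus_ip>-6, minus_ea<-4",
    "shallow_ea_low_gap": "minus_ea>-1, optical_gap<2",
    "deep_ea_high_gap": "minus_ea<-4, optical_gap>4",
}


@dataclass
class RunConfig:
    out_dir: str | Path = "results/pipeline"
    seed: int = 0
    skeletons_file: str | Path | None = None  # default: bundled pool
    max_substituents: int = 2
    backend: str = "huckel"  # "huckel" | "table"
    huckel_params_file: str | Path | None = None
    table_file: str | Path | None = None  # cheap table when backend == "table"
    ip_increment: float = 0.5
    ea_increment: float = 0.5
    region_queries: dict = field(default_factory=lambda: dict(DEFAULT_REGION_QUERIES))

    def validate(self) -> None:
        if self.backend not in ("huckel", "table"):
            raise ValueError(f"unknown backend {self.backend!r}")
        for label, path in (
            ("skeletons_file", self.skeletons_file),
            ("huckel_params_file", self.huckel_params_file),
            ("table_file", self.table_file),
        ):
            if path is not None and not Path(path).is_file():
                raise FileNotFoundError(f"{label} does not exist: {path}")
        if self.backend == "table" and self.table_file is None:
            raise ValueError("backend 'table' requires table_file")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to out_dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
        "outputs": {},
    }

    def done(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})

    try:
        # 1. enumerate
        skeletons = (
            read_smiles_file(config.skeletons_file)
            if config.skeletons_file
            else load_skeleton_pool()
        )
        substituents = load_substituents()
        spec = LibrarySpec(
            skeletons=tuple(skeletons),
            substituents=tuple(substituents),
            max_substituents=config.max_substituents,
        )
        library = build_library(spec)
        library_to_frame(library).to_csv(out / "library.csv", index=False)
        manifest["outputs"]["library"] = "library.csv"
        done("enumerate", n_molecules=len(library), n_skeletons=len(skeletons))

        # 2. cheap properties
        if config.backend == "huckel":
            params = (
                HuckelParams.from_yaml(config.huckel_params_file)
                if config.huckel_params_file
                else HuckelParams()
            )
            backend = HuckelBackend(params=params)
        else:
            backend = TableBackend.from_csv(config.table_file)
        cheap, errors = run_backend(library, backend)
        write_property_table(cheap, out / "properties_cheap.csv")
        manifest["outputs"]["properties_cheap"] = "properties_cheap.csv"
        done("properties", backend=backend.name, n_records=len(cheap), n_errors=len(errors))

        # 3. synthetic reference + calibration
        synth = SynthConfig(seed=config.seed)
        reference = simulate_reference_from_cheap(cheap, synth)
        write_property_table(reference, out / "properties_reference.csv")
        models = fit_all(cheap, reference)
        calibrated = apply_calibration(models, cheap)
        write_property_table(calibrated, out / "properties_calibrated.csv")
        (out / "calibration.json").write_text(
            json.dumps({p: m.to_dict() for p, m in models.items()}, indent=2, sort_keys=True)
        )
        manifest["outputs"].update(
            {
                "properties_reference": "properties_reference.csv",
                "properties_calibrated": "properties_calibrated.csv",
                "calibration": "calibration.json",
            }
        )
        done(
            "calibrate",
            mae={p: round(m.mae_calibrated, 6) for p, m in models.items()},
        )

        # 4. fragments
        census = fragment_census(library, radius=1)
        filtered = filter_fragments(census)
        for name, c in (("fragments.csv", census), ("fragments_filtered.csv", filtered)):
            rows = sorted(((k, len(v)) for k, v in c.molecules.items()))
            with open(out / name, "w") as fh:
                fh.write("fragment,count\n")
                fh.writelines(f'"{k}",{n}\n' for k, n in rows)
        manifest["outputs"]["fragments"] = "fragments.csv"
        manifest["outputs"]["fragments_filtered"] = "fragments_filtered.csv"
        done("fragments", n_fragments=len(census), n_filtered=len(filtered))

        # 5. landscape: topography, hulls, region counts
        topo = topography(
            calibrated,
            library,
            TopographyConfig(config.ip_increment, config.ea_increment),
        )
        topo.to_frame().to_csv(out / "topography.csv", index=False)

        by_id = library.by_id()
        subsets = {
            "all_molecules": calibrated,
            "all_skeletons": [r for r in calibrated if not by_id[r.molecule_id].substituents],
        }
        hulls = {
            label: {
                "projection": ["minus_ip", "minus_ea"],
                "vertices": convex_hull2d(recs, subset_label=label).vertices.tolist(),
            }
            for label, recs in subsets.items()
            if recs
        }
        (out / "hulls.json").write_text(json.dumps(hulls, indent=2, sort_keys=True))

        regions = {
            name: region_count(calibrated, query)
            for name, query in config.region_queries.items()
        }
        (out / "region_counts.json").write_text(json.dumps(regions, indent=2, sort_keys=True))
        manifest["outputs"].update(
            {
                "topography": "topography.csv",
                "hulls": "hulls.json",
                "region_counts": "region_counts.json",
            }
        )
        done("landscape", n_cells=len(topo.cells), region_counts=regions)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
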