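"""Seeded synthetic generator of paired cheap/reference property tables.

The generator emulates the statistical structure the downstream
analyses rely on, without any quantum-chemistry engine:

* per-skeleton base (-IP, -EA, ΔO) triples drawn from a trivariate
  Gaussian whose default covariance reproduces the qualitative
  correlations of real screens (-IP and -EA positively correlated; the
  gap grows as -IP deepens and -EA shallows);
* substituent shifts with class-dependent sign (strong acceptors pull
  -IP and -EA down, strong donors push them up), magnitude that scales
  with the parent skeleton's own level — donor/acceptor groups bite
  hardest when they counteract the skeleton's natural electron richness
  or poverty — and a second substituent attenuated by a configurable
  factor (the observed "less than additive" behaviour);
* a reference table that is a near-linear (rigid-shift) transform of
  the cheap table plus Gaussian noise, the relation the calibration
  stage is built to recover.

All randomness flows through one ``numpy`` generator seeded from the
config; identical configs give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_core import PROPERTY_NAMES, PropertyRecord, Skeleton
from .datasets import load_skeleton_pool
from .enumeration import Library

#: floor applied to sampled optical gaps (eV)
GAP_FLOOR = 0.1


def _default_cov() -> np.ndarray:
    sd = np.array([0.8, 0.9, 0.7])
    corr = np.array(
        [
            [1.0, 0.6, -0.35],
            [0.6, 1.0, 0.35],
            [-0.35, 0.35, 1.0],
        ]
    )
    return corr * np.outer(sd, sd)


@dataclass
class SynthConfig:
    """Tunable knobs of the synthetic property generator (energies in eV)."""

    base_mean: tuple[float, float, float] = (-7.0, -1.8, 4.0)
    base_cov: np.ndarray = field(default_factory=_default_cov)
    # mean first-substituent shift of (-IP, -EA), by donor/acceptor class
    substituent_shift_means: dict = field(
        default_factory=lambda: {
            "strong_acceptor": {"minus_ip": -0.6, "minus_ea": -0.8},
            "strong_donor": {"minus_ip": 0.7, "minus_ea": 0.5},
            "other": {"minus_ip": 0.0, "minus_ea": 0.0},
        }
    )
    shift_jitter_sd: float = 0.15
    gap_shift_sd: float = 0.15
    second_substituent_attenuation: float = 0.7
    skeleton_dependence_slope: float = 0.25
    calib_slope: dict = field(
        default_factory=lambda: {"minus_ip": 0.95, "minus_ea": 0.92, "optical_gap": 1.08}
    )
    calib_intercept: dict = field(
        default_factory=lambda: {"minus_ip": 0.35, "minus_ea": -0.55, "optical_gap": -0.20}
    )
    noise_sd: dict = field(
        default_factory=lambda: {"minus_ip": 0.25, "minus_ea": 0.15, "optical_gap": 0.26}
    )
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.second_substituent_attenuation <= 1:
            raise ValueError("second_substituent_attenuation must be in (0, 1]")
        if any(self.noise_sd[p] < 0 for p in PROPERTY_NAMES):
            raise ValueError("noise_sd must be non-negative")
        if self.shift_jitter_sd < 0 or self.gap_shift_sd < 0:
            raise ValueError("shift standard deviations must be non-negative")
        acc = self.substituent_shift_means["strong_acceptor"]
        don = self.substituent_shift_means["strong_donor"]
        if not (acc["minus_ip"] <= 0 and acc["minus_ea"] <= 0):
            raise ValueError("acceptor shifts must move -IP and -EA downward")
        if not (don["minus_ip"] >= 0 and don["minus_ea"] >= 0):
            raise ValueError("donor shifts must move -IP and -EA upward")
        cov = np.asarray(self.base_cov, float)
        if cov.shape != (3, 3) or np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("base_cov must be a 3x3 positive semi-definite matrix")


def _shift_factor(cfg: SynthConfig, prop: str, parent_value: float) -> float:
    """Skeleton-dependent scaling of the substituent shift magnitude.

    The -IP shift grows for parents with inherently deeper -IP; the
    -EA shift grows for parents with inherently shallower -EA.
    """
    if prop == "minus_ip":
        raw = 1.0 + cfg.skeleton_dependence_slope * (cfg.base_mean[0] - parent_value)
    else:
        raw = 1.0 + cfg.skeleton_dependence_slope * (parent_value - cfg.base_mean[1])
    return float(np.clip(raw, 0.1, 3.0))


def simulate_properties(
    library: Library,
    config: SynthConfig,
    substituent_classes: dict[str, str],
    return_diagnostics: bool = False,
):
    """Generate paired cheap/reference tables for every library entry.

    ``substituent_classes`` maps substituent name -> donor/acceptor
    class.  Returns ``(cheap_records, reference_records)`` and, when
    requested, a diagnostics DataFrame holding the individual shift
    contributions of the first and second substituent per molecule.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    skeleton_ids = sorted({e.skeleton_id for e in library})
    base = {
        sid: rng.multivariate_normal(config.base_mean, np.asarray(config.base_cov, float))
        for sid in skeleton_ids
    }

    cheap: list[PropertyRecord] = []
    reference: list[PropertyRecord] = []
    diag_rows = []
    for entry in library:
        values = dict(zip(PROPERTY_NAMES, base[entry.skeleton_id]))
        shifts = []  # one (d_ip, d_ea, d_gap) per substituent, pre-attenuation
        for name in entry.substituents:
            cls = substituent_classes.get(name, "other")
            means = config.substituent_shift_means[cls]
            d_ip = (
                means["minus_ip"] * _shift_factor(config, "minus_ip", values["minus_ip"])
                + rng.normal(0.0, config.shift_jitter_sd)
            )
            d_ea = (
                means["minus_ea"] * _shift_factor(config, "minus_ea", values["minus_ea"])
                + rng.normal(0.0, config.shift_jitter_sd)
            )
            d_gap = rng.normal(0.0, config.gap_shift_sd)
            shifts.append((d_ip, d_ea, d_gap))
        att = config.second_substituent_attenuation
        applied = [
            tuple(s * (att if k == 1 else 1.0) for s in shift)
            for k, shift in enumerate(shifts)
        ]
        for d_ip, d_ea, d_gap in applied:
            values["minus_ip"] += d_ip
            values["minus_ea"] += d_ea
            values["optical_gap"] += d_gap
        values["optical_gap"] = max(values["optical_gap"], GAP_FLOOR)

        cheap.append(PropertyRecord(entry.id, level="cheap", **values))
        ref_values = {
            p: config.calib_slope[p] * values[p]
            + config.calib_intercept[p]
            + rng.normal(0.0, config.noise_sd[p])
            for p in PROPERTY_NAMES
        }
        ref_values["optical_gap"] = max(ref_values["optical_gap"], GAP_FLOOR)
        reference.append(PropertyRecord(entry.id, level="reference", **ref_values))

        if return_diagnostics:
            row = {"id": entry.id, "n_substituents": len(entry.substituents)}
            for k in range(2):
                for j, p in enumerate(PROPERTY_NAMES):
                    row[f"shift{k + 1}_{p}"] = applied[k][j] if k < len(applied) else np.nan
            diag_rows.append(row)

    if return_diagnostics:
        return cheap, reference, pd.DataFrame(diag_rows)
    return cheap, reference


def simulate_reference_from_cheap(
    cheap: list[PropertyRecord], config: SynthConfig
) -> list[PropertyRecord]:
    """Reference table as the configured linear transform of an existing
    cheap table plus Gaussian noise (used when the cheap values come from
    a real backend rather than the base-property sampler)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = []
    for rec in cheap:
        values = {
            p: config.calib_slope[p] * rec.value(p)
            + config.calib_intercept[p]
            + rng.normal(0.0, config.noise_sd[p])
            for p in PROPERTY_NAMES
        }
        values["optical_gap"] = max(values["optical_gap"], GAP_FLOOR)
        out.append(PropertyRecord(rec.molecule_id, level="reference", **values))
    return out


def make_fixture_skeletons(n: int, seed: int = 0) -> list[Skeleton]:
    """Deterministic sample of ``n`` skeletons from the curated pool."""
    pool = load_skeleton_pool()
    if n > len(pool):
        raise ValueError(f"requested {n} skeletons but the pool holds {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]
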