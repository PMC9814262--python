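"""Synthetic property generator: seed contract, shift structure, recovery."""

import numpy as np
import pytest

from aromap import (
    MoleculeEntry,
    SynthConfig,
    fit_calibration,
    load_skeleton_pool,
    make_fixture_skeletons,
    simulate_properties,
    simulate_reference_from_cheap,
)
from aromap.chem_core import PROPERTY_NAMES
from aromap.enumeration import Library


def synthetic_library(n_skeletons=50, subs_per_entry=(0, 1, 2), per_skeleton=20, homo=False):
    """A structural stand-in library (structures are placeholders; the
    generator only reads ids, skeleton ids and substituent multisets).

    Substituent names cycle through an acceptor/donor/other triple; with
    ``homo`` the multisets repeat one name (pairs of equals).
    """
    names = ("NO2", "NH2", "Me")
    entries = []
    k = 0
    for s in range(n_skeletons):
        sid = f"sk{s:03d}"
        entries.append(MoleculeEntry(f"m{k}", f"parent{s}", sid))
        k += 1
        for i in range(per_skeleton):
            n_sub = subs_per_entry[i % len(subs_per_entry)]
            if homo:
                subs = (names[i % 2],) * n_sub
            else:
                subs = tuple(names[(i + j) % 3] for j in range(n_sub))
            entries.append(MoleculeEntry(f"m{k}", f"x{s}_{i}", sid, substituents=subs))
            k += 1
    return Library(entries=entries)


CLASSES = {"NO2": "strong_acceptor", "NH2": "strong_donor", "Me": "other"}


class TestSeedContract:
    def test_same_seed_identical_different_seed_differs(self):
        lib = synthetic_library(n_skeletons=5, per_skeleton=4)
        a = simulate_properties(lib, SynthConfig(seed=7), CLASSES)
        b = simulate_properties(lib, SynthConfig(seed=7), CLASSES)
        c = simulate_properties(lib, SynthConfig(seed=8), CLASSES)
        assert a == b
        assert a != c


class TestDegenerateConfigs:
    def test_zero_noise_identity_map_equates_tables(self):
        lib = synthetic_library(n_skeletons=5, per_skeleton=4)
        cfg = SynthConfig(
            seed=1,
            calib_slope={p: 1.0 for p in PROPERTY_NAMES},
            calib_intercept={p: 0.0 for p in PROPERTY_NAMES},
            noise_sd={p: 0.0 for p in PROPERTY_NAMES},
        )
        cheap, ref = simulate_properties(lib, cfg, CLASSES)
        for c, r in zip(cheap, ref):
            for p in PROPERTY_NAMES:
                assert c.value(p) == pytest.approx(r.value(p))

    def test_invalid_configs_rejected_before_sampling(self):
        lib = synthetic_library(1, per_skeleton=1)
        with pytest.raises(ValueError, match="attenuation"):
            simulate_properties(lib, SynthConfig(second_substituent_attenuation=0.0), CLASSES)
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_properties(
                lib, SynthConfig(noise_sd={p: -1.0 for p in PROPERTY_NAMES}), CLASSES
            )
        bad = SynthConfig()
        bad.substituent_shift_means["strong_acceptor"]["minus_ea"] = +1.0
        with pytest.raises(ValueError, match="acceptor"):
            simulate_properties(lib, bad, CLASSES)


class TestShiftStructure:
    def test_second_substituent_attenuation_recovered(self):
        """mean |second shift| / mean |first shift| matches the configured
        attenuation within 3 standard errors (Monte-Carlo, ~1000 mols)."""
        lib = synthetic_library(n_skeletons=50, subs_per_entry=(2,), per_skeleton=20, homo=True)
        cfg = SynthConfig(seed=11, second_substituent_attenuation=0.7)
        _, _, diag = simulate_properties(lib, cfg, CLASSES, return_diagnostics=True)
        two = diag[diag.n_substituents == 2]
        s1 = np.abs(np.concatenate([two.shift1_minus_ip, two.shift1_minus_ea]))
        s2 = np.abs(np.concatenate([two.shift2_minus_ip, two.shift2_minus_ea]))
        ratio = s2.mean() / s1.mean()
        se = ratio * np.sqrt(
            s1.var() / (len(s1) * s1.mean() ** 2) + s2.var() / (len(s2) * s2.mean() ** 2)
        )
        assert abs(ratio - 0.7) < 3 * max(se, 1e-3)

    def test_donor_acceptor_shift_directions(self):
        lib = synthetic_library(n_skeletons=40, subs_per_entry=(1,), per_skeleton=10)
        cfg = SynthConfig(seed=3)
        _, _, diag = simulate_properties(lib, cfg, CLASSES, return_diagnostics=True)
        ids = {e.id: e.substituents for e in lib}
        diag["cls"] = diag["id"].map(lambda i: CLASSES.get(ids[i][0]) if ids[i] else None)
        acc = diag[diag.cls == "strong_acceptor"]
        don = diag[diag.cls == "strong_donor"]
        assert acc.shift1_minus_ea.mean() < 0 < don.shift1_minus_ea.mean()
        assert acc.shift1_minus_ip.mean() < 0 < don.shift1_minus_ip.mean()

    def test_shift_magnitude_tracks_parent_level(self):
        """Donor -IP shifts are larger for deeper--IP parents (the
        configured skeleton dependence)."""
        lib = synthetic_library(n_skeletons=60, subs_per_entry=(1,), per_skeleton=6)
        cfg = SynthConfig(seed=5, shift_jitter_sd=0.0)
        cheap, _, diag = simulate_properties(lib, cfg, CLASSES, return_diagnostics=True)
        by_id = {r.molecule_id: r for r in cheap}
        ids = {e.id: (e.skeleton_id, e.substituents) for e in lib}
        parents = {e.skeleton_id: e.id for e in lib if not e.substituents}
        rows = [
            (by_id[parents[ids[i][0]]].minus_ip, s)
            for i, s in zip(diag.id, diag.shift1_minus_ip)
            if ids[i][1] and CLASSES[ids[i][1][0]] == "strong_donor"
        ]
        parent_ip, shift = np.array(rows).T
        # deeper parent -IP (more negative) => larger positive donor shift
        assert np.corrcoef(parent_ip, shift)[0, 1] < -0.8


class TestCalibrationRecovery:
    def test_fit_recovers_true_slope_and_intercept(self):
        lib = synthetic_library(n_skeletons=50, per_skeleton=3)  # n = 200
        cfg = SynthConfig(seed=19)
        cheap, ref = simulate_properties(lib, cfg, CLASSES)
        for p in PROPERTY_NAMES:
            model = fit_calibration([c.value(p) for c in cheap], [r.value(p) for r in ref], p)
            assert abs(model.slope - cfg.calib_slope[p]) < 3 * model.stderr_slope
            assert abs(model.intercept - cfg.calib_intercept[p]) < 3 * model.stderr_intercept

    def test_reference_from_cheap_matches_configured_relation(self):
        lib = synthetic_library(n_skeletons=10, per_skeleton=2)
        cfg = SynthConfig(seed=2, noise_sd={p: 0.0 for p in PROPERTY_NAMES})
        cheap, _ = simulate_properties(lib, cfg, CLASSES)
        ref = simulate_reference_from_cheap(cheap, cfg)
        for c, r in zip(cheap, ref):
            for p in PROPERTY_NAMES:
                expected = cfg.calib_slope[p] * c.value(p) + cfg.calib_intercept[p]
                if p == "optical_gap":
                    expected = max(expected, 0.1)
                assert r.value(p) == pytest.approx(expected)


class TestFixtureSkeletons:
    def test_whole_pool_and_empty(self):
        pool = load_skeleton_pool()
        assert make_fixture_skeletons(len(pool), seed=0) == pool
        assert make_fixture_skeletons(0, seed=0) == []

    def test_deterministic_sampling(self):
        assert make_fixture_skeletons(4, seed=9) == make_fixture_skeletons(4, seed=9)

    def test_oversized_request_names_pool_size(self):
        with pytest.raises(ValueError, match="pool holds"):
            make_fixture_skeletons(999, seed=0)
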