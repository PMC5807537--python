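"""CIU fingerprints, shared-mixture state detection and transitions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vinlock.config import load_variant
from vinlock.ciu import (
    CIUFingerprint, ConformerState, build_fingerprint, detect_states,
    detect_transitions, stability_profile, compare_variants,
)
from vinlock.imms import fit_calibration
from vinlock.synthgen import (
    gen_ciu, gen_calibrants, default_calibration, state_occupancies,
)

MODEL = default_calibration()


def simple_records(voltages, ccs_centers, charge=17, mass=117000.0,
                   n_per=400, width=60.0, seed=0):
    """Unimodal (or per-voltage-specified) arrival peaks at given CCS."""
    from vinlock.imms import drift_from_ccs

    rng = np.random.default_rng(seed)
    rows = []
    for v, c in zip(voltages, ccs_centers):
        ccs = rng.normal(c, width, n_per)
        drift = drift_from_ccs(ccs, charge, mass, MODEL)
        bins = np.round(drift / 0.1).astype(int)
        uniq, cnt = np.unique(bins, return_counts=True)
        rows += [(charge, float(v), float(b * 0.1), int(n))
                 for b, n in zip(uniq, cnt)]
    return pd.DataFrame(rows, columns=["z", "voltage", "drift_ms", "intensity"])


class TestBuildFingerprint:
    def test_rows_normalised_and_unimodal(self):
        rec = simple_records([50, 100, 150, 200, 240], [6266] * 5)
        fp = build_fingerprint(rec, MODEL, 117000.0)
        np.testing.assert_allclose(fp.intensity.sum(axis=1), 1.0, atol=1e-9)
        # single narrow arrival peak: one dominant bin region per row
        assert (fp.intensity.max(axis=1) > 0.05).all()

    def test_mixed_charges_rejected(self):
        rec = simple_records([50, 100, 150, 200, 240], [6266] * 5)
        rec.loc[0, "z"] = 18
        with pytest.raises(ValueError, match="mixed charge"):
            build_fingerprint(rec, MODEL, 117000.0)

    def test_too_few_voltages_rejected(self):
        rec = simple_records([50, 100, 150], [6266] * 3)
        with pytest.raises(ValueError, match=">= 5"):
            build_fingerprint(rec, MODEL, 117000.0)

    def test_all_zero_row_flagged(self):
        rec = simple_records([50, 100, 150, 200, 240], [6266] * 5)
        rec.loc[rec["voltage"] == 150, "intensity"] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            fp = build_fingerprint(rec, MODEL, 117000.0)
        i = int(np.where(fp.voltages == 150)[0][0])
        assert not fp.row_valid[i]
        assert fp.intensity[i].sum() == 0.0

    def test_smoothing_preserves_row_sums(self):
        rec = simple_records([50, 100, 150, 200, 240], [6266] * 5)
        fp = build_fingerprint(rec, MODEL, 117000.0, smoothing_sigma_bins=2.0)
        np.testing.assert_allclose(fp.intensity.sum(axis=1), 1.0, atol=1e-9)

    def test_low_voltage_rows_center_on_closed_state(self):
        v = load_variant("vinculin")
        rec = gen_ciu(v, model=MODEL, seed=4)
        fp = build_fingerprint(rec, MODEL, v.mass_da)
        low = fp.intensity[fp.voltages <= 100]
        centers = (low * fp.ccs_axis).sum(axis=1)
        assert np.all(np.abs(centers - 6266.0) < 60.0)


class TestDetectStates:
    def test_single_component_data_one_state(self):
        rec = simple_records([50, 100, 150, 200, 240], [6266] * 5, n_per=2000)
        fp = build_fingerprint(rec, MODEL, 117000.0)
        with pytest.warns(UserWarning, match="resolvable"):
            states = detect_states(fp, max_states=3, seed=0)
        assert len(states) == 1
        np.testing.assert_allclose(states[0].occupancy, 1.0, atol=1e-9)

    def test_vinculin_three_states_at_printed_centroids(self):
        v = load_variant("vinculin")
        rec = gen_ciu(v, model=MODEL, seed=7)
        fp = build_fingerprint(rec, MODEL, v.mass_da)
        states = detect_states(fp, max_states=3, seed=7)
        assert [s.label for s in states] == ["C", "SO", "O"]
        for st, truth in zip(states, (6266.0, 6970.0, 7268.0)):
            assert abs(st.centroid - truth) < 50.0

    def test_t12_open_state_centroid(self):
        v = load_variant("t12")
        rec = gen_ciu(v, model=MODEL, seed=7)
        fp = build_fingerprint(rec, MODEL, v.mass_da)
        states = detect_states(fp, max_states=3, seed=7)
        assert abs(states[-1].centroid - 7173.0) < 50.0

    def test_labels_stable_under_matrix_rescaling(self):
        v = load_variant("vinculin")
        rec = gen_ciu(v, model=MODEL, seed=9)
        fp = build_fingerprint(rec, MODEL, v.mass_da)
        states = detect_states(fp, seed=1)
        rec2 = rec.copy()
        rec2["intensity"] *= 11
        fp2 = build_fingerprint(rec2, MODEL, v.mass_da)
        states2 = detect_states(fp2, seed=1)
        assert [s.label for s in states] == [s.label for s in states2]
        for a, b in zip(states, states2):
            assert a.centroid == pytest.approx(b.centroid, rel=5e-3)


class TestDetectTransitions:
    def _states(self, occ_by_label, voltages=None):
        voltages = voltages if voltages is not None \
            else np.arange(50.0, 245.0, 5.0)
        out = []
        for i, (label, occ) in enumerate(occ_by_label.items()):
            out.append(ConformerState(label, 6000.0 + 500 * i, 100.0,
                                      np.asarray(occ, float), voltages))
        return out

    def test_onset_completion_coexistence(self):
        volts = np.arange(50.0, 245.0, 5.0)
        c_occ = np.where(volts <= 180, 1.0, 0.0)
        so_occ = np.where(volts >= 140, 0.5, 0.0)
        states = self._states({"C": c_occ, "SO": so_occ}, volts)
        (tr,) = detect_transitions(states)
        assert tr.onset_voltage == 140.0
        assert tr.completion_voltage == 180.0
        assert tr.coexistence_width == 40.0
        assert tr.mode == "gradual"

    def test_abrupt_switch(self):
        volts = np.arange(50.0, 245.0, 5.0)
        c_occ = np.where(volts < 140, 1.0, 0.0)
        so_occ = np.where(volts >= 140, 1.0, 0.0)
        states = self._states({"C": c_occ, "SO": so_occ}, volts)
        (tr,) = detect_transitions(states)
        assert tr.mode == "abrupt"
        assert tr.coexistence_width <= 0

    def test_absent_state_reported(self):
        volts = np.arange(50.0, 245.0, 5.0)
        states = self._states({"C": np.ones_like(volts),
                               "SO": np.zeros_like(volts)}, volts)
        (tr,) = detect_transitions(states)
        assert tr.mode == "absent"
        assert tr.onset_voltage is None

    def test_threshold_monotonicity(self):
        """Coexistence widens monotonically as the presence threshold
        drops toward zero."""
        v = load_variant("vinculin")
        rec = gen_ciu(v, model=MODEL, seed=5)
        fp = build_fingerprint(rec, MODEL, v.mass_da)
        states = detect_states(fp, seed=5)
        widths = []
        for thr in (0.30, 0.20, 0.10, 0.05, 0.02):
            (tr, _) = detect_transitions(states, presence_threshold=thr)
            widths.append(tr.coexistence_width)
        assert widths == sorted(widths)

    def test_single_state_rejected(self):
        states = self._states({"C": np.ones(39)})
        with pytest.raises(ValueError):
            detect_transitions(states)


class TestStability:
    def test_t12_a974k_semi_open_less_stable_than_t12(self):
        dwell = {}
        for name in ("t12", "t12_a974k"):
            v = load_variant(name)
            rec = gen_ciu(v, model=MODEL, seed=11)
            fp = build_fingerprint(rec, MODEL, v.mass_da)
            states = detect_states(fp, seed=11)
            prof = stability_profile(states)
            dwell[name] = float(
                prof.loc[prof["state"] == "SO", "dwell_v"].iloc[0]
            )
        assert dwell["t12_a974k"] < dwell["t12"]

    def test_persistent_state_spans_grid(self):
        volts = np.arange(50.0, 245.0, 5.0)
        st = ConformerState("C", 6266.0, 100.0, np.ones_like(volts), volts)
        prof = stability_profile([st])
        assert prof.loc[0, "dwell_v"] == pytest.approx(volts[-1] - volts[0] + 5)

    def test_never_present_state_zero_dwell(self):
        volts = np.arange(50.0, 245.0, 5.0)
        st = ConformerState("O", 7268.0, 100.0, np.zeros_like(volts), volts)
        assert stability_profile([st]).loc[0, "dwell_v"] == 0.0


class TestCompareVariants:
    def test_identical_fingerprints_zero_difference(self):
        v = load_variant("vinculin")
        rec = gen_ciu(v, model=MODEL, seed=2)
        fp = build_fingerprint(rec, MODEL, v.mass_da)
        out = compare_variants({"a": fp, "b": fp}, overlay_voltages=(125.0,))
        ov = out["overlays"][125.0]
        np.testing.assert_allclose(ov["a"], ov["b"], atol=1e-12)
        assert out["onsets"]["onset_v"].nunique() == 1

    def test_t12_semi_open_before_vinculin_at_125v(self):
        fps = {}
        for name in ("vinculin", "t12"):
            v = load_variant(name)
            rec = gen_ciu(v, model=MODEL, seed=3)
            fps[name] = build_fingerprint(rec, MODEL, v.mass_da)
        out = compare_variants(fps, overlay_voltages=(125.0,))
        ov = out["overlays"][125.0]
        above = ov["ccs"] > 6500.0
        assert ov.loc[above, "t12"].sum() > ov.loc[above, "vinculin"].sum()

    def test_onset_order_across_all_variants(self):
        fps = {}
        for name in ("vinculin", "metavinculin", "t12", "t12_a974k"):
            v = load_variant(name)
            rec = gen_ciu(v, model=MODEL, seed=6)
            fps[name] = build_fingerprint(rec, MODEL, v.mass_da)
        onsets = compare_variants(fps)["onsets"].set_index("variant")["onset_v"]
        assert onsets["t12"] == onsets["t12_a974k"] == 120.0
        assert onsets["vinculin"] == onsets["metavinculin"] == 140.0


def test_parameter_recovery_across_seeds():
    """Generator truths (centroids, onsets) recovered over repeated seeded
    runs: centroids within sampling error, onsets within one 5 V step."""
    v = load_variant("vinculin")
    truth = {"C": 6266.0, "SO": 6970.0, "O": 7268.0}
    n_ok_cent = n_ok_onset = 0
    seeds = range(20)
    for seed in seeds:
        rec = gen_ciu(v, model=MODEL, seed=100 + seed)
        fp = build_fingerprint(rec, MODEL, v.mass_da)
        states = detect_states(fp, seed=100 + seed)
        if len(states) == 3 and all(
            abs(st.centroid - truth[st.label]) <= 50.0 for st in states
        ):
            n_ok_cent += 1
        trs = detect_transitions(states) if len(states) >= 2 else []
        if trs and trs[0].onset_voltage is not None \
                and abs(trs[0].onset_voltage - 140.0) <= 5.0:
            n_ok_onset += 1
    assert n_ok_cent >= 18    # >= 90% of runs
    assert n_ok_onset >= 18
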