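"""Synthetic generator: beat construction, mixing modes, cohort structure."""

import dataclasses
import warnings

import numpy as np
import pytest

from conftest import P2_INPUTS, P2_OUTPUTS, stack_augmented, stack_leads
from ecgrecon import (
    SynthConfig,
    WaveShape,
    build_augmented_input,
    default_morphology,
    delineate,
    filter_metadata,
    fit_ols,
    generate_beat,
    generate_cohort,
    make_mixing,
    measured_snr_db,
    predict,
)
from ecgrecon.io import STANDARD_LEADS


class TestGenerateBeat:
    def test_disjoint_supports(self):
        components, bounds, r_idx = generate_beat(default_morphology(), 500.0)
        assert bounds["P"][1] <= bounds["QRS"][0] < bounds["QRS"][1] <= bounds["T"][0]
        assert bounds["QRS"][0] <= r_idx < bounds["QRS"][1]
        for wave, (on, off) in bounds.items():
            x = components[wave]
            assert np.all(x[:on] == 0) and np.all(x[off:] == 0)
            assert x[on] != 0 and x[off - 1] != 0  # bounds exactly hug the support

    def test_r_amplitude_doubling_is_linear(self):
        morph = default_morphology()
        base, _, _ = generate_beat(morph, 500.0)
        morph["R"] = WaveShape(2 * 1.10, morph["R"].center_s, morph["R"].width_s)
        morph["Q"] = WaveShape(2 * -0.12, morph["Q"].center_s, morph["Q"].width_s)
        morph["S"] = WaveShape(2 * -0.25, morph["S"].center_s, morph["S"].width_s)
        doubled, _, _ = generate_beat(morph, 500.0)
        np.testing.assert_array_equal(doubled["QRS"], 2.0 * base["QRS"])
        np.testing.assert_array_equal(doubled["P"], base["P"])
        np.testing.assert_array_equal(doubled["T"], base["T"])

    def test_overlapping_morphology_rejected(self):
        morph = default_morphology()
        morph["T"] = WaveShape(0.45, 0.080, 0.030)  # T starts inside the QRS
        with pytest.raises(ValueError, match="overlap"):
            generate_beat(morph, 500.0)

    def test_delineation_recovers_constructed_fiducials(self, global_cohort):
        """Cross-module check: the detector lands within 10 ms of construction."""
        it = global_cohort.items[3]
        detected = delineate(it.record)
        tol = round(0.010 * it.record.fs)
        for tb, db in zip(it.fiducials.beats, detected.beats):
            for f in ("p_on", "p_off", "qrs_on", "qrs_off", "t_on", "t_off"):
                assert abs(getattr(db, f) - getattr(tb, f)) <= tol


class TestGenerateRecord:
    def test_global_mixing_exact_linearity(self, global_cohort):
        """Every lead is an exact linear function of three independent leads."""
        X = stack_leads(global_cohort, P2_INPUTS)
        for lead in P2_OUTPUTS + ("III", "aVF"):
            y = stack_leads(global_cohort, (lead,))
            m = fit_ols(X, y)
            assert np.max(np.abs(predict(m, X) - y)) < 1e-9

    def test_per_wave_mixing_breaks_three_lead_model(self, per_wave_cohort):
        X3 = stack_leads(per_wave_cohort, P2_INPUTS)
        y = stack_leads(per_wave_cohort, ("V4",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            m3 = fit_ols(X3, y)
        resid3 = np.max(np.abs(predict(m3, X3) - y))
        assert resid3 > 1e-3  # strictly positive residual: misspecified
        X6 = stack_augmented(per_wave_cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            m6 = fit_ols(X6, y)
        assert np.max(np.abs(predict(m6, X6) - y)) < 1e-9

    def test_determinism(self):
        cfg = SynthConfig(n_patients=2, noise_snr_db=20, seed=77)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for ia, ib in zip(a.items, b.items):
            np.testing.assert_array_equal(ia.record.samples, ib.record.samples)

    def test_limb_lead_identities_by_construction(self, global_cohort):
        rec = global_cohort.items[0].record
        i, ii = rec.lead("I"), rec.lead("II")
        np.testing.assert_allclose(rec.lead("III"), ii - i, atol=1e-12)
        np.testing.assert_allclose(rec.lead("aVR"), -(i + ii) / 2, atol=1e-12)
        np.testing.assert_allclose(rec.lead("aVL"), i - ii / 2, atol=1e-12)
        np.testing.assert_allclose(rec.lead("aVF"), ii - i / 2, atol=1e-12)

    def test_noise_snr_calibration(self, noisy_cohort):
        mixing = noisy_cohort.mixing
        for it in noisy_cohort.items[:3]:
            clean = it.sources @ mixing.gains.T + mixing.offsets[None, :]
            for j in (0, 1, 8):  # I, II, V3
                snr = measured_snr_db(clean[:, j], it.record.samples[:, j])
                assert abs(snr - 20.0) <= 1.0

    def test_fiducial_invariants(self):
        for seed in range(6):
            cohort = generate_cohort(SynthConfig(n_patients=2, seed=2000 + seed))
            for it in cohort.items:
                it.fiducials.validate(it.record.n_samples)

    def test_sources_vanish_outside_fiducials(self, global_cohort):
        it = global_cohort.items[0]
        for w, wave in enumerate(("P", "QRS", "T")):
            mask = np.zeros(it.record.n_samples, dtype=bool)
            for on, off in it.fiducials.segments(wave):
                mask[on:off] = True
            assert np.all(it.sources[~mask, w] == 0.0)
            assert np.any(it.sources[mask, w] != 0.0)


class TestMixing:
    def test_truth_map_requires_spanning_inputs(self):
        mixing = make_mixing("per_wave", disparity=0.2)
        with pytest.raises(ValueError):
            mixing.truth_linear_map(P2_INPUTS, ("V4",))

    def test_global_truth_map_exact(self):
        mixing = make_mixing("global")
        A, C = mixing.truth_linear_map(P2_INPUTS, P2_OUTPUTS)
        assert A.shape == (5, 3) and C.shape == (5,)
        M_in = np.stack([mixing.row(l) for l in P2_INPUTS])
        M_out = np.stack([mixing.row(l) for l in P2_OUTPUTS])
        np.testing.assert_allclose(A @ M_in, M_out, atol=1e-12)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            make_mixing("sideways")


class TestGenerateCohort:
    def test_counts_and_distinct_patients(self):
        cohort = generate_cohort(SynthConfig(n_patients=10, seed=1))
        assert len(cohort) == 10
        assert len({it.record.patient_id for it in cohort.items}) == 10
        assert all(it.record.lead_names == STANDARD_LEADS for it in cohort.items)

    def test_records_per_patient_share_morphology(self):
        cohort = generate_cohort(SynthConfig(n_patients=3, records_per_patient=2, seed=9))
        assert len(cohort) == 6
        by_pat = {}
        for it in cohort.items:
            by_pat.setdefault(it.record.patient_id, []).append(it)
        for items in by_pat.values():
            assert len(items) == 2
            # same morphology/heart rate: same beat count and close R spacing
            assert len(items[0].fiducials.beats) == pytest.approx(
                len(items[1].fiducials.beats), abs=1
            )

    def test_injected_rows_filtered(self):
        cohort = generate_cohort(
            SynthConfig(n_patients=8, seed=4, n_duplicate_patients=1, n_abnormal=1,
                        n_blank_leads=1)
        )
        assert len(cohort) == 11
        kept = filter_metadata(cohort.metadata)
        assert len(kept) == 8
        assert kept == list(range(8))

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            generate_cohort(SynthConfig(n_patients=0))

    def test_blank_lead_is_actually_blank(self):
        cohort = generate_cohort(SynthConfig(n_patients=2, seed=4, n_blank_leads=1))
        blank_item = cohort.items[-1]
        assert blank_item.metadata.has_blank_lead
        assert np.all(blank_item.record.lead("V6") == 0.0)
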