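"""Generators: determinism, ground-truth consistency, marginal statistics."""

import numpy as np
import pytest
from pydantic import ValidationError

from retinagel import synthgen
from retinagel.io import PackingError, PresetError
from retinagel.synthgen import (DEGRADATION_PRESETS, FIELD_PRESETS,
                                GELATION_PRESETS, INTERFACE_PRESETS,
                                OCT_PRESETS, RETINA_PRESETS,
                                DegradationPreset, FieldPreset,
                                GelationPreset, RetinaSectionPreset,
                                render_field, render_interface,
                                render_oct_series, render_retina_sections,
                                simulate_degradation, simulate_gelation_tracks)


# -------------------------------------------------------------- determinism

def test_generators_are_deterministic_given_seed():
    """Bit-identical outputs on repeated calls with the same seed."""
    p = GELATION_PRESETS["gtn_hpa"]
    a, _ = simulate_gelation_tracks(p, seed=7)
    b, _ = simulate_gelation_tracks(p, seed=7)
    np.testing.assert_array_equal(a[0].x, b[0].x)
    np.testing.assert_array_equal(a[-1].y, b[-1].y)

    d1, _ = simulate_degradation(DEGRADATION_PRESETS["ipn75"], "collagenase",
                                 seed=7)
    d2, _ = simulate_degradation(DEGRADATION_PRESETS["ipn75"], "collagenase",
                                 seed=7)
    np.testing.assert_array_equal(d1.released_fraction, d2.released_fraction)

    f1, t1 = render_field(FIELD_PRESETS["default"], seed=7)
    f2, t2 = render_field(FIELD_PRESETS["default"], seed=7)
    np.testing.assert_array_equal(f1["live"], f2["live"])
    assert t1.equals(t2)

    s1, _ = render_interface(INTERFACE_PRESETS["ipn50"], seed=7)
    s2, _ = render_interface(INTERFACE_PRESETS["ipn50"], seed=7)
    np.testing.assert_array_equal(s1[0].gel_mask, s2[0].gel_mask)


# ----------------------------------------------------------------- gelation

def test_alpha_curve_crosses_half_at_programmed_gel_point():
    p = GELATION_PRESETS["gtn_hpa"]
    assert p.alpha_of(p.t_gel) == pytest.approx(0.5)
    assert p.t_alpha_half == pytest.approx(42.0)
    # liquid well before, gel well after
    assert p.alpha_of(0.0) > 0.85
    assert float(p.alpha_of(p.duration)) < 0.15


def test_zero_amplitude_freezes_beads():
    p = GELATION_PRESETS["gtn_hpa"].model_copy(update={"msd_amplitude": 0.0})
    tracks, _ = simulate_gelation_tracks(p, seed=1)
    for tr in tracks[:3]:
        np.testing.assert_array_equal(tr.x, 0.0)
        np.testing.assert_array_equal(tr.y, 0.0)


def test_constant_alpha_one_is_diffusive():
    """Windowed log-log MSD slope stays ~1 for a pure liquid."""
    from retinagel.rheolab import compute_msd, msd_to_moduli, GSERParams
    rng = np.random.default_rng(3)
    tracks = synthgen.simulate_tracks_constant_alpha(
        1.0, 0.2, n_beads=30, frame_interval=0.1, duration=60.0, rng=rng)
    curves = compute_msd(tracks, window=10.0, every=10.0, max_lag=1.0)
    alphas = [msd_to_moduli(c, GSERParams()).alpha for c in curves]
    assert np.median(alphas) > 0.9


def test_gelation_preset_validation():
    with pytest.raises(ValidationError):
        GelationPreset(name="bad", t_gel=100.0, alpha_liquid=0.9,
                       alpha_gel=0.1, transition_width=5.0, msd_amplitude=0.1,
                       n_beads=5, frame_interval=0.1, duration=50.0)  # < t_gel
    with pytest.raises(ValidationError):
        GelationPreset(name="bad", t_gel=1.0, alpha_liquid=0.9, alpha_gel=0.1,
                       transition_width=5.0, msd_amplitude=0.1, n_beads=5,
                       frame_interval=1.0, duration=1.5)  # too short


# -------------------------------------------------------------- degradation

def test_degradation_noiseless_plateaus_match_composition():
    p = DEGRADATION_PRESETS["ipn75"].model_copy(update={"noise_sd": 0.0,
                                                        "duration": 600.0})
    coll, truth_c = simulate_degradation(p, "collagenase", seed=1)
    hyal, truth_h = simulate_degradation(p, "hyaluronidase", seed=1)
    both, truth_b = simulate_degradation(p, "both", seed=1)
    assert truth_c["f_target"] == pytest.approx(0.75)
    assert truth_h["f_target"] == pytest.approx(0.25)
    assert truth_b["f_target"] == pytest.approx(1.0)
    assert coll.released_fraction[-1] == pytest.approx(0.75, abs=1e-6)
    assert both.released_fraction[-1] == pytest.approx(1.0, abs=1e-3)


def test_degradation_homopolymer_fully_degrades():
    p = DEGRADATION_PRESETS["gtn_hpa"].model_copy(update={"noise_sd": 0.0,
                                                          "duration": 600.0})
    s, _ = simulate_degradation(p, "collagenase", seed=1)
    assert s.released_fraction[-1] == pytest.approx(1.0, abs=1e-6)


def test_degradation_series_stays_clipped():
    p = DEGRADATION_PRESETS["ipn75"].model_copy(update={"noise_sd": 0.5})
    s, _ = simulate_degradation(p, "both", seed=1)
    assert s.released_fraction.min() >= 0.0
    assert s.released_fraction.max() <= 1.0


def test_unknown_enzyme_rejected():
    with pytest.raises(PresetError):
        simulate_degradation(DEGRADATION_PRESETS["ipn75"], "trypsin")


# -------------------------------------------------------------- cell fields

def test_field_truth_table_matches_requested_counts():
    p = FIELD_PRESETS["viability70"]
    channels, truth = render_field(p, seed=1)
    assert len(truth) == p.n_live + p.n_dead
    viability = 100.0 * (truth.channel == "live").mean()
    assert viability == pytest.approx(70.0)


def test_blank_field_has_empty_truth():
    p = FieldPreset(name="blank", n_live=0, n_dead=0)
    channels, truth = render_field(p, seed=1)
    assert len(truth) == 0
    assert channels["live"].max() < 0.5   # background noise only


def test_overpacked_field_raises():
    p = FieldPreset(name="packed", n_live=4000, n_dead=0,
                    image_shape=(64, 64))
    with pytest.raises(PackingError):
        render_field(p, seed=1)


# ------------------------------------------------------------ retina fields

def test_retina_layer_fractions_marginal_recovery():
    """Truth layer draws match the preset occupancies within 3 SE."""
    p = RETINA_PRESETS["ipn50"]
    gcl = total = 0
    for seed in range(4):
        _, truth = render_retina_sections(p, seed=seed, n_fields=5)
        cells = truth["cells"]
        gcl += (cells.layer == "GCL").sum()
        total += len(cells)
    frac = gcl / total
    se = np.sqrt(0.40 * 0.60 / total)
    assert abs(frac - 0.40) < 3 * se


def test_retina_all_gcl_preset():
    p = RETINA_PRESETS["ipn50"].model_copy(
        update={"layer_fractions": {"GCL": 1.0}})
    _, truth = render_retina_sections(p, seed=1, n_fields=2)
    assert (truth["cells"].layer == "GCL").all()


def test_retina_unknown_layer_name_rejected():
    with pytest.raises(ValidationError):
        RetinaSectionPreset(name="bad", engraft_fraction=0.5,
                            n_cells_per_field=5, n_fields=1,
                            layer_fractions={"GCL": 0.5, "sclera": 0.5})


def test_retina_scale_extrapolates_to_engraft_fraction():
    p = RETINA_PRESETS["ipn50"]
    expected = p.engraft_fraction * p.injected_total
    assert p.n_cells_per_field * p.fields_per_retina_scale == pytest.approx(expected)


# ----------------------------------------------------------------- interface

def test_interface_extreme_probabilities():
    p = INTERFACE_PRESETS["ipn50"].model_copy(update={"attach_prob": 1.0,
                                                      "n_slides": 2})
    slides, _ = render_interface(p, seed=1)
    assert all(s.flags.all() for s in slides)
    p0 = p.model_copy(update={"attach_prob": 0.0})
    slides, _ = render_interface(p0, seed=1)
    assert not any(s.flags.any() for s in slides)


def test_interface_marginal_attachment_near_preset():
    p = INTERFACE_PRESETS["ipn50"]
    means = []
    for seed in range(10):
        slides, _ = render_interface(p, seed=seed)
        means.append(np.mean([s.flags.mean() for s in slides]))
    grand = float(np.mean(means))
    assert abs(grand - p.attach_prob) < 0.05


def test_interface_gel_touches_boundary_only_where_attached():
    slides, _ = render_interface(INTERFACE_PRESETS["ipn50"], seed=2)
    s = slides[0]
    cols = np.flatnonzero(s.retina_mask.any(axis=0))
    tops = np.argmax(s.retina_mask[:, cols], axis=0)
    touching = s.gel_mask[tops - 1, cols]
    np.testing.assert_array_equal(touching, s.flags)


# ----------------------------------------------------------------- OCT

def test_oct_truth_counts_follow_decay():
    p = OCT_PRESETS["halflife_demo"]
    stacks, truth = render_oct_series(p, seed=1)
    assert truth.gel_px.iloc[0] == p.gel_px_day0
    ratio = truth.gel_px.iloc[1] / truth.gel_px.iloc[0]
    assert ratio == pytest.approx(0.5, abs=0.01)
    assert (np.diff(truth.gel_px) <= 0).all()


def test_oct_zero_gel_and_zero_rate():
    ctrl, truth = render_oct_series(OCT_PRESETS["control"], seed=1)
    assert (truth.gel_px == 0).all()
    p = OCT_PRESETS["halflife_demo"].model_copy(update={"decay_rate": 0.0,
                                                        "n_days": 3})
    _, truth = render_oct_series(p, seed=1)
    assert (truth.normalized_mass == 1.0).all()
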