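import numpy as np
import pytest

import afrecur as af
from afrecur.data import AnalysisConfig
from afrecur.hrv import (DELTA_SET_NAMES, FEATURE_NAMES, FEATURE_SET_NAMES,
                         hrv_feature_set)
from naive_oracles import naive_dfa, naive_entropies

RNG = np.random.default_rng(20240917)


@pytest.mark.parametrize(
    "series, expected",
    [
        ([800, 810, 790, 805],
         dict(mean=801.25, sdnn=8.539125638299666, rmssd=15.545631755148024,
              pnn50=0.0, pnn20=0.0)),
        ([800, 825, 810], dict(mean=811.6666666666666, pnn50=0.0, pnn20=50.0)),
        ([700.0] * 10, dict(mean=700.0, sdnn=0.0, rmssd=0.0, pnn50=0.0,
                            pnn20=0.0)),
    ],
)
def test_time_domain_matches_hand_computed_values(series, expected):
    out = af.time_domain(series)
    for key, val in expected.items():
        assert out[key] == pytest.approx(val, abs=1e-9)


def test_time_domain_needs_two_intervals():
    with pytest.raises(ValueError):
        af.time_domain([800.0])


def test_triangular_index_on_uniform_histogram():
    # 4 equally tall bins of 25 beats each -> TRI = n / modal = 4
    values = np.repeat([805.0, 815.0, 825.0, 835.0], 25)
    out = af.geometric(values, bin_width=10.0)
    assert out["tri"] == pytest.approx(4.0)


def test_degenerate_single_bin_histogram():
    out = af.geometric(np.full(30, 800.0), bin_width=10.0)
    assert out["tri"] == pytest.approx(1.0)
    assert out["tinn"] == pytest.approx(10.0)


def test_tinn_recovers_triangular_support_width():
    # histogram heights 1,2,3,4,5,4,3,2,1 at 10-ms bins: the generating
    # triangle has its feet 5 bins either side of the apex -> base 100 ms
    centers = 755.0 + 10.0 * np.arange(9)
    heights = [1, 2, 3, 4, 5, 4, 3, 2, 1]
    values = np.repeat(centers, heights)
    out = af.geometric(values, bin_width=10.0)
    assert abs(out["tinn"] - 100.0) <= 20.0


def test_entropies_zero_for_perfectly_regular_series():
    # constant series hits the SDNN = 0 convention
    out = af.entropies(np.full(60, 800.0))
    assert out == {"apen": 0.0, "sampen": 0.0}
    # strictly increasing ramp with tolerance wide enough to match everything
    ramp = 800.0 + 0.5 * np.arange(80)
    out = af.entropies(ramp, m=2, r_fraction=50.0)
    assert out["apen"] == pytest.approx(0.0, abs=1e-12)
    assert out["sampen"] == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_entropies_match_naive_template_counting(seed):
    x = 800.0 + 30.0 * np.random.default_rng(seed).standard_normal(120)
    ours = af.entropies(x)
    naive = naive_entropies(x)
    assert ours["apen"] == pytest.approx(naive["apen"], abs=1e-10)
    assert ours["sampen"] == pytest.approx(naive["sampen"], abs=1e-10)


def test_poincare_identity_and_alternating_series():
    x = 800.0 + 40.0 * RNG.standard_normal(200)
    out = af.poincare(x)
    sdnn = np.std(x, ddof=1)
    assert out["sd1"] ** 2 + out["sd2"] ** 2 == pytest.approx(2 * sdnn**2,
                                                              rel=1e-9)
    alt = np.tile([800.0, 900.0], 50)
    alt_out = af.poincare(alt)
    assert alt_out["sd1"] > alt_out["sd2"]
    const = af.poincare(np.full(50, 800.0))
    assert const["sd1"] == const["sd2"] == 0.0
    assert np.isnan(const["sd1sd2_ratio"])


def test_dfa_matches_naive_oracle():
    x = 800.0 + 35.0 * np.random.default_rng(11).standard_normal(400)
    ours = af.dfa(x)
    naive = naive_dfa(x)
    assert ours["dfa_alpha1"] == pytest.approx(naive["dfa_alpha1"], abs=1e-8)
    assert ours["dfa_alpha2"] == pytest.approx(naive["dfa_alpha2"], abs=1e-8)


def test_dfa_alpha2_missing_when_series_too_short():
    x = 800.0 + 10.0 * RNG.standard_normal(33)
    out = af.dfa(x)
    assert np.isfinite(out["dfa_alpha1"])
    assert np.isnan(out["dfa_alpha2"])


def test_delta_group_formula_and_zero_baseline():
    first = {n: 40.0 for n in FEATURE_SET_NAMES}
    last = dict(first, rmssd=30.0)
    deltas, flagged = af.delta_group(first, last)
    assert deltas["rmssd"] == pytest.approx(25.0)
    assert all(deltas[n] == 0.0 for n in DELTA_SET_NAMES if n != "rmssd")
    assert not flagged
    assert set(deltas) == set(DELTA_SET_NAMES)

    first_zero = dict(first, sdnn=0.0)
    deltas, flagged = af.delta_group(first_zero, last)
    assert np.isnan(deltas["sdnn"])
    assert flagged == ["sdnn"]


def test_aoi_slicing_and_boundary_overlap(default_cohort):
    rec = default_cohort.records[0]
    fb = rec.flashback.intervals
    aois = af.extract_aois(rec)
    assert np.array_equal(aois.whole_flashback.intervals, fb)
    assert np.array_equal(aois.first300.intervals, fb[:300])
    assert np.array_equal(aois.last100.intervals, fb[-100:])
    assert np.array_equal(aois.af_onset.intervals, rec.af_episode.intervals)

    short = af.ICMRecord(
        patient_id="B1",
        flashback=af.RRSeries(800.0 + np.arange(301.0)),
        af_episode=rec.af_episode,
        clinical=rec.clinical, recurrence=0)
    aois = af.extract_aois(short)
    # B = beats 1..300 and C = beats 202..301 overlap, as defined
    assert np.array_equal(aois.first300.intervals,
                          short.flashback.intervals[:300])
    assert np.array_equal(aois.last100.intervals,
                          short.flashback.intervals[201:])

    with pytest.raises(ValueError, match="AoI B"):
        af.extract_aois(short, AnalysisConfig(first_beats=350))


def test_feature_vector_is_deterministic_and_complete(default_cohort):
    rec = default_cohort.records[0]
    fv1 = af.assemble_feature_vector(rec)
    fv2 = af.assemble_feature_vector(rec)
    assert tuple(fv1.values.index) == FEATURE_NAMES
    assert len(fv1.values) == 58
    assert fv1.values.equals(fv2.values)


def test_pnn_ordering_over_random_series():
    for seed in range(20):
        x = 800.0 + 45.0 * np.random.default_rng(seed).standard_normal(150)
        out = af.time_domain(x)
        assert out["pnn50"] <= out["pnn20"]


def test_scaling_equivariance_of_feature_battery():
    """Scaling intervals by a power of two (exact in floating point) scales
    ms-denominated features by the same factor and leaves dimensionless
    ones unchanged; entropies are invariant because r tracks SDNN."""
    x = 800.0 + 35.0 * np.random.default_rng(4).standard_normal(250)
    cfg = AnalysisConfig()
    c = 2.0
    base = hrv_feature_set(x, cfg)
    scaled = hrv_feature_set(
        c * x, AnalysisConfig(geometric_bin_width_ms=c * cfg.geometric_bin_width_ms))
    equivariant = ("mean", "sdnn", "rmssd", "tinn", "sd1", "sd2")
    invariant = ("tri", "sd1sd2_ratio", "apen", "sampen",
                 "dfa_alpha1", "dfa_alpha2", "pnn50")
    for name in equivariant:
        assert scaled[name] == pytest.approx(c * base[name], rel=1e-9)
    for name in invariant:
        if name.startswith("pnn"):
            continue  # pNN thresholds are absolute ms, not scale-free
        assert scaled[name] == pytest.approx(base[name], rel=1e-8)


def test_extractor_transform_returns_58_columns(small_cohort):
    frame = af.HRVFeatureExtractor().fit_transform(small_cohort)
    assert frame.shape == (len(small_cohort), 58)
    assert tuple(frame.columns) == FEATURE_NAMES
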