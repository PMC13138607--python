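"""Synthetic fixtures: exactness, noise statistics, self-consistency."""

import numpy as np
import pytest

from icglimit import (
    FilterSet,
    ICG_TISSUE,
    NoiseModel,
    SyntheticTruth,
    TISSUE_MEDIUM,
    TissueScenario,
    make_concentration_series,
    make_skin_series,
    nmin_curve,
    separate_table,
    skin_series_frame,
)
from icglimit.background_separation import SignalRecord, separate_background

NOISELESS = NoiseModel(shot_noise=False, floor_fraction=0.0)


def test_truth_validation():
    with pytest.raises(ValueError, match=">= 0"):
        SyntheticTruth(wavelengths=(650.0, 785.0), true_saf=(100.0, -1.0),
                       true_ssc=(10.0, 10.0), rd_ratio=0.8, s_f0=1000.0)
    with pytest.raises(ValueError, match="monotone"):
        SyntheticTruth(wavelengths=(650.0, 785.0), true_saf=(100.0, 200.0),
                       true_ssc=(10.0, 10.0), rd_ratio=0.8, s_f0=1000.0)


def test_default_truth_pins_measured_anchors():
    truth = SyntheticTruth.default()
    i785 = truth.wavelengths.index(785.0)
    assert truth.true_saf[i785] == pytest.approx(3200.0, rel=1e-12)
    assert truth.s_f0 == pytest.approx(20_000.0)
    ratios = np.array(truth.true_saf) / np.array(truth.true_ssc)
    assert ratios[truth.wavelengths.index(650.0)] == pytest.approx(25.0)
    assert ratios[truth.wavelengths.index(792.0)] == pytest.approx(4.0)


def test_noiseless_af_reference_ratio_is_exact():
    records, _ = make_skin_series(noise=NOISELESS)
    rec785 = next(r for r in records if r.wavelength == 785.0)
    sep = separate_background(rec785)
    assert sep.s_af / rec785.s_f0 == pytest.approx(0.16, rel=1e-12)


def test_noisy_af_reference_ratio_near_measured_value():
    records, _ = make_skin_series(noise=NoiseModel(seed=7))
    rec785 = next(r for r in records if r.wavelength == 785.0)
    sep = separate_background(rec785)
    assert sep.s_af / rec785.s_f0 == pytest.approx(0.16, rel=0.2)


def test_recovery_unbiased_over_seeds():
    """Across 100 noise realizations the mean recovered Saf at each
    wavelength is within 3 standard errors of the truth."""
    n_seeds = 100
    truth = SyntheticTruth.default()
    recovered = []
    for seed in range(n_seeds):
        records, _ = make_skin_series(truth, NoiseModel(seed=seed))
        sep = separate_table(skin_series_frame(records))
        recovered.append(sep["s_af"].to_numpy())
    recovered = np.array(recovered)
    mean = recovered.mean(axis=0)
    se = recovered.std(axis=0, ddof=1) / np.sqrt(n_seeds)
    assert np.all(np.abs(mean - np.array(truth.true_saf)) < 3.0 * se)


def test_recovery_coverage_of_propagated_errors():
    """~95% of noise realizations put the recovered Saf within +/-2 of its
    propagated standard deviation (binomial check, 200 seeds)."""
    n_seeds = 200
    truth = SyntheticTruth.default()
    hits = 0
    total = 0
    for seed in range(n_seeds):
        records, _ = make_skin_series(truth, NoiseModel(seed=seed))
        sep = separate_table(skin_series_frame(records))
        for s_af, s_err, t in zip(sep["s_af"], sep["s_af_stderr"], truth.true_saf):
            total += 1
            if abs(s_af - t) <= 2.0 * s_err:
                hits += 1
    coverage = hits / total
    # 3-sigma binomial band around 0.954 at n=1000
    assert 0.90 <= coverage <= 0.99, coverage


def test_poisson_noise_scales_with_roi_size():
    signal = 5000.0
    small = NoiseModel(floor_fraction=0.0, roi_pixels=100)
    large = NoiseModel(floor_fraction=0.0, roi_pixels=10_000)
    assert small.stderr(signal, 0.0) == pytest.approx(
        10.0 * large.stderr(signal, 0.0)
    )


def _scenario():
    return TissueScenario(medium=TISSUE_MEDIUM, fluorophore=ICG_TISSUE)


def test_concentration_series_noiseless_matches_closed_form(synthetic_grid_table):
    """The empirical SBR of the noiseless dilution ladder equals the
    closed-form model curve to floating point."""
    filters = FilterSet()
    scen = _scenario()
    concs = [6.5e-11, 6.5e-10, 6.5e-9, 6.5e-8]
    records, truth_table = make_concentration_series(
        concs, scen, filters, noise=NOISELESS, rf_rd_source=synthetic_grid_table
    )
    sens = nmin_curve(scen, filters, od_values=[filters.od_ex],
                      rf_rd_source=synthetic_grid_table)
    n0 = scen.fluorophore.concentration
    for rec, (_, row) in zip(records, truth_table.iterrows()):
        empirical_sbr = rec.s_total / rec.s_bg - 1.0
        model = (sens.saf_over_sf + sens.ssc_over_sf) * n0 / row["n"]
        assert empirical_sbr == pytest.approx(1.0 / model, rel=1e-9)


def test_concentration_zero_gives_pure_background(synthetic_grid_table):
    records, _ = make_concentration_series(
        [0.0], _scenario(), FilterSet(), noise=NOISELESS,
        rf_rd_source=synthetic_grid_table,
    )
    assert records[0].s_total == pytest.approx(records[0].s_bg, rel=1e-12)


def test_concentration_series_af_toggle_constant_factor(synthetic_grid_table):
    """Fitted SBR with AF disabled exceeds the with-AF curve by exactly
    1 + Saf/Ssc at every concentration."""
    filters = FilterSet()
    scen = _scenario()
    concs = [6.5e-11, 6.5e-10, 6.5e-8]
    with_af, _ = make_concentration_series(
        concs, scen, filters, noise=NOISELESS, rf_rd_source=synthetic_grid_table
    )
    without_af, _ = make_concentration_series(
        concs, scen, filters, noise=NOISELESS, rf_rd_source=synthetic_grid_table,
        include_af=False,
    )
    sens = nmin_curve(scen, filters, od_values=[filters.od_ex],
                      rf_rd_source=synthetic_grid_table)
    expected = 1.0 + sens.saf_over_sf / sens.ssc_over_sf
    for rec_af, rec_no in zip(with_af, without_af):
        sbr_af = rec_af.s_total / rec_af.s_bg - 1.0
        sbr_no = rec_no.s_total / rec_no.s_bg - 1.0
        assert sbr_no / sbr_af == pytest.approx(expected, rel=1e-9)


def test_empty_concentration_list_rejected(synthetic_grid_table):
    with pytest.raises(ValueError, match="empty"):
        make_concentration_series([], _scenario(), FilterSet(),
                                  rf_rd_source=synthetic_grid_table)


def test_synthetic_images_match_scalar_fixture(tmp_path):
    from icglimit.background_separation import roi_mean_from_tiff
    from icglimit.synthetic_data import write_synthetic_images

    truth = SyntheticTruth.default()
    paths = write_synthetic_images(tmp_path, truth, NoiseModel(seed=3),
                                   shape=(120, 100), roi=(10, 110, 10, 90))
    i785 = truth.wavelengths.index(785.0)
    mean_bg, stderr_bg, n = roi_mean_from_tiff(paths["background"], (10, 110, 10, 90))
    expected_bg = truth.true_saf[i785] + truth.true_ssc[i785]
    assert n == 100 * 80
    assert mean_bg == pytest.approx(expected_bg, rel=0.01)
    mean_tot, _, _ = roi_mean_from_tiff(paths["total"], (10, 110, 10, 90))
    assert mean_tot == pytest.approx(expected_bg + truth.s_f0, rel=0.01)
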