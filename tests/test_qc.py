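"""Quality-control metrics: SNR ladder, spike detection, cosine coherence, drift."""

import numpy as np
import pytest

from ftirfp import (
    Group,
    QCConfig,
    SyntheticConfig,
    Spectrum,
    baseline_area_fraction,
    cosine_fp,
    gaussian_band,
    generate_cohort,
    qc_group_compare,
    qc_table,
    snr_amide_i,
    spike_count,
)
from ftirfp.qc import GroupingError, QCRecord, UndefinedSNRError
from ftirfp.spectra import Window

from conftest import make_set

STD_GRID = 400.0 + 2.0 * np.arange(1801)


def flat_spectrum_with_band(noise_sd=0.0, seed=0, amp=1.0, center=1650.0, fwhm=30.0):
    rng = np.random.default_rng(seed)
    y = gaussian_band(STD_GRID, center, fwhm, amp)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, STD_GRID.size)
    return Spectrum(STD_GRID, y, donor_id="T")


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def test_snr_seeded_ground_truth():
    s = flat_spectrum_with_band(noise_sd=0.01, seed=7)
    snr, source = snr_amide_i(s)
    assert source == "offband_primary"
    assert snr == pytest.approx(100.0, rel=0.15)


def test_snr_scale_invariance():
    s = flat_spectrum_with_band(noise_sd=0.01, seed=3)
    doubled = Spectrum(s.wavenumbers, 2.0 * s.absorbance, donor_id="T")
    assert snr_amide_i(s)[0] == pytest.approx(snr_amide_i(doubled)[0], rel=1e-9)


def test_snr_fallback_ladder_by_offband_point_count():
    """Noise source steps down as the off-band windows fall short of points."""
    rng = np.random.default_rng(5)

    def spectrum(step):
        grid = np.arange(1500.0, 2300.0 + step, step)
        y = gaussian_band(grid, 1650.0, 30.0, 1.0) + rng.normal(0, 0.01, grid.size)
        return Spectrum(grid, y, donor_id="T")

    # 2 cm-1: primary window holds 51 points
    assert snr_amide_i(spectrum(2.0))[1] == "offband_primary"
    # 12 cm-1: primary has 9 (<10) points but the wider fallback has 17
    assert snr_amide_i(spectrum(12.0))[1] == "offband_fallback"
    # 25 cm-1: primary 5, fallback 9 -> global SD as the last resort
    assert snr_amide_i(spectrum(25.0))[1] == "global_sd"


def test_snr_zero_noise_is_an_error():
    s = flat_spectrum_with_band(noise_sd=0.0)
    with pytest.raises(UndefinedSNRError):
        snr_amide_i(s)


# ---------------------------------------------------------------------------
# Spike detection
# ---------------------------------------------------------------------------

def test_spike_count_smooth_band_is_zero():
    s = flat_spectrum_with_band(amp=1.0, center=1350.0, fwhm=400.0)
    assert spike_count(s) == 0


def test_spike_count_constant_spectrum_convention():
    s = Spectrum(STD_GRID, np.full(STD_GRID.size, 0.3), donor_id="T")
    assert spike_count(s) == 0


def test_spike_count_recovers_injected_spikes():
    rng = np.random.default_rng(11)
    noise = 0.001
    y = rng.normal(0.0, noise, STD_GRID.size) + 0.5
    positions = [np.argmin(np.abs(STD_GRID - w)) for w in (1100.0, 1400.0, 1700.0)]
    for p in positions:
        y[p] += 100 * noise
    s = Spectrum(STD_GRID, y, donor_id="T")
    assert spike_count(s, QCConfig(spike_merge_runs=True)) == 3
    # point counting equals a brute-force recount of |z| > 6
    mask = (STD_GRID >= 900) & (STD_GRID <= 1800)
    d = np.diff(y[mask])
    z = (d - np.median(d)) / (1.4826 * np.median(np.abs(d - np.median(d))))
    assert spike_count(s) == int(np.sum(np.abs(z) > 6))


def test_spike_count_scale_invariance():
    rng = np.random.default_rng(2)
    y = rng.normal(0.0, 0.01, STD_GRID.size)
    y[600] += 1.0
    s = Spectrum(STD_GRID, y, donor_id="T")
    scaled = Spectrum(STD_GRID, 7.0 * y, donor_id="T")
    assert spike_count(s) == spike_count(scaled)


def test_spike_recovery_on_synthetic_cohort():
    """Run-counted spikes match the injected truth for >=95% of 100 spectra."""
    cfg = SyntheticConfig(
        bands=[],
        baseline_poly_coeffs_sd=(0.001,),
        baseline_offset=0.2,
        noise_sd=0.001,
        spike_amplitude=0.05,  # 50x the noise SD
        spike_rate=2.0,
        pathlength_cv=0.0,
        n_dcd=17,
        n_dbd=17,
        replicates_per_donor=3,
        seed=13,
    )
    spectra, truth = generate_cohort(cfg)
    grid = cfg.grid()
    fp_mask = (grid >= 900.0) & (grid <= 1800.0)
    qc = QCConfig(spike_merge_runs=True)
    hits = 0
    total = min(100, spectra.n_spectra)
    for i in range(total):
        m = spectra.meta.iloc[i]
        injected = sum(
            1
            for pos, _ in truth.donor(m["donor_id"]).spikes[m["replicate_id"]]
            if fp_mask[pos]
        )
        hits += spike_count(spectra.row(i), qc) == injected
    assert hits >= 0.95 * total


# ---------------------------------------------------------------------------
# Cosine coherence
# ---------------------------------------------------------------------------

def test_cosine_identical_donors_and_scale_invariance():
    band = gaussian_band(STD_GRID, 1300.0, 120.0, 1.0) + 0.1
    s = make_set(STD_GRID, [band, band, 5.0 * band], donors=["A", "B", "C"])
    vals = cosine_fp(s)
    assert np.allclose(vals, 1.0, atol=1e-12)


def test_cosine_orthogonal_donor_is_zero():
    # even number of window points so an alternating sign flip is orthogonal
    config = QCConfig(fingerprint=Window(900.0, 1798.0, "fingerprint"))
    mask = config.fingerprint.mask(STD_GRID)
    v = np.full(STD_GRID.size, 1.0)
    w = v.copy()
    signs = np.ones(mask.sum())
    signs[1::2] = -1.0
    w[mask] = signs
    s = make_set(STD_GRID, [v, v, w], donors=["A", "B", "C"])
    vals = cosine_fp(s, config)
    # median of {v, v, w} equals v pointwise; w is constructed orthogonal to v
    assert vals[2] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Baseline area fraction
# ---------------------------------------------------------------------------

def test_baseline_fraction_linear_ramp_is_100_percent():
    y = 0.001 * (STD_GRID - 300.0)
    s = Spectrum(STD_GRID, y, donor_id="T")
    assert baseline_area_fraction(s) == pytest.approx(100.0, abs=1e-9)


def test_baseline_fraction_pure_peak_near_zero():
    s = flat_spectrum_with_band(amp=1.0, center=1350.0, fwhm=60.0)
    assert baseline_area_fraction(s) == pytest.approx(0.0, abs=1e-6)


def test_baseline_fraction_peak_on_offset_closed_form():
    c = 0.05
    peak = gaussian_band(STD_GRID, 1350.0, 60.0, 1.0)
    s = Spectrum(STD_GRID, peak + c, donor_id="T")
    mask = (STD_GRID >= 900) & (STD_GRID <= 1800)
    x = STD_GRID[mask]
    L = x[-1] - x[0]
    A = np.trapezoid(peak[mask], x)
    expected = 100.0 * c * L / (c * L + A)
    assert baseline_area_fraction(s) == pytest.approx(expected, rel=1e-9)


def test_baseline_fraction_nonpositive_area_rejected():
    s = Spectrum(STD_GRID, np.full(STD_GRID.size, -1.0), donor_id="T")
    with pytest.raises(ValueError, match="raw spectral area"):
        baseline_area_fraction(s)


# ---------------------------------------------------------------------------
# QC table and group comparison
# ---------------------------------------------------------------------------

def test_qc_table_counts_order_and_componentwise_oracle(donor_set):
    records = qc_table(donor_set)
    assert len(records) == 10
    assert [r.donor_id for r in records] == sorted(r.donor_id for r in records)
    # row-order invariance
    perm = np.random.default_rng(0).permutation(donor_set.n_spectra)
    records_perm = qc_table(donor_set.subset(perm))
    for a, b in zip(records, records_perm):
        assert a == b
    # spike counts equal direct per-donor computation
    for r in records:
        i = donor_set.meta.index[donor_set.meta["donor_id"] == r.donor_id][0]
        assert r.spike_count == spike_count(donor_set.row(i))


def _records_from_columns(snr, spikes, cosine, group):
    return [
        QCRecord(
            donor_id=f"{group.value}{i}",
            group=group,
            snr_amide_i=s,
            spike_count=k,
            cosine_fp=c,
            baseline_area_fraction=0.0,
            snr_noise_source="offband_primary",
        )
        for i, (s, k, c) in enumerate(zip(snr, spikes, cosine))
    ]


TABLE_RECORDS = _records_from_columns(
    [204.725, 67.697, 58.219, 77.158, 80.408],
    [57, 12, 6, 4, 53],
    [0.859, 0.998, 1.0, 0.994, 0.987],
    Group.DCD,
) + _records_from_columns(
    [81.152, 4.364, 20.737, 67.108, 85.07],
    [34, 12, 36, 6, 8],
    [0.992, 0.942, 0.953, 0.998, 0.998],
    Group.DBD,
)


def test_group_compare_reproduces_published_qc_statistics():
    stats = qc_group_compare(TABLE_RECORDS)
    snr = stats["snr_amide_i"]
    assert snr.u == 16.0
    assert snr.p_two_sided == pytest.approx(0.5476, abs=1e-4)
    assert snr.r_rank_biserial == pytest.approx(-0.28)
    assert snr.dcd_mean == pytest.approx(97.64, abs=0.005)
    assert snr.dcd_sd == pytest.approx(60.49, abs=0.005)
    assert snr.dcd_median == pytest.approx(77.16, abs=0.005)
    assert snr.dcd_iqr[0] == pytest.approx(67.70, abs=0.005)
    assert snr.dcd_iqr[1] == pytest.approx(80.41, abs=0.005)
    spikes = stats["spike_count"]
    assert spikes.u == 13.0
    assert spikes.r_rank_biserial == pytest.approx(-0.04)
    assert spikes.p_two_sided >= 0.95


def test_group_compare_identical_groups_gives_null_center():
    recs = _records_from_columns([1.0, 2.0], [3, 4], [0.9, 0.8], Group.DCD)
    recs += _records_from_columns([1.0, 2.0], [3, 4], [0.9, 0.8], Group.DBD)
    stats = qc_group_compare(recs)
    assert stats["snr_amide_i"].u == 2.0  # n1*n2/2
    assert stats["snr_amide_i"].r_rank_biserial == 0.0


def test_group_compare_label_exchange_flips_r_preserves_p():
    swapped = [
        QCRecord(
            r.donor_id,
            Group.DBD if r.group is Group.DCD else Group.DCD,
            r.snr_amide_i,
            r.spike_count,
            r.cosine_fp,
            r.baseline_area_fraction,
            r.snr_noise_source,
        )
        for r in TABLE_RECORDS
    ]
    orig = qc_group_compare(TABLE_RECORDS)
    flip = qc_group_compare(swapped)
    for metric in orig:
        assert flip[metric].r_rank_biserial == pytest.approx(
            -orig[metric].r_rank_biserial, abs=1e-12
        )
        assert flip[metric].p_two_sided == pytest.approx(
            orig[metric].p_two_sided, abs=1e-12
        )


def test_group_compare_requires_both_groups():
    with pytest.raises(GroupingError):
        qc_group_compare(TABLE_RECORDS[:5])


def test_all_qc_metrics_scale_invariant_on_cohort(donor_set):
    scaled = make_set(
        donor_set.grid,
        3.7 * donor_set.matrix,
        donors=donor_set.meta["donor_id"].tolist(),
        groups=[g.value for g in donor_set.meta["group"]],
        replicates=donor_set.meta["replicate_id"].tolist(),
    )
    for a, b in zip(qc_table(donor_set), qc_table(scaled)):
        assert b.snr_amide_i == pytest.approx(a.snr_amide_i, rel=1e-9)
        assert b.spike_count == a.spike_count
        assert b.cosine_fp == pytest.approx(a.cosine_fp, abs=1e-9)
        assert b.baseline_area_fraction == pytest.approx(
            a.baseline_area_fraction, rel=1e-9
        )
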