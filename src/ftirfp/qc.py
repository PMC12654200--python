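"""Spectral quality control on donor-level spectra.

Four complementary metrics, each computed on donor-level mean spectra:

1. **Amide I SNR** — maximum rubber-band-corrected peak height in
   1600–1700 cm⁻¹ divided by the sample SD of the corrected absorbance in an
   off-band window (1800–1900 cm⁻¹, falling back to 2000–2200 cm⁻¹ and
   finally to the global SD when too few off-band points exist).
2. **Spike count** — points in the fingerprint first-difference whose robust
   z-score (median / 1.4826·MAD) exceeds 6 in magnitude; optionally maximal
   runs of consecutive flagged points instead of raw points.
3. **Cosine similarity to the cohort median** — shape coherence of each
   vector-normalized fingerprint spectrum against the vector-normalized
   pointwise median.
4. **Baseline area fraction** — area under the rubber-band baseline over the
   fingerprint window as a percentage of the raw spectral area (drift index).

All four are invariant to uniform rescaling of the spectrum, so pathlength
differences cannot masquerade as quality differences. The DCD-vs-DBD group
comparison uses exact Mann–Whitney tests with rank-biserial effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import rubberband_baseline
from .spectra import (
    AMIDE_I,
    FINGERPRINT,
    OFFBAND_FALLBACK,
    OFFBAND_PRIMARY,
    Group,
    SpectraSet,
    Spectrum,
    Window,
)
from .stats import mwu_exact

__all__ = [
    "QCConfig",
    "QCRecord",
    "QCGroupStats",
    "snr_amide_i",
    "spike_count",
    "cosine_fp",
    "baseline_area_fraction",
    "qc_table",
    "qc_group_compare",
    "UndefinedSNRError",
    "GroupingError",
]

MAD_SCALE = 1.4826  # makes the MAD a consistent estimator of the SD


class UndefinedSNRError(ValueError):
    """Noise estimate is exactly zero (degenerate, typically synthetic, input)."""


class GroupingError(ValueError):
    """A required donor group is empty or missing."""


@dataclass(frozen=True)
class QCConfig:
    amide_window: Window = AMIDE_I
    offband_primary: Window = OFFBAND_PRIMARY
    offband_fallback: Window = OFFBAND_FALLBACK
    fingerprint: Window = FINGERPRINT
    spike_z_threshold: float = 6.0
    min_offband_points: int = 10
    spike_merge_runs: bool = False

    def __post_init__(self) -> None:
        if self.spike_z_threshold <= 0:
            raise ValueError("spike_z_threshold must be > 0")
        if self.min_offband_points < 2:
            raise ValueError("min_offband_points must be >= 2")


@dataclass(frozen=True)
class QCRecord:
    """Per-donor QC metrics."""

    donor_id: str
    group: Group
    snr_amide_i: float
    spike_count: int
    cosine_fp: float
    baseline_area_fraction: float  # percent
    snr_noise_source: str


@dataclass(frozen=True)
class QCGroupStats:
    """DCD-vs-DBD comparison of one QC metric (DCD is the first sample)."""

    metric: str
    dcd_median: float
    dcd_iqr: tuple[float, float]
    dbd_median: float
    dbd_iqr: tuple[float, float]
    dcd_mean: float
    dcd_sd: float
    dbd_mean: float
    dbd_sd: float
    u: float
    p_two_sided: float
    r_rank_biserial: float


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1))


def snr_amide_i(spectrum: Spectrum, config: QCConfig = QCConfig()) -> tuple[float, str]:
    """Amide I SNR and the noise window actually used.

    The rubber-band correction is computed on the full available spectrum
    (the hull must span both the Amide I band and the off-band windows).
    Noise source ladder: primary off-band window → fallback window → global
    SD, stepping down whenever a window holds fewer than
    ``min_offband_points`` grid points.
    """
    wn = spectrum.wavenumbers
    if not np.any(config.amide_window.mask(wn)):
        raise ValueError("spectrum does not cover the Amide I window")
    corrected = spectrum.absorbance - rubberband_baseline(wn, spectrum.absorbance)
    signal = float(corrected[config.amide_window.mask(wn)].max())
    for window, source in (
        (config.offband_primary, "offband_primary"),
        (config.offband_fallback, "offband_fallback"),
    ):
        sel = corrected[window.mask(wn)]
        if sel.size >= config.min_offband_points:
            noise = _sample_sd(sel)
            break
    else:
        noise = _sample_sd(corrected)
        source = "global_sd"
    if noise == 0.0:
        raise UndefinedSNRError(
            "off-band noise estimate is exactly zero; SNR undefined "
            "(degenerate or noise-free synthetic input)"
        )
    return signal / noise, source


def spike_count(spectrum: Spectrum, config: QCConfig = QCConfig()) -> int:
    """Spike artifacts in the fingerprint window via a robust z on first differences.

    z = (d − median(d)) / (1.4826 · MAD(d)); points with |z| > threshold are
    flagged. MAD = 0 (perfectly smooth/constant input) returns 0 by
    convention. With ``spike_merge_runs`` the count is the number of maximal
    runs of consecutive flagged points (one narrow spike perturbs two
    successive differences, so run counting approximates the event count).
    """
    wn = spectrum.wavenumbers
    mask = config.fingerprint.mask(wn)
    if not np.any(mask):
        raise ValueError("spectrum does not cover the fingerprint window")
    d = np.diff(spectrum.absorbance[mask])
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0.0:
        return 0
    z = (d - med) / (MAD_SCALE * mad)
    flags = np.abs(z) > config.spike_z_threshold
    if not config.spike_merge_runs:
        return int(flags.sum())
    # count maximal runs of consecutive True
    return int(np.sum(np.diff(np.concatenate(([0], flags.astype(int)))) == 1))


def cosine_fp(spectra_set: SpectraSet, config: QCConfig = QCConfig()) -> np.ndarray:
    """Cosine similarity of each row to the cohort median, fingerprint window.

    The pointwise median across donors and every donor row are scaled to
    unit Euclidean norm before the dot product.
    """
    if spectra_set.n_spectra < 2:
        raise ValueError("cosine similarity needs at least 2 donors")
    mask = config.fingerprint.mask(spectra_set.grid)
    if not np.any(mask):
        raise ValueError("set does not cover the fingerprint window")
    fp = spectra_set.matrix[:, mask]
    median = np.median(fp, axis=0)
    mnorm = np.linalg.norm(median)
    rnorms = np.linalg.norm(fp, axis=1)
    if mnorm == 0 or np.any(rnorms == 0):
        raise ValueError("zero-norm fingerprint window; cosine undefined")
    return (fp / rnorms[:, None]) @ (median / mnorm)


def baseline_area_fraction(spectrum: Spectrum, config: QCConfig = QCConfig()) -> float:
    """Rubber-band baseline area as % of the raw area, fingerprint window."""
    wn = spectrum.wavenumbers
    mask = config.fingerprint.mask(wn)
    if not np.any(mask):
        raise ValueError("spectrum does not cover the fingerprint window")
    x = wn[mask]
    y = spectrum.absorbance[mask]
    raw_area = float(np.trapezoid(y, x))
    if raw_area <= 0:
        raise ValueError(f"nonpositive raw spectral area ({raw_area}); fraction undefined")
    base_area = float(np.trapezoid(rubberband_baseline(x, y), x))
    return 100.0 * base_area / raw_area


def qc_table(spectra_set: SpectraSet, config: QCConfig = QCConfig()) -> list[QCRecord]:
    """All four QC metrics per donor, ordered by donor_id.

    Expects a donor-level (post-aggregation) set; errors from individual
    metrics are re-raised annotated with the donor id.
    """
    order = np.argsort(spectra_set.meta["donor_id"].to_numpy())
    ordered = spectra_set.subset(order)
    cosines = cosine_fp(ordered, config)
    records = []
    for i in range(ordered.n_spectra):
        s = ordered.row(i)
        try:
            snr, source = snr_amide_i(s, config)
            records.append(
                QCRecord(
                    donor_id=s.donor_id,
                    group=s.group,
                    snr_amide_i=snr,
                    spike_count=spike_count(s, config),
                    cosine_fp=float(cosines[i]),
                    baseline_area_fraction=baseline_area_fraction(s, config),
                    snr_noise_source=source,
                )
            )
        except ValueError as exc:
            raise type(exc)(f"donor {s.donor_id!r}: {exc}") from exc
    return records


_METRICS = ("snr_amide_i", "spike_count", "cosine_fp", "baseline_area_fraction")


def qc_group_compare(records: list[QCRecord]) -> dict[str, QCGroupStats]:
    """Exact DCD-vs-DBD comparison of every QC metric.

    Per metric: median [IQR] and mean ± SD per group, Mann–Whitney U with
    DCD as the first sample (0.5 per tied pair), exact two-sided p by
    enumeration, and rank-biserial r = 1 − 2U/(n₁n₂).
    """
    dcd = [r for r in records if r.group is Group.DCD]
    dbd = [r for r in records if r.group is Group.DBD]
    if not dcd or not dbd:
        raise GroupingError(
            f"both groups required: {len(dcd)} DCD and {len(dbd)} DBD records"
        )
    out = {}
    for metric in _METRICS:
        a = np.array([getattr(r, metric) for r in dcd], dtype=float)
        b = np.array([getattr(r, metric) for r in dbd], dtype=float)
        res = mwu_exact(a, b)
        out[metric] = QCGroupStats(
            metric=metric,
            dcd_median=float(np.median(a)),
            dcd_iqr=(float(np.percentile(a, 25)), float(np.percentile(a, 75))),
            dbd_median=float(np.median(b)),
            dbd_iqr=(float(np.percentile(b, 25)), float(np.percentile(b, 75))),
            dcd_mean=float(a.mean()),
            dcd_sd=_sample_sd(a),
            dbd_mean=float(b.mean()),
            dbd_sd=_sample_sd(b),
            u=res.u,
            p_two_sided=res.p_two_sided,
            r_rank_biserial=res.r_rank_biserial,
        )
    return out


def qc_records_frame(records: list[QCRecord]) -> pd.DataFrame:
    """QC records as a tidy DataFrame (CSV-ready, one row per donor)."""
    return pd.DataFrame(
        {
            "donor_id": [r.donor_id for r in records],
            "group": [r.group.value for r in records],
            "snr_amide_i": [r.snr_amide_i for r in records],
            "spike_count": [r.spike_count for r in records],
            "cosine_fp": [r.cosine_fp for r in records],
            "baseline_area_fraction": [r.baseline_area_fraction for r in records],
            "snr_noise_source": [r.snr_noise_source for r in records],
        }
    )


def qc_group_frame(stats: dict[str, QCGroupStats]) -> pd.DataFrame:
    """Group-comparison stats as a tidy DataFrame (one row per metric)."""
    rows = []
    for s in stats.values():
        rows.append(
            {
                "metric": s.metric,
                "dcd_median": s.dcd_median,
                "dcd_q1": s.dcd_iqr[0],
                "dcd_q3": s.dcd_iqr[1],
                "dbd_median": s.dbd_median,
                "dbd_q1": s.dbd_iqr[0],
                "dbd_q3": s.dbd_iqr[1],
                "dcd_mean": s.dcd_mean,
                "dcd_sd": s.dcd_sd,
                "dbd_mean": s.dbd_mean,
                "dbd_sd": s.dbd_sd,
                "u": s.u,
                "p_two_sided": s.p_two_sided,
                "r_rank_biserial": s.r_rank_biserial,
            }
        )
    return pd.DataFrame(rows)
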