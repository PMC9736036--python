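"""Spectral preprocessing: background subtraction, lock-mass drift
correction, quality filtering, 0.1 Da binning over 600–1000 m/z, TIC
normalisation and per-sample representative averaging.

The chain turns a bag of raw burn spectra into exactly one quality-
controlled feature vector per sample (4000 bins at the defaults), the input
to the multivariate and univariate analyses. Drift correction uses the
phosphatidic-acid internal lock mass at 699.497 Th (plus the leucine-
enkephalin external lock mass at 554.262 Th when the spectrum covers it, in
which case a two-point linear recalibration replaces the rigid shift).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .lipid_annotation import EXTERNAL_LOCKMASS_MZ, INTERNAL_LOCKMASS_MZ
from .spectra_io import Manifest, RawSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "BinnedSpectrum",
    "QCReport",
    "FeatureMatrix",
    "subtract_background",
    "estimate_and_correct_lockmass",
    "quality_filter",
    "bin_spectrum",
    "tic_normalize",
    "sample_representative",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing constants.

    Defaults follow standard REIMS lipid-profiling practice: processing
    restricted to 600–1000 m/z, 0.1 Da bins (4000 features), lock masses at
    554.262 (external) and 699.497 (internal) Th, and a noise-to-signal
    quality cutoff of 5 on the p95/median intensity ratio.
    """

    external_lockmass: float = EXTERNAL_LOCKMASS_MZ  # 554.262 at 3 dp
    internal_lockmass: float = INTERNAL_LOCKMASS_MZ  # 699.497 at 3 dp
    lockmass_window: float = 0.5
    bin_lo: float = 600.0
    bin_hi: float = 1000.0
    bin_width: float = 0.1
    snr_min: float = 5.0
    min_tic: float = 1e-6
    background_quantile: float = 0.10

    def __post_init__(self) -> None:
        if not (self.bin_lo < self.bin_hi and self.bin_width > 0):
            raise ValueError("require bin_lo < bin_hi and bin_width > 0")
        n = (self.bin_hi - self.bin_lo) / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(bin_hi - bin_lo) / bin_width must be an integer")

    @property
    def n_bins(self) -> int:
        return int(round((self.bin_hi - self.bin_lo) / self.bin_width))

    def bin_edges(self) -> np.ndarray:
        """Lower edge of each half-open bin [edge, edge + bin_width)."""
        return self.bin_lo + self.bin_width * np.arange(self.n_bins)


@dataclass
class BinnedSpectrum:
    values: np.ndarray
    bin_lo: float = 600.0
    bin_width: float = 0.1
    normalised: bool = False
    spectrum_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("binned values must be a 1-D vector")
        if self.values.size and float(self.values.min()) < -1e-12:
            raise ValueError("binned values must be non-negative")


@dataclass(frozen=True)
class QCReport:
    spectrum_id: str
    tic: float
    snr_estimate: float
    passed: bool
    reason: str = ""


def subtract_background(s: RawSpectrum, quantile: float = 0.10) -> RawSpectrum:
    """Subtract a constant background level (an intensity quantile), clip at 0."""
    if len(s) == 0:
        return s
    level = float(np.quantile(s.intensity, quantile))
    out = np.maximum(s.intensity - level, 0.0)
    return replace(s, mz=s.mz.copy(), intensity=out)


def _refine_apex(mz: np.ndarray, intensity: np.ndarray, i: int) -> float:
    """Sub-grid apex via a quadratic fit to log-intensity at i−1, i, i+1.

    Exact for a sampled Gaussian; falls back to the grid position when the
    neighbours are missing or non-positive.
    """
    if i <= 0 or i >= len(mz) - 1:
        return float(mz[i])
    y = intensity[i - 1 : i + 2]
    if np.any(y <= 0):
        return float(mz[i])
    x = mz[i - 1 : i + 2]
    a, b, _ = np.polyfit(x - x[1], np.log(y), 2)
    if a >= 0:  # not a local maximum in log space
        return float(mz[i])
    return float(x[1] - b / (2 * a))


def _locate_peak(s: RawSpectrum, reference: float, window: float) -> float | None:
    mask = np.abs(s.mz - reference) <= window
    if not np.any(mask):
        return None
    idx = np.flatnonzero(mask)
    local = idx[int(np.argmax(s.intensity[idx]))]
    if s.intensity[local] <= 0:
        return None
    return _refine_apex(s.mz, s.intensity, int(local))


def estimate_and_correct_lockmass(
    s: RawSpectrum, cfg: PreprocessConfig | None = None
) -> tuple[RawSpectrum, float | None]:
    """Estimate mass drift from the lock-mass peak(s) and undo it.

    The most intense point within ±``lockmass_window`` of the internal lock
    mass gives ``drift = observed − 699.497``; the spectrum is rigidly
    shifted by −drift. When the external lock-mass region is also inside the
    spectrum's m/z range, both references are used to fit a linear
    (slope, offset) recalibration instead. If no usable peak is found the
    spectrum is returned unchanged with drift ``None`` (flagged).
    """
    cfg = cfg or PreprocessConfig()
    if len(s) == 0:
        return s, None
    internal_obs = _locate_peak(s, cfg.internal_lockmass, cfg.lockmass_window)
    if internal_obs is None:
        logger.warning("lock-mass correction skipped for %s: no peak near %.3f",
                       s.spectrum_id or "<spectrum>", cfg.internal_lockmass)
        return s, None
    drift = internal_obs - cfg.internal_lockmass

    external_in_range = (
        s.mz[0] <= cfg.external_lockmass - cfg.lockmass_window
        and s.mz[-1] >= cfg.external_lockmass + cfg.lockmass_window
    )
    if external_in_range:
        external_obs = _locate_peak(s, cfg.external_lockmass, cfg.lockmass_window)
        if external_obs is not None and not np.isclose(external_obs, internal_obs):
            slope = (cfg.internal_lockmass - cfg.external_lockmass) / (internal_obs - external_obs)
            offset = cfg.internal_lockmass - slope * internal_obs
            corrected = replace(s, mz=slope * s.mz + offset, intensity=s.intensity.copy())
            return corrected, float(drift)
    corrected = replace(s, mz=s.mz - drift, intensity=s.intensity.copy())
    return corrected, float(drift)


def spectrum_qc(s: RawSpectrum, cfg: PreprocessConfig | None = None) -> QCReport:
    """Noise-to-signal QC: p95/median intensity ratio plus a TIC floor."""
    cfg = cfg or PreprocessConfig()
    if len(s) == 0:
        return QCReport(s.spectrum_id, 0.0, 0.0, False, "empty spectrum")
    tic = float(s.intensity.sum())
    p95 = float(np.percentile(s.intensity, 95))
    med = float(np.median(s.intensity))
    snr = p95 / (med + 1e-12)
    passed = tic >= cfg.min_tic and snr >= cfg.snr_min
    reason = ""
    if tic < cfg.min_tic:
        reason = f"tic {tic:.3g} below {cfg.min_tic:.3g}"
    elif snr < cfg.snr_min:
        reason = f"signal-to-noise {snr:.2f} below {cfg.snr_min:.2f}"
    return QCReport(s.spectrum_id, tic, snr, passed, reason)


def quality_filter(
    spectra: Sequence[RawSpectrum], cfg: PreprocessConfig | None = None
) -> tuple[list[RawSpectrum], list[RawSpectrum], list[QCReport]]:
    """Partition spectra into (kept, excluded) by the QC rule."""
    cfg = cfg or PreprocessConfig()
    kept: list[RawSpectrum] = []
    excluded: list[RawSpectrum] = []
    reports: list[QCReport] = []
    for s in spectra:
        report = spectrum_qc(s, cfg)
        reports.append(report)
        (kept if report.passed else excluded).append(s)
    return kept, excluded, reports


def bin_spectrum(s: RawSpectrum, cfg: PreprocessConfig | None = None) -> BinnedSpectrum:
    """Sum intensities into half-open 0.1 Da bins over [600, 1000).

    Points outside the range are dropped; total in-range intensity is
    conserved exactly (up to float addition order).
    """
    cfg = cfg or PreprocessConfig()
    values = np.zeros(cfg.n_bins)
    if len(s):
        mask = (s.mz >= cfg.bin_lo) & (s.mz < cfg.bin_hi)
        if np.any(mask):
            # small epsilon guards against 600.1 landing in bin 0 through
            # float round-off in the division
            idx = np.floor((s.mz[mask] - cfg.bin_lo) / cfg.bin_width + 1e-9).astype(int)
            np.clip(idx, 0, cfg.n_bins - 1, out=idx)
            values = np.bincount(idx, weights=s.intensity[mask], minlength=cfg.n_bins).astype(float)
    return BinnedSpectrum(values, cfg.bin_lo, cfg.bin_width,
                          spectrum_id=s.spectrum_id, sample_id=s.sample_id)


def tic_normalize(b: BinnedSpectrum) -> BinnedSpectrum:
    """Scale to unit total ion count; all-zero vectors pass through flagged."""
    total = float(b.values.sum())
    if total <= 0:
        return BinnedSpectrum(b.values.copy(), b.bin_lo, b.bin_width, normalised=False,
                              spectrum_id=b.spectrum_id, sample_id=b.sample_id)
    return BinnedSpectrum(b.values / total, b.bin_lo, b.bin_width, normalised=True,
                          spectrum_id=b.spectrum_id, sample_id=b.sample_id)


def sample_representative(binned: Sequence[BinnedSpectrum]) -> BinnedSpectrum:
    """Element-wise mean of a sample's normalised burn spectra, re-normalised."""
    if not binned:
        raise ValueError("cannot build a representative from zero spectra")
    first = binned[0]
    for b in binned:
        if b.values.shape != first.values.shape or b.bin_lo != first.bin_lo:
            raise ValueError("all binned spectra must share one grid")
        if not b.normalised:
            raise ValueError("representative averaging expects normalised spectra")
    mean = np.mean([b.values for b in binned], axis=0)
    out = BinnedSpectrum(mean, first.bin_lo, first.bin_width,
                         sample_id=first.sample_id)
    return tic_normalize(out)


@dataclass
class FeatureMatrix:
    """Per-sample representative spectra: samples × bins, patient-aware."""

    sample_ids: list[str]
    patient_ids: list[str]
    labels: list[str]  # histology values, e.g. "normal"/"cancer"
    X: np.ndarray
    bin_lo: float = 600.0
    bin_width: float = 0.1

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = len(self.sample_ids)
        if not (len(self.patient_ids) == len(self.labels) == n == self.X.shape[0]):
            raise ValueError("sample_ids, patient_ids, labels and X rows must align")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.X.shape[1]

    def bin_edges(self) -> np.ndarray:
        return self.bin_lo + self.bin_width * np.arange(self.n_bins)

    def bin_labels(self) -> list[str]:
        return [f"mz_{edge:.1f}" for edge in self.bin_edges()]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return FeatureMatrix(
            [self.sample_ids[i] for i in idx],
            [self.patient_ids[i] for i in idx],
            [self.labels[i] for i in idx],
            self.X[idx],
            self.bin_lo, self.bin_width,
        )

    def binary(self) -> "FeatureMatrix":
        """Rows restricted to the modelled classes (normal vs cancer)."""
        keep = np.array([lab in ("normal", "cancer") for lab in self.labels])
        return self.subset(keep)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.bin_labels())
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "patient_id", self.patient_ids)
        df.insert(2, "histology", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path)
        mz_cols = [c for c in df.columns if c.startswith("mz_")]
        edges = np.array([float(c[3:]) for c in mz_cols])
        width = float(np.round(np.median(np.diff(edges)), 6)) if len(edges) > 1 else 0.1
        return cls(
            df["sample_id"].astype(str).tolist(),
            df["patient_id"].astype(str).tolist(),
            df["histology"].astype(str).tolist(),
            df[mz_cols].to_numpy(dtype=float),
            float(edges[0]) if len(edges) else 600.0,
            width,
        )


def preprocess_cohort(
    spectra: Sequence[RawSpectrum],
    manifest: Manifest,
    cfg: PreprocessConfig | None = None,
) -> tuple[FeatureMatrix, list[QCReport], dict[str, float | None]]:
    """Full chain: subtract → lock-mass correct → QC → bin → normalise →
    one representative row per sample.

    Returns the feature matrix (samples with ≥1 passing spectrum, all
    histologies retained), the per-spectrum QC reports, and the estimated
    drift per spectrum id (``None`` where correction was skipped).

    Samples losing every burn to QC are dropped with a log line, mirroring
    how fluid-dominated biopsy samples fall out of a REIMS analysis.
    """
    cfg = cfg or PreprocessConfig()
    drifts: dict[str, float | None] = {}
    corrected: list[RawSpectrum] = []
    for s in spectra:
        if s.sample_id not in manifest:
            raise ValueError(f"spectrum {s.spectrum_id!r}: sample {s.sample_id!r} not in manifest")
        sub = subtract_background(s, cfg.background_quantile)
        fixed, drift = estimate_and_correct_lockmass(sub, cfg)
        drifts[s.spectrum_id] = drift
        corrected.append(fixed)
    kept, excluded, reports = quality_filter(corrected, cfg)
    logger.info("quality filter: %d kept, %d excluded of %d spectra",
                len(kept), len(excluded), len(corrected))

    by_sample: dict[str, list[BinnedSpectrum]] = {}
    for s in kept:
        b = tic_normalize(bin_spectrum(s, cfg))
        if not b.normalised:
            continue  # all-zero after binning: treat as failed
        by_sample.setdefault(s.sample_id, []).append(b)

    sample_ids, patient_ids, labels, rows = [], [], [], []
    for record in manifest.records:
        group = by_sample.get(record.sample_id)
        if not group:
            logger.info("sample %s dropped: no spectra passed QC", record.sample_id)
            continue
        rep = sample_representative(group)
        sample_ids.append(record.sample_id)
        patient_ids.append(record.patient_id)
        labels.append(record.histology.value)
        rows.append(rep.values)
    X = np.vstack(rows) if rows else np.zeros((0, cfg.n_bins))
    return FeatureMatrix(sample_ids, patient_ids, labels, X, cfg.bin_lo, cfg.bin_width), reports, drifts
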