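"""Seeded synthetic REIMS cohorts for endometrial Pipelle classification.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage — lock-mass correction, binning, PC-LDA with
leave-one-patient-out validation, univariate discovery — is testable without
any instrument data:

* a two-class patient cohort (85 normal / 59 cancer by default, with cancer
  subtypes, presentation and tissue-quality grades drawn from the study-like
  composition table below);
* one research sample per patient, 1–5 burns per sample (uniform, median 3);
* m/z 600–1000 lipid peaks: Gaussian peak shapes on a dense profile grid,
  lognormal peak heights, a curated discriminant panel whose mean log
  intensity is shifted upward in cancer, plus an abundant class-neutral
  background panel;
* per-spectrum rigid mass drift (invertible by two-point/one-point lock-mass
  correction), multiplicative TIC variation, additive clipped-Gaussian
  baseline noise, and a configurable fraction of degraded (baseline-
  dominated) burns that the quality filter should reject.

Burns within a sample share the sample's biological peak means, so patients
— not burns — carry the independent biological variation; this is what makes
leave-one-patient-out validation genuinely harder than leave-one-burn-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .lipid_annotation import (
    EXTERNAL_LOCKMASS_MZ,
    INTERNAL_LOCKMASS_MZ,
    Adduct,
    LipidFormula,
    adduct_mz,
    curated_adducts,
    curated_panel,
    extended_panel,
    monoisotopic_mass,
)
from .spectra_io import (
    CancerSubtype,
    Histology,
    Manifest,
    Modality,
    Quality,
    RawSpectrum,
    SampleRecord,
)

__all__ = [
    "COHORT_COMPOSITION",
    "PanelEntry",
    "SimulationConfig",
    "build_reference_panel",
    "simulate_burn_spectrum",
    "simulate_cohort",
]

#: Cohort composition used for categorical draws (counts per class). The
#: per-class totals, presentation mix, cancer subtype mix and Pipelle tissue
#: quality mix define the default study conditions.
COHORT_COMPOSITION: Mapping[str, Mapping] = {
    "normal": {
        "n": 85,
        "presentation": {"PMB": 36, "HMB": 26, "IMB": 10, "abdo_pain": 11, "other": 2},
        "quality": {"poor": 40, "moderate": 22, "good": 23},
    },
    "cancer": {
        "n": 59,
        "presentation": {"PMB": 49, "HMB": 3, "IMB": 0, "abdo_pain": 5, "other": 2},
        "quality": {"poor": 14, "moderate": 9, "good": 36},
        "subtypes": {
            "endometrioid_low": 30,
            "endometrioid_high": 19,
            "serous": 7,
            "carcinosarcoma": 2,
            "clear_cell": 1,
        },
    },
}

#: Internal/external lock masses (Th); peaks other than the internal
#: reference are kept out of a guard band around each so that lock-mass
#: estimation is unambiguous.
INTERNAL_LOCKMASS = INTERNAL_LOCKMASS_MZ
EXTERNAL_LOCKMASS = EXTERNAL_LOCKMASS_MZ
_LOCKMASS_GUARD = 0.6
_CURATED_GUARD = 0.3


@dataclass(frozen=True)
class PanelEntry:
    """One simulated species: a lipid, its adduct, and class intensities.

    Intensities are natural-log means of the Gaussian peak height; for
    "discriminant" entries the cancer mean exceeds the normal mean, for
    "background" entries the two are equal.
    """

    lipid: LipidFormula
    adduct: Adduct
    theoretical_mz: float
    mean_log_intensity_normal: float
    mean_log_intensity_cancer: float
    role: str = "background"  # "discriminant" | "background"

    @property
    def lipid_name(self) -> str:
        return self.lipid.name

    @property
    def formula(self) -> Mapping[str, int]:
        return self.lipid.elements


def build_reference_panel(
    discriminant_effect: float = 1.0,
    discriminant_mean_log: float = 4.0,
    background_mean_log: float = 5.5,
    n_background: int = 40,
) -> list[PanelEntry]:
    """Build the simulation panel: curated discriminant lipids + background.

    The nine curated species (the MS/MS-assignable panel, observed as
    [M−H]⁻ except the ceramide's [M+Cl]⁻) get a +``discriminant_effect``
    natural-log intensity shift in cancer. ``n_background`` class-neutral
    diacyl species are spread over 600–1000 m/z, kept clear of both lock
    masses and of every curated peak. Background species are given ~4.5×
    the per-species abundance of the discriminant set so that the panel's
    total ion current is background-dominated, keeping the fold-change
    distortion introduced by TIC normalisation small.
    """
    adducts = curated_adducts()
    discriminant_names = {
        "Cer(d18:1/18:0)", "PA(34:2)", "PG(O-16:0/14:0)", "PA(36:2)",
        "PE(P-16:0/20:4)", "PE(P-16:0/20:4)(12OH)", "PE(18:0/20:4)",
        "PS(36:2)", "PC(O-18:0/20:4)",
    }
    panel: list[PanelEntry] = []
    for lipid in curated_panel():
        if lipid.name not in discriminant_names:
            continue
        adduct = adducts[lipid.name]
        mz = adduct_mz(monoisotopic_mass(lipid), adduct)
        panel.append(
            PanelEntry(
                lipid, adduct, mz,
                mean_log_intensity_normal=discriminant_mean_log,
                mean_log_intensity_cancer=discriminant_mean_log + discriminant_effect,
                role="discriminant",
            )
        )
    keep_out = [INTERNAL_LOCKMASS, EXTERNAL_LOCKMASS]
    curated_mzs = [p.theoretical_mz for p in panel]

    candidates: list[tuple[float, LipidFormula]] = []
    for lipid in extended_panel():
        if lipid.name in discriminant_names or lipid.chains is not None:
            continue
        mz = adduct_mz(monoisotopic_mass(lipid), Adduct.M_MINUS_H)
        if not (600.0 <= mz < 1000.0):
            continue
        if any(abs(mz - lm) < _LOCKMASS_GUARD for lm in keep_out):
            continue
        if any(abs(mz - cm) < _CURATED_GUARD for cm in curated_mzs):
            continue
        candidates.append((mz, lipid))
    candidates.sort(key=lambda t: t[0])
    if n_background > 0 and candidates:
        stride = max(1, len(candidates) // n_background)
        chosen = candidates[::stride][:n_background]
    else:
        chosen = []
    for mz, lipid in chosen:
        panel.append(
            PanelEntry(
                lipid, Adduct.M_MINUS_H, mz,
                mean_log_intensity_normal=background_mean_log,
                mean_log_intensity_cancer=background_mean_log,
                role="background",
            )
        )
    return panel


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    ``burns_min``/``burns_max`` give a uniform integer law on {1..5}, whose
    median over a cohort is 3 burns per sample. Intensity noise is lognormal
    (``log_intensity_sd`` per burn on top of a per-patient biological offset
    ``patient_log_sd``); baseline noise is a Gaussian clipped at zero;
    ``mass_drift_range`` is the half-width of the uniform per-spectrum rigid
    drift; ``tic_scale_sd`` the sigma of the lognormal TIC factor.
    """

    n_normal_patients: int = 85
    n_cancer_patients: int = 59
    burns_min: int = 1
    burns_max: int = 5
    peak_sigma_mz: float = 0.02
    log_intensity_sd: float = 0.25
    patient_log_sd: float = 0.35
    baseline_noise_sd: float = 0.5
    mass_drift_range: float = 0.03
    tic_scale_sd: float = 0.3
    poor_quality_fraction: float = 0.15
    discriminant_effect: float = 1.0
    mz_min: float = 595.0
    mz_max: float = 1005.0
    mz_step: float = 0.01
    modality: Modality = Modality.DIATHERMY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal_patients < 1 or self.n_cancer_patients < 1:
            raise ValueError("patient counts must be >= 1")
        if not (1 <= self.burns_min <= self.burns_max):
            raise ValueError("burns_min/burns_max must satisfy 1 <= min <= max")
        if not (0.0 <= self.poor_quality_fraction < 1.0):
            raise ValueError("poor_quality_fraction must be in [0, 1)")
        if self.peak_sigma_mz <= 0 or self.mz_step <= 0 or self.mz_min >= self.mz_max:
            raise ValueError("invalid spectral grid / peak width parameters")

    def grid(self) -> np.ndarray:
        n = int(round((self.mz_max - self.mz_min) / self.mz_step))
        return self.mz_min + self.mz_step * np.arange(n)


def simulate_burn_spectrum(
    panel: Sequence[PanelEntry],
    histology: Histology | str,
    drift: float,
    tic_scale: float,
    rng: np.random.Generator,
    *,
    sample_log_offsets: np.ndarray | None = None,
    degraded: bool = False,
    peak_sigma_mz: float = 0.02,
    log_intensity_sd: float = 0.25,
    baseline_noise_sd: float = 0.5,
    mz_min: float = 595.0,
    mz_max: float = 1005.0,
    mz_step: float = 0.01,
    spectrum_id: str = "",
    sample_id: str = "",
    patient_id: str = "",
    modality: Modality = Modality.DIATHERMY,
    burn_index: int = 1,
) -> RawSpectrum:
    """One burn: Gaussian peaks at drifted panel m/z plus baseline noise.

    Peak heights are lognormal around the class mean (plus the sample's
    biological offset); a degraded burn has its peaks attenuated 50× and an
    elevated baseline, emulating a blood/fluid-dominated acquisition.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    histology = Histology(histology)
    n = int(round((mz_max - mz_min) / mz_step))
    mz = mz_min + mz_step * np.arange(n)
    intensity = np.zeros(n)
    if sample_log_offsets is None:
        sample_log_offsets = np.zeros(len(panel))
    for entry, offset in zip(panel, sample_log_offsets):
        mean_log = (
            entry.mean_log_intensity_cancer
            if histology is Histology.CANCER
            else entry.mean_log_intensity_normal
        )
        height = float(np.exp(mean_log + offset + rng.normal(0.0, log_intensity_sd)))
        if degraded:
            height *= 0.02
        centre = entry.theoretical_mz + drift
        lo = np.searchsorted(mz, centre - 5 * peak_sigma_mz)
        hi = np.searchsorted(mz, centre + 5 * peak_sigma_mz)
        if hi > lo:
            window = mz[lo:hi]
            intensity[lo:hi] += height * np.exp(
                -0.5 * ((window - centre) / peak_sigma_mz) ** 2
            )
    if baseline_noise_sd > 0:
        loc = 4.0 * baseline_noise_sd if degraded else 0.0
        intensity += rng.normal(loc, baseline_noise_sd, n)
    np.clip(intensity, 0.0, None, out=intensity)
    intensity *= tic_scale
    return RawSpectrum(
        mz, intensity,
        spectrum_id=spectrum_id, sample_id=sample_id, patient_id=patient_id,
        modality=modality, burn_index=burn_index,
    )


def _categorical(rng: np.random.Generator, counts: Mapping[str, int]) -> str:
    keys = list(counts)
    weights = np.array([counts[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=weights / weights.sum()))]


def simulate_cohort(
    config: SimulationConfig,
    panel: Sequence[PanelEntry] | None = None,
) -> tuple[list[RawSpectrum], Manifest]:
    """Generate a full cohort: one sample per patient, several burns each.

    Deterministic for a fixed config (single RNG stream seeded from
    ``config.seed``). A burn is degraded with probability
    ``poor_quality_fraction``; a sample whose burns are *all* degraded is
    flagged ``quality=poor`` in the manifest (its spectra should fail the
    downstream quality filter, so the sample drops out of the analysis, as
    happens for fluid-dominated Pipelle samples).
    """
    if panel is None:
        panel = build_reference_panel(discriminant_effect=config.discriminant_effect)
    rng = np.random.default_rng(config.seed)
    spectra: list[RawSpectrum] = []
    records: list[SampleRecord] = []
    classes = [(Histology.NORMAL, config.n_normal_patients), (Histology.CANCER, config.n_cancer_patients)]
    idx = 0
    for histology, n_patients in classes:
        comp = COHORT_COMPOSITION[histology.value]
        for _ in range(n_patients):
            idx += 1
            sample_id = f"S{idx:04d}"
            patient_id = f"P{idx:04d}"
            subtype = (
                CancerSubtype(_categorical(rng, comp["subtypes"]))
                if histology is Histology.CANCER
                else None
            )
            tissue_quality = Quality(_categorical(rng, comp["quality"]))
            n_burns = int(rng.integers(config.burns_min, config.burns_max + 1))
            offsets = rng.normal(0.0, config.patient_log_sd, len(panel))
            all_degraded = True
            for burn in range(1, n_burns + 1):
                drift = float(rng.uniform(-config.mass_drift_range, config.mass_drift_range))
                tic_scale = float(np.exp(rng.normal(0.0, config.tic_scale_sd)))
                degraded = bool(rng.random() < config.poor_quality_fraction)
                all_degraded &= degraded
                spectra.append(
                    simulate_burn_spectrum(
                        panel, histology, drift, tic_scale, rng,
                        sample_log_offsets=offsets,
                        degraded=degraded,
                        peak_sigma_mz=config.peak_sigma_mz,
                        log_intensity_sd=config.log_intensity_sd,
                        baseline_noise_sd=config.baseline_noise_sd,
                        mz_min=config.mz_min, mz_max=config.mz_max, mz_step=config.mz_step,
                        spectrum_id=f"{sample_id}_b{burn}",
                        sample_id=sample_id, patient_id=patient_id,
                        modality=config.modality, burn_index=burn,
                    )
                )
            records.append(
                SampleRecord(
                    sample_id=sample_id,
                    patient_id=patient_id,
                    histology=histology,
                    cancer_subtype=subtype,
                    quality=Quality.POOR if all_degraded else tissue_quality,
                    modality=config.modality,
                )
            )
    return spectra, Manifest(records)
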