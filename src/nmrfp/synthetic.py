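"""Synthetic cohort generator: spectra, quantified features, survival.

Emulates a dilated-cardiomyopathy heart-failure cohort of the kind the
pipeline targets: two latent classes (survivor-like / deceased-like
serum fingerprint) whose 1D 1H-NMR spectra differ in creatine (lower in
the deceased class), creatinine, trimethylamine-N-oxide and lactate
(higher), and broad lipoprotein signals; per-sample dilution to exercise
PQN; exponential survival times with a configurable between-class hazard
ratio and administrative censoring near 8 years; and clinical covariates
drawn class-conditionally around published-cohort-style medians.

Randomness is counter-based: the master seed plus a patient index (or
iteration index) feeds ``numpy.random.default_rng``, so enlarging the
cohort never reshuffles existing patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .plsda import DECEASED, SURVIVOR
from .spectra import Spectrum, write_spectrum_tsv

__all__ = [
    "PeakSpec",
    "SimConfig",
    "DEFAULT_PEAKS",
    "default_ppm_grid",
    "generate_cohort",
    "generate_spectrum",
    "generate_cohort_spectra",
    "generate_feature_table",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_spectra_dir",
]

PPM_MIN, PPM_MAX = 0.2, 10.0


@dataclass(frozen=True)
class PeakSpec:
    """One metabolite's contribution to the synthetic spectrum.

    ``class_effect`` is the deceased-class / survivor-class mean
    concentration ratio; ``cv`` the between-subject coefficient of
    variation of the (log-normal) concentration; ``linewidth`` the
    Lorentzian full width at half maximum in ppm.
    """

    metabolite_name: str
    centers: tuple[float, ...]
    multiplet_intensities: tuple[float, ...]
    linewidth: float = 0.004
    class_effect: float = 1.0
    cv: float = 0.2

    def __post_init__(self):
        if len(self.centers) != len(self.multiplet_intensities):
            raise ValueError("centers and multiplet_intensities differ in length")
        if not all(PPM_MIN <= c <= PPM_MAX for c in self.centers):
            raise ValueError(
                f"{self.metabolite_name}: centers must lie in "
                f"[{PPM_MIN}, {PPM_MAX}] ppm")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be positive")
        if self.class_effect <= 0:
            raise ValueError("class_effect must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


#: Default peak library.  Effect directions: creatine lower, and
#: trimethylamine-N-oxide / creatinine / lactate higher, in the
#: deceased-like class; lipoproteins as broad 0.05 ppm humps at 0.85 and
#: 1.25 ppm; the anomeric glucose doublet at 5.24 ppm anchors calibration.
DEFAULT_PEAKS: tuple[PeakSpec, ...] = (
    PeakSpec("creatine", (3.03, 3.93), (3.0, 2.0), 0.004, 0.70, 0.20),
    PeakSpec("creatinine", (3.05, 4.06), (3.0, 2.0), 0.004, 1.40, 0.20),
    PeakSpec("trimethylamine-N-oxide", (3.27,), (9.0,), 0.004, 1.50, 0.25),
    PeakSpec("lactate", (1.32, 1.34, 4.10, 4.12), (3.0, 3.0, 0.5, 0.5),
             0.004, 1.30, 0.25),
    PeakSpec("alanine", (1.46, 1.48), (1.5, 1.5), 0.004, 1.0, 0.20),
    # anomeric reference kept as a single line (no J fine structure) so an
    # already-calibrated spectrum re-calibrates with zero shift
    PeakSpec("glucose", (5.24, 3.41, 3.47, 3.83), (2.0, 2.0, 2.0, 1.5),
             0.004, 1.0, 0.15),
    PeakSpec("lipoprotein-CH3", (0.85,), (8.0,), 0.05, 1.15, 0.20),
    PeakSpec("lipoprotein-CH2", (1.25,), (12.0,), 0.05, 1.15, 0.20),
)


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings.

    Survival times are exponential per latent class: rate
    ``baseline_hazard`` (events/year) for the survivor-like class and
    ``baseline_hazard * hazard_ratio`` for the deceased-like class, with
    administrative censoring at ``censor_time`` years.
    """

    n_patients: int = 106
    prop_deceased: float = 26 / 106
    hazard_ratio: float = 5.71
    baseline_hazard: float = 0.04
    censor_time: float = 8.0
    dilution_cv: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0 < self.prop_deceased < 1:
            raise ValueError("prop_deceased must be strictly between 0 and 1")
        n_dec = int(round(self.n_patients * self.prop_deceased))
        if n_dec < 1 or n_dec >= self.n_patients:
            raise ValueError("prop_deceased degenerate for this cohort size")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard parameters must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if self.dilution_cv < 0 or self.noise_sd < 0:
            raise ValueError("dilution_cv and noise_sd must be non-negative")


# class-conditional covariate settings (survivor-like, deceased-like):
# normal (mean, sd) except NT-proBNP, log-normal (median, log-sd)
_COVARIATES = {
    "age_at_diagnosis": ((48.5, 11.1), (55.5, 17.0)),
    "time_from_diagnosis": ((15.0, 5.9), (15.0, 7.4)),
    "sbp": ((120.0, 14.8), (110.0, 14.8)),
    "eddi": ((30.8, 3.8), (36.9, 5.7)),
    "lavi": ((41.3, 16.3), (47.8, 26.9)),
    "lvef": ((46.0, 7.4), (37.5, 9.6)),
}
_NTPROBNP = ((180.6, 0.9), (613.3, 1.0))
# categorical class-conditional proportions (from published-cohort counts)
_SEX_M = (55 / 80, 19 / 26)
_NYHA = ((31 / 80, 41 / 80, 8 / 80, 0.0),
         (7 / 26, 12 / 26, 5 / 26, 2 / 26))
_DIURETIC = (51 / 80, 24 / 26)
_NYHA_LEVELS = ("I", "II", "III", "IV")


def _quota_counts(props, n: int) -> list[int]:
    """Largest-remainder rounding of proportions into integer counts."""
    raw = np.asarray(props, dtype=float) * n
    base = np.floor(raw + 1e-9).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for j in order[:rem]:
        base[j] += 1
    return base.tolist()


def _quota_assign(levels, props, n: int, rng) -> np.ndarray:
    counts = _quota_counts(props, n)
    arr = np.repeat(np.asarray(levels, dtype=object), counts)
    rng.shuffle(arr)
    return arr


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate a cohort table with latent class, covariates and survival.

    Exactly ``round(n_patients * prop_deceased)`` patients carry
    ``true_class = deceased``.  Continuous covariates come from
    class-conditional normal / log-normal draws; sex, NYHA class and
    diuretic use are assigned by within-class quota so cohort-level
    proportions are stable.
    """
    n = config.n_patients
    n_dec = int(round(n * config.prop_deceased))
    n_surv = n - n_dec
    classes = np.array([SURVIVOR] * n_surv + [DECEASED] * n_dec, dtype=object)
    rows = []
    for i in range(n):
        cls = classes[i]
        c = 1 if cls == DECEASED else 0
        rng = np.random.default_rng([config.seed, 1, i])
        row = {"patient_id": f"P{i + 1:03d}", "true_class": cls}
        for name, params in _COVARIATES.items():
            mu, sd = params[c]
            row[name] = float(rng.normal(mu, sd))
        row["lvef"] = float(np.clip(row["lvef"], 10.0, 75.0))
        row["time_from_diagnosis"] = float(max(row["time_from_diagnosis"], 0.5))
        row["eddi"] = float(max(row["eddi"], 15.0))
        row["lavi"] = float(max(row["lavi"], 10.0))
        med, lsd = _NTPROBNP[c]
        row["nt_probnp"] = float(med * np.exp(rng.normal(0.0, lsd)))
        rate = config.baseline_hazard * (config.hazard_ratio if c else 1.0)
        t_event = rng.exponential(1.0 / rate)
        row["survival_time"] = float(min(t_event, config.censor_time))
        row["event"] = int(t_event <= config.censor_time)
        rows.append(row)
    df = pd.DataFrame(rows)
    # within-class quota assignment of categoricals
    for c, cls in enumerate((SURVIVOR, DECEASED)):
        mask = df["true_class"] == cls
        m = int(mask.sum())
        rng = np.random.default_rng([config.seed, 2, c])
        df.loc[mask, "sex"] = _quota_assign(
            ("M", "F"), (_SEX_M[c], 1 - _SEX_M[c]), m, rng)
        df.loc[mask, "nyha"] = _quota_assign(_NYHA_LEVELS, _NYHA[c], m, rng)
        df.loc[mask, "diuretic"] = _quota_assign(
            (1, 0), (_DIURETIC[c], 1 - _DIURETIC[c]), m, rng).astype(int)
    df["diuretic"] = df["diuretic"].astype(int)
    cols = ["patient_id", "true_class", "survival_time", "event", "lvef",
            "nt_probnp", "age_at_diagnosis", "sex", "nyha", "sbp", "eddi",
            "lavi", "time_from_diagnosis", "diuretic"]
    return df[cols]


def default_ppm_grid(step: float = 0.001) -> np.ndarray:
    return np.round(np.arange(PPM_MIN, PPM_MAX + step / 2, step), 6)


def _lorentzian(ppm: np.ndarray, center: float, height: float,
                fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return height * hw**2 / ((ppm - center) ** 2 + hw**2)


def generate_spectrum(true_class: str, peaks=DEFAULT_PEAKS,
                      dilution: float = 1.0, noise_sd: float = 0.02,
                      ppm_grid: np.ndarray | None = None,
                      seed: int = 0, sample_id: str = "") -> Spectrum:
    """Simulate one serum spectrum for a patient of the given latent class.

    intensity = dilution * sum over metabolites of concentration *
    Lorentzian multiplet + Gaussian noise; deceased-class draws have each
    metabolite's mean concentration multiplied by its ``class_effect``.
    """
    if true_class not in (SURVIVOR, DECEASED):
        raise ValueError(f"unknown class {true_class!r}")
    if not peaks:
        raise ValueError("empty peak library")
    if ppm_grid is None:
        ppm_grid = default_ppm_grid()
    ppm = np.asarray(ppm_grid, dtype=float)
    if ppm.ndim != 1 or ppm.size < 2 or not np.all(np.diff(ppm) > 0):
        raise ValueError("ppm_grid must be strictly increasing")
    rng = np.random.default_rng([seed, 3])
    intensity = np.zeros_like(ppm)
    for pk in peaks:
        mean = pk.class_effect if true_class == DECEASED else 1.0
        # log-normal with the requested mean and coefficient of variation
        if pk.cv > 0:
            sigma = np.sqrt(np.log1p(pk.cv**2))
            conc = mean * rng.lognormal(-sigma**2 / 2.0, sigma)
        else:
            conc = mean
        for center, height in zip(pk.centers, pk.multiplet_intensities):
            intensity += conc * _lorentzian(ppm, center, height, pk.linewidth)
    intensity *= dilution
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=ppm.size)
    return Spectrum(ppm, intensity, sample_id)


def generate_cohort_spectra(cohort: pd.DataFrame, config: SimConfig,
                            peaks=DEFAULT_PEAKS,
                            ppm_grid: np.ndarray | None = None,
                            ) -> tuple[list[Spectrum], np.ndarray]:
    """One spectrum per cohort row; returns (spectra, applied dilutions).

    Dilution factors are log-normal with coefficient of variation
    ``config.dilution_cv`` so that PQN has something to undo.
    """
    if ppm_grid is None:
        ppm_grid = default_ppm_grid()
    spectra = []
    dilutions = np.empty(len(cohort))
    for k, (_, pat) in enumerate(cohort.iterrows()):
        rng = np.random.default_rng([config.seed, 4, k])
        if config.dilution_cv > 0:
            sigma = np.sqrt(np.log1p(config.dilution_cv**2))
            dil = float(rng.lognormal(-sigma**2 / 2.0, sigma))
        else:
            dil = 1.0
        dilutions[k] = dil
        spectra.append(generate_spectrum(
            pat["true_class"], peaks=peaks, dilution=dil,
            noise_sd=config.noise_sd, ppm_grid=ppm_grid,
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=str(pat["patient_id"])))
    return spectra, dilutions


def generate_feature_table(cohort: pd.DataFrame,
                           effects: dict[str, float],
                           cv: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Quantified-feature table (patients x named concentrations).

    Stands in for an external quantification platform's output: each
    feature is log-normal with unit survivor-class median; the
    deceased-class median is multiplied by its class effect.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    names = list(effects)
    if len(set(names)) != len(names):
        raise ValueError("effect keys must be unique")
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    is_dec = (cohort["true_class"] == DECEASED).to_numpy()
    data = np.empty((len(cohort), len(names)))
    for k in range(len(cohort)):
        rng = np.random.default_rng([seed, 5, k])
        draws = rng.normal(0.0, sigma, size=len(names)) if sigma else \
            np.zeros(len(names))
        base = np.exp(draws)
        if is_dec[k]:
            base = base * np.asarray([effects[n] for n in names])
        data[k] = base
    return pd.DataFrame(data, columns=names,
                        index=cohort["patient_id"].to_numpy())


# ---------------------------------------------------------------------------
# plain-text I/O

def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "survival_time", "event", "lvef", "nt_probnp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df[["survival_time", "event"]].isna().any().any():
        raise ValueError("cohort table has missing survival fields")
    return df


def write_spectra_dir(spectra: list[Spectrum], directory: str | Path) -> None:
    """Write per-sample two-column TSVs plus a manifest.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec in spectra:
        fname = f"{spec.sample_id}.tsv"
        write_spectrum_tsv(spec, directory / fname)
        rows.append({"sample_id": spec.sample_id, "filename": fname})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
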