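"""Spectral processing: ppm calibration, uniform binning, PQN and PCA.

Turns calibrated frequency-domain 1D NMR spectra into the normalized
binned matrix consumed by the fingerprint classifier.  Bins are 0.02 ppm
wide over 0.2-10 ppm by default, with the residual-water and ethanol
regions excluded; probabilistic quotient normalization (PQN) corrects
per-sample dilution against the cohort median spectrum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "BinnedMatrix",
    "CalibrationError",
    "DEFAULT_EXCLUSIONS",
    "calibrate_ppm",
    "bin_spectrum",
    "bin_spectra",
    "pqn_normalize",
    "pca_scores",
    "read_spectrum_tsv",
    "write_spectrum_tsv",
    "read_spectra_dir",
    "write_binned_csv",
    "read_binned_csv",
]

#: ppm regions removed before analysis: residual water and the two
#: ethanol multiplets.
DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = (
    (4.37, 5.13),
    (1.12, 1.23),
    (3.53, 3.73),
)

_EPS = 1e-9


class CalibrationError(ValueError):
    """No usable reference peak found in the calibration window."""


@dataclass(frozen=True)
class Spectrum:
    """One sample's frequency-domain spectrum.

    Parameters
    ----------
    ppm : array
        Chemical-shift axis in ppm, strictly monotone (either direction).
    intensity : array
        Intensities in arbitrary units, same length as ``ppm``.
    sample_id : str
        Sample label.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or inten.ndim != 1 or ppm.size != inten.size:
            raise ValueError("ppm and intensity must be 1-D of equal length")
        d = np.diff(ppm)
        if ppm.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", inten)

    def ascending(self) -> "Spectrum":
        """Return a copy with the ppm axis in ascending order."""
        if self.ppm.size >= 2 and self.ppm[1] < self.ppm[0]:
            return Spectrum(self.ppm[::-1].copy(), self.intensity[::-1].copy(),
                            self.sample_id)
        return self


@dataclass
class BinnedMatrix:
    """Samples x retained-bins matrix of integrated spectral areas.

    ``values`` holds one row per sample; ``bin_starts`` labels each
    retained bin by its starting ppm (bin width is uniform).  PQN state
    is tracked in ``normalization`` and, after normalization, the
    per-sample dilution quotients in ``quotients``.
    """

    values: np.ndarray
    bin_starts: np.ndarray
    bin_width: float
    sample_ids: list[str]
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)
    normalization: str = "raw"
    quotients: np.ndarray | None = None
    reference_spectrum: np.ndarray | None = None

    @property
    def bin_edges(self) -> np.ndarray:
        """Edges of the retained bins as an (n_bins, 2) array."""
        starts = np.asarray(self.bin_starts, dtype=float)
        return np.column_stack([starts, starts + self.bin_width])

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=[f"{s:.2f}" for s in self.bin_starts])


def calibrate_ppm(spectrum: Spectrum, reference_ppm: float = 5.24,
                  search_halfwidth: float = 0.05) -> Spectrum:
    """Shift the ppm axis so the tallest peak near ``reference_ppm`` sits on it.

    By default calibrates to the anomeric glucose doublet at 5.24 ppm.
    The spectrum must contain a local maximum inside
    ``[reference_ppm - search_halfwidth, reference_ppm + search_halfwidth]``;
    a flat window raises :class:`CalibrationError`.
    """
    spec = spectrum.ascending()
    lo, hi = reference_ppm - search_halfwidth, reference_ppm + search_halfwidth
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    if not mask.any():
        raise CalibrationError(
            f"no spectral points in calibration window [{lo:.3f}, {hi:.3f}] ppm")
    idx = np.flatnonzero(mask)
    window = spec.intensity[idx]
    if np.ptp(window) <= _EPS * max(1.0, np.abs(window).max(initial=0.0)):
        raise CalibrationError(
            f"no peak found in calibration window [{lo:.3f}, {hi:.3f}] ppm "
            "(window is flat)")
    peak_ppm = spec.ppm[idx[np.argmax(window)]]
    shift = reference_ppm - peak_ppm
    if abs(shift) < 1e-9:
        return spectrum
    return Spectrum(spectrum.ppm + shift, spectrum.intensity, spectrum.sample_id)


def _bin_edges(ppm_range: tuple[float, float], bin_width: float) -> np.ndarray:
    lo, hi = ppm_range
    n = int(round((hi - lo) / bin_width))
    if not np.isclose(lo + n * bin_width, hi, atol=1e-6):
        n = int(np.floor((hi - lo) / bin_width + _EPS))
    return lo + bin_width * np.arange(n + 1)

def _retained_mask(edges: np.ndarray,
                   exclusions: list[tuple[float, float]]) -> np.ndarray:
    """A bin is dropped iff it overlaps an exclusion with positive measure."""
    starts, ends = edges[:-1], edges[1:]
    keep = np.ones(starts.size, dtype=bool)
    for lo, hi in exclusions:
        overlap = np.minimum(ends, hi) - np.maximum(starts, lo)
        keep &= overlap <= _EPS
    return keep


def bin_spectrum(spectrum: Spectrum, bin_width: float = 0.02,
                 ppm_range: tuple[float, float] = (0.2, 10.0),
                 exclusions: list[tuple[float, float]] | None = None,
                 ) -> BinnedMatrix:
    """Integrate one spectrum into uniform chemical-shift bins.

    Each bin ``[edge_k, edge_{k+1})`` receives the trapezoidal integral of
    the intensity over that interval (interpolating at the edges, so a
    constant spectrum of 1.0 yields exactly ``bin_width`` per bin).  Bins
    overlapping any exclusion interval are dropped.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if exclusions is None:
        exclusions = list(DEFAULT_EXCLUSIONS)
    lo, hi = ppm_range
    exclusions = [(max(a, lo), min(b, hi)) for a, b in exclusions
                  if max(a, lo) < min(b, hi)]
    spec = spectrum.ascending()
    if spec.ppm[0] > lo + _EPS or spec.ppm[-1] < hi - _EPS:
        raise ValueError(
            f"spectrum covers [{spec.ppm[0]:.3f}, {spec.ppm[-1]:.3f}] ppm, "
            f"binning range [{lo}, {hi}] not covered")
    edges = _bin_edges(ppm_range, bin_width)
    # cumulative trapezoid of intensity, then bin integral by edge interpolation
    cum = np.concatenate([[0.0], np.cumsum(
        0.5 * (spec.intensity[1:] + spec.intensity[:-1]) * np.diff(spec.ppm))])
    # exact trapezoid of the piecewise-linear interpolant: cumulative value at
    # the grid point left of each edge plus the partial trapezoid up to it
    f_edges = np.interp(edges, spec.ppm, spec.intensity)
    k = np.searchsorted(spec.ppm, edges, side="right") - 1
    k = np.clip(k, 0, spec.ppm.size - 2)
    left = spec.ppm[k]
    f_left = spec.intensity[k]
    cum_edges = cum[k] + 0.5 * (f_left + f_edges) * (edges - left)
    areas = np.diff(cum_edges)
    keep = _retained_mask(edges, exclusions)
    return BinnedMatrix(values=areas[keep][None, :],
                        bin_starts=edges[:-1][keep],
                        bin_width=bin_width,
                        sample_ids=[spectrum.sample_id],
                        excluded_regions=exclusions)


def bin_spectra(spectra: list[Spectrum], bin_width: float = 0.02,
                ppm_range: tuple[float, float] = (0.2, 10.0),
                exclusions: list[tuple[float, float]] | None = None,
                ) -> BinnedMatrix:
    """Bin a list of spectra into one matrix (rows in input order)."""
    if not spectra:
        raise ValueError("no spectra given")
    rows = [bin_spectrum(s, bin_width, ppm_range, exclusions) for s in spectra]
    first = rows[0]
    return BinnedMatrix(values=np.vstack([r.values for r in rows]),
                        bin_starts=first.bin_starts,
                        bin_width=bin_width,
                        sample_ids=[s.sample_id for s in spectra],
                        excluded_regions=first.excluded_regions)


def pqn_normalize(matrix: BinnedMatrix,
                  reference: str = "median_spectrum") -> BinnedMatrix:
    """Probabilistic quotient normalization against the cohort median spectrum.

    For each sample the dilution quotient is the median, over bins where the
    reference is strictly positive, of sample-bin / reference-bin; the
    sample row is divided by its quotient.  Quotients and the reference are
    stored on the returned matrix and ``normalization`` is set to ``"pqn"``.

    Renormalizing an already-normalized matrix reuses its stored reference,
    making the operation exactly idempotent (all quotients 1).
    """
    if reference != "median_spectrum":
        raise ValueError(f"unknown PQN reference {reference!r}")
    X = np.asarray(matrix.values, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PQN needs at least 2 samples")
    if matrix.normalization == "pqn" and matrix.reference_spectrum is not None:
        ref = np.asarray(matrix.reference_spectrum, dtype=float)
    else:
        ref = np.median(X, axis=0)
    pos = ref > 0
    if pos.sum() < 0.5 * ref.size:
        raise ValueError("reference spectrum must be positive on >=50% of bins")
    quotients = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        row = X[i]
        if not np.any(row != 0):
            raise ValueError(
                f"sample {matrix.sample_ids[i]!r} is all zero; cannot normalize")
        quotients[i] = np.median(row[pos] / ref[pos])
        if quotients[i] <= 0:
            raise ValueError(
                f"sample {matrix.sample_ids[i]!r} has non-positive PQN quotient")
    out = replace(matrix)
    out.values = X / quotients[:, None]
    out.normalization = "pqn"
    out.quotients = quotients
    out.reference_spectrum = ref
    return out


def pca_scores(matrix: BinnedMatrix | np.ndarray, n_components: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and explained-variance fractions of the binned matrix.

    The matrix is column-mean-centered and decomposed by SVD; scores are
    mutually orthogonal and explained-variance fractions are
    non-increasing and sum to at most 1.
    """
    X = matrix.values if isinstance(matrix, BinnedMatrix) else np.asarray(matrix)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, bins)="
            f"{min(n - 1, p)}")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    total = np.sum(s**2)
    evr = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return scores, evr


# ---------------------------------------------------------------------------
# I/O: two-column TSV spectra with a manifest, BinnedMatrix CSV + sidecar JSON

def write_spectrum_tsv(spectrum: Spectrum, path: str | Path) -> None:
    arr = np.column_stack([spectrum.ppm, spectrum.intensity])
    np.savetxt(path, arr, fmt="%.6f\t%.8g", comments="",
               header="ppm\tintensity")


def read_spectrum_tsv(path: str | Path, sample_id: str | None = None) -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    if sample_id is None:
        sample_id = Path(path).stem
    return Spectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), sample_id)


def read_spectra_dir(directory: str | Path) -> list[Spectrum]:
    """Read all spectra listed in ``manifest.csv`` (sample_id, filename)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    return [read_spectrum_tsv(directory / row.filename, row.sample_id)
            for row in manifest.itertuples()]


def write_binned_csv(matrix: BinnedMatrix, path: str | Path) -> None:
    """Write the matrix as CSV (header = bin-start ppm) plus sidecar JSON."""
    path = Path(path)
    matrix.to_dataframe().to_csv(path, index_label="sample_id")
    meta = {
        "bin_width": matrix.bin_width,
        "bin_starts": [round(float(s), 6) for s in matrix.bin_starts],
        "excluded_regions": [list(r) for r in matrix.excluded_regions],
        "normalization": matrix.normalization,
        "quotients": (None if matrix.quotients is None
                      else [float(q) for q in matrix.quotients]),
        "reference_spectrum": (None if matrix.reference_spectrum is None
                               else [float(v) for v in
                                     matrix.reference_spectrum]),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_binned_csv(path: str | Path) -> BinnedMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col="sample_id")
    meta_path = path.with_suffix(".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    else:
        starts = [float(c) for c in df.columns]
        width = round(starts[1] - starts[0], 6) if len(starts) > 1 else 0.02
        meta = {"bin_width": width, "bin_starts": starts,
                "excluded_regions": [], "normalization": "raw",
                "quotients": None}
    q = meta.get("quotients")
    ref = meta.get("reference_spectrum")
    return BinnedMatrix(values=df.to_numpy(dtype=float),
                        bin_starts=np.asarray(meta["bin_starts"], dtype=float),
                        bin_width=float(meta["bin_width"]),
                        sample_ids=[str(s) for s in df.index],
                        excluded_regions=[tuple(r) for r in
                                          meta["excluded_regions"]],
                        normalization=meta["normalization"],
                        quotients=None if q is None else np.asarray(q),
                        reference_spectrum=None if ref is None
                        else np.asarray(ref))
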