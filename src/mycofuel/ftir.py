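"""FTIR chemometrics for tracking microbial lipid accumulation.

Implements the processing chain used to follow lipid storage in oleaginous
fungi by mid-infrared spectroscopy:

1. window extraction (the lipid acyl-chain region 2800-3050 cm^-1 and the
   CH2/CH3 bending region 1350-1500 cm^-1 carry most of the signal),
2. second-derivative band resolution — boxcar (moving-mean) smoothing of a
   configurable odd width (default 25 points) followed by a central
   finite-difference second derivative; overlapping absorption bands appear
   as resolved local *minima* of the second derivative,
3. assignment of resolved band positions against a reference dictionary of
   lipid/protein vibrational modes,
4. correlation-matrix PCA over a spectral window: spectra are standardized
   per wavenumber (zero mean, unit variance), the correlation matrix is
   diagonalized, and scores are projections of the standardized spectra on
   the leading eigenvectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "FtirError",
    "Spectrum",
    "BandReference",
    "BandAssignment",
    "PCAResult",
    "BAND_REFERENCE",
    "extract_window",
    "resample",
    "second_derivative",
    "find_bands",
    "assign_bands",
    "pca_window",
]


class FtirError(ValueError):
    """Invalid spectrum or spectral operation."""


@dataclass
class Spectrum:
    """A single-beam absorbance spectrum on a strictly monotone grid.

    Wavenumbers are stored ascending; spectra supplied descending (the
    native instrument order) are flipped on construction.  ``processing``
    is an append-only log of the transforms applied.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    processing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wn.ndim != 1 or ab.ndim != 1:
            raise FtirError("wavenumbers and absorbance must be 1-D")
        if wn.size != ab.size:
            raise FtirError(
                f"length mismatch: {wn.size} wavenumbers, "
                f"{ab.size} absorbances"
            )
        if wn.size >= 2:
            d = np.diff(wn)
            if np.all(d < 0):
                wn, ab = wn[::-1], ab[::-1]
                d = -d
            if not np.all(d > 0):
                raise FtirError("wavenumber grid must be strictly monotone")
        self.wavenumbers = wn
        self.absorbance = ab

    def __len__(self) -> int:
        return self.wavenumbers.size

    def log(self, step: str) -> "Spectrum":
        return replace(self, processing=self.processing + (step,))


def extract_window(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Inclusive sub-spectrum on [lo, hi] cm^-1."""
    if lo >= hi:
        raise FtirError(f"window bounds out of order: {lo} >= {hi}")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise FtirError(
            f"window [{lo}, {hi}] cm^-1 does not overlap the grid "
            f"[{s.wavenumbers[0]:g}, {s.wavenumbers[-1]:g}]"
        )
    return Spectrum(
        wavenumbers=s.wavenumbers[mask],
        absorbance=s.absorbance[mask],
        label=s.label,
        processing=s.processing + (f"window[{lo:g},{hi:g}]",),
    )


def resample(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto a new (strictly increasing) grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise FtirError("target grid must be 1-D strictly increasing")
    ab = np.interp(grid, s.wavenumbers, s.absorbance)
    return Spectrum(
        wavenumbers=grid,
        absorbance=ab,
        label=s.label,
        processing=s.processing + ("resample",),
    )


def _uniform_grid(s: Spectrum) -> Spectrum:
    """Resample to the median step if the grid is not uniform."""
    d = np.diff(s.wavenumbers)
    h = np.median(d)
    if np.max(np.abs(d - h)) <= 1e-9 * max(1.0, abs(h)):
        return s
    grid = np.arange(s.wavenumbers[0], s.wavenumbers[-1] + h / 2, h)
    return resample(s, grid)


def second_derivative(s: Spectrum, width: int = 25) -> Spectrum:
    """Smoothed second derivative d2A/dnu2.

    Moving-mean (boxcar) smoothing of ``width`` points, then the central
    three-point second difference scaled by the squared grid step.  The
    (width-1)/2 + 1 points at each end, where the stencil is undefined, are
    trimmed.  Exact for quadratic baselines; a pure Gaussian band yields a
    minimum at the band centre.
    """
    if width < 3 or width % 2 == 0:
        raise FtirError("smoothing width must be an odd integer >= 3")
    s = _uniform_grid(s)
    n = len(s)
    if n < width + 2:
        raise FtirError(
            f"spectrum has {n} points; need at least width + 2 = {width + 2}"
        )
    h = float(s.wavenumbers[1] - s.wavenumbers[0])
    half = width // 2
    smooth = np.convolve(s.absorbance, np.ones(width) / width, mode="valid")
    wn_smooth = s.wavenumbers[half:n - half]
    d2 = (smooth[:-2] - 2.0 * smooth[1:-1] + smooth[2:]) / h**2
    return Spectrum(
        wavenumbers=wn_smooth[1:-1],
        absorbance=d2,
        label=s.label,
        processing=s.processing + (f"second_derivative[width={width}]",),
    )


def find_bands(d2: Spectrum, prominence: float = 0.0) -> np.ndarray:
    """Band centres: local minima of the second derivative below threshold.

    A minimum qualifies when the second derivative there is below
    ``-prominence`` *and* the dip has at least that prominence relative to
    its surroundings; both filters together reject baseline float-level
    wiggles as well as shoulders riding on stronger bands.
    """
    if prominence < 0:
        raise FtirError("prominence must be >= 0")
    y = -d2.absorbance
    kwargs = (
        {"height": prominence, "prominence": prominence}
        if prominence > 0 else {}
    )
    idx, _ = find_peaks(y, **kwargs)
    idx = idx[d2.absorbance[idx] < 0]
    return d2.wavenumbers[idx]


@dataclass(frozen=True)
class BandReference:
    """One reference vibrational band (single position or a range)."""

    lo: float
    hi: float
    mode: str
    biomolecule: str

    def distance(self, peak: float) -> float:
        if self.lo <= peak <= self.hi:
            return 0.0
        return min(abs(peak - self.lo), abs(peak - self.hi))


# Mid-IR band dictionary for microbial lipid extracts.
BAND_REFERENCE: tuple[BandReference, ...] = (
    BandReference(3008, 3008, "=C-H stretching", "Lipid (unsaturation)"),
    BandReference(2953, 2953, "-C-H (CH3) stretching (asym)", "Lipid"),
    BandReference(2924, 2924, "-C-H (CH2) stretching (asym)", "Lipid"),
    BandReference(2853, 2853, "-C-H (CH2) stretching (sym)", "Lipid"),
    BandReference(1745, 1745, "-C=O (ester) stretching", "Lipid"),
    BandReference(1465, 1465, "-C-H (CH2, CH3) bending (scissoring)", "Lipid"),
    BandReference(1415, 1415, "C-H rocking", "Protein"),
    BandReference(1377, 1377, "-C-H (CH3) bending (sym)", "Lipid"),
    BandReference(
        1240, 1265, "P=O asymmetric stretching of >PO2- phosphodiester",
        "Polyphosphate, phospholipid",
    ),
    BandReference(720, 720, "CH2 rocking, bending", "Lipid"),
)


@dataclass(frozen=True)
class BandAssignment:
    """A resolved band matched (or not) to a reference mode."""

    peak: float
    reference_lo: float | None
    reference_hi: float | None
    mode: str
    biomolecule: str
    matched: bool


def assign_bands(
    peaks: Iterable[float],
    reference: Sequence[BandReference] = BAND_REFERENCE,
    tol: float = 4.0,
) -> list[BandAssignment]:
    """Nearest-reference assignment of resolved band positions.

    A peak matches the reference of minimum distance if that distance is
    within ``tol`` cm^-1 (peaks inside a ranged reference have distance 0);
    peaks matching nothing are labelled ``unassigned``.
    """
    if tol < 0:
        raise FtirError("tolerance must be >= 0")
    out = []
    for p in peaks:
        p = float(p)
        best = min(reference, key=lambda r: r.distance(p), default=None)
        if best is not None and best.distance(p) <= tol:
            out.append(
                BandAssignment(
                    peak=p,
                    reference_lo=best.lo,
                    reference_hi=best.hi,
                    mode=best.mode,
                    biomolecule=best.biomolecule,
                    matched=True,
                )
            )
        else:
            out.append(
                BandAssignment(
                    peak=p, reference_lo=None, reference_hi=None,
                    mode="unassigned", biomolecule="unassigned", matched=False,
                )
            )
    return out


@dataclass
class PCAResult:
    """Correlation-matrix PCA of a set of spectra over one window.

    ``loadings`` has shape (n_kept_wavenumbers, n_components), columns
    orthonormal; ``scores`` has shape (n_spectra, n_components);
    ``explained_variance_ratio`` are the eigenvalue fractions of the
    correlation matrix, non-increasing.
    """

    wavenumbers: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    labels: list[str] = field(default_factory=list)
    dropped_wavenumbers: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )

    def reconstruct_standardized(self) -> np.ndarray:
        """scores @ loadings.T — equals Z exactly with all components kept."""
        return self.scores @ self.loadings.T


def pca_window(
    spectra: Sequence[Spectrum],
    lo: float | None = None,
    hi: float | None = None,
    n_components: int | None = None,
) -> PCAResult:
    """Correlation-matrix PCA of spectra over a wavenumber window.

    Spectra must already share a grid (use :func:`resample`).  Each
    wavenumber variable is standardized to zero mean and unit variance
    (ddof=1); zero-variance variables are dropped with a warning.  The
    correlation matrix is diagonalized, eigenpairs are sorted by descending
    eigenvalue, and the sign of each eigenvector is fixed so that its
    largest-magnitude loading is positive.
    """
    if len(spectra) < 3:
        raise FtirError("need at least 3 spectra for PCA")
    if lo is not None or hi is not None:
        lo = spectra[0].wavenumbers[0] if lo is None else lo
        hi = spectra[0].wavenumbers[-1] if hi is None else hi
        spectra = [extract_window(s, lo, hi) for s in spectra]
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if len(s) != len(grid) or not np.allclose(s.wavenumbers, grid):
            raise FtirError(
                "spectra are not on a common grid; resample first"
            )

    X = np.vstack([s.absorbance for s in spectra])
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} zero-variance "
            "wavenumber variables",
            stacklevel=2,
        )
    if not keep.any():
        raise FtirError("all wavenumber variables have zero variance")
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    n = X.shape[0]
    corr = Z.T @ Z / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # reproducible orientation: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    if n_components is not None:
        eigvec = eigvec[:, :n_components]
        ratio = eigval[:n_components] / eigval.sum()
    else:
        ratio = eigval / eigval.sum()
    return PCAResult(
        wavenumbers=grid[keep],
        loadings=eigvec,
        scores=Z @ eigvec,
        explained_variance_ratio=ratio,
        labels=[s.label for s in spectra],
        dropped_wavenumbers=grid[~keep],
    )
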