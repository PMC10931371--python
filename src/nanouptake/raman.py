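"""Label-free Raman hyperspectral pipeline.

Preprocessing (cosmic-spike removal, SNIP baseline subtraction, silent-region
excision, per-spectrum mean normalization) followed by linear unmixing:
N-FINDR endmember extraction under the pure-pixel assumption and per-pixel
non-negative least squares (NNLS) abundances.  Univariate band-intensity
imaging and automated endmember identification against the component band
library complete the chain.

The estimator classes (:class:`RamanPreprocessor`, :class:`NFINDR`) follow
scikit-learn conventions (``fit``/``transform``, trailing-underscore fitted
attributes) and operate on 2-D matrices of shape ``(n_pixels, n_channels)``;
the module-level functions wrap them for :class:`RamanCube` inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls as _scipy_nnls
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .bands import ComponentLibrary, default_library

logger = logging.getLogger(__name__)

__all__ = [
    "RamanCube",
    "PreprocessParams",
    "EndmemberSet",
    "AbundanceStack",
    "BandImage",
    "DegeneratePixelError",
    "despike",
    "snip_baseline",
    "normalize_mean",
    "cut_silent_region",
    "preprocess",
    "RamanPreprocessor",
    "NFINDR",
    "nfindr_extract",
    "nnls_abundances",
    "band_intensity_image",
    "classify_endmembers",
    "peak_positions",
    "cosine_similarity",
]


class DegeneratePixelError(ValueError):
    """A pixel spectrum carries no usable signal (non-positive mean)."""


# --------------------------------------------------------------------------
# containers


@dataclass
class RamanCube:
    """Hyperspectral Raman image: a spectrum per (x, y, z) grid point.

    Attributes
    ----------
    axis : (n_channels,) ndarray
        Strictly increasing wavenumber axis in cm^-1.
    intensities : (n_z, n_y, n_x, n_channels) ndarray
        Per-pixel spectra.
    step_um : float
        Lateral pixel pitch in micrometres.
    z_step_um : float
        Spacing between imaging planes in micrometres.
    """

    axis: np.ndarray
    intensities: np.ndarray
    step_um: float = 0.5
    z_step_um: float = 1.5

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.ndim != 1 or self.axis.size == 0:
            raise ValueError("axis must be a non-empty 1-D array")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.intensities.ndim != 4:
            raise ValueError(
                "intensities must have shape (n_z, n_y, n_x, n_channels)"
            )
        if self.intensities.shape[-1] != self.axis.size:
            raise ValueError("spectra length does not match axis length")
        if self.step_um <= 0 or self.z_step_um <= 0:
            raise ValueError("step sizes must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[:3]

    @property
    def n_pixels(self) -> int:
        nz, ny, nx = self.grid_shape
        return nz * ny * nx

    def as_matrix(self) -> np.ndarray:
        """Spectra flattened to ``(n_pixels, n_channels)`` (z-major order)."""
        return self.intensities.reshape(-1, self.axis.size)

    def with_data(self, axis: np.ndarray, matrix: np.ndarray) -> "RamanCube":
        """New cube on ``axis`` with flattened spectra ``matrix``."""
        nz, ny, nx = self.grid_shape
        return RamanCube(
            axis=np.asarray(axis, dtype=float),
            intensities=np.asarray(matrix, dtype=float).reshape(
                nz, ny, nx, -1
            ),
            step_um=self.step_um,
            z_step_um=self.z_step_um,
        )


@dataclass(frozen=True)
class PreprocessParams:
    """Tunables of the spectral preprocessing chain.

    despike_zmax : modified z-score threshold on channel-to-channel
        differences above which a channel counts as a cosmic spike.
    despike_window : half-width (channels) of the neighborhood whose
        unflagged mean replaces a spike.
    snip_iterations : maximum SNIP clipping window in channels.
    silent_region : (lo, hi) in cm^-1; channels strictly inside are cut.
    """

    despike_zmax: float = 6.0
    despike_window: int = 5
    snip_iterations: int = 60
    silent_region: tuple[float, float] = (1800.0, 2700.0)

    def __post_init__(self) -> None:
        if self.snip_iterations < 1:
            raise ValueError("snip_iterations must be >= 1")
        if self.silent_region[0] >= self.silent_region[1]:
            raise ValueError("silent_region must satisfy lo < hi")
        if self.despike_window < 1:
            raise ValueError("despike_window must be >= 1")


@dataclass
class EndmemberSet:
    """Extracted pure-component spectra on a working axis."""

    axis: np.ndarray
    spectra: np.ndarray  # (k, n_channels)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if self.spectra.shape[1] != self.axis.size:
            raise ValueError("endmember length does not match axis")
        if self.spectra.shape[0] < 1:
            raise ValueError("need at least one endmember")
        if not self.labels:
            self.labels = ["unassigned"] * self.spectra.shape[0]
        if len(self.labels) != self.spectra.shape[0]:
            raise ValueError("one label per endmember required")

    @property
    def k(self) -> int:
        return self.spectra.shape[0]


@dataclass
class AbundanceStack:
    """Per-endmember non-negative abundance maps over the cube grid."""

    maps: np.ndarray  # (k, n_z, n_y, n_x)
    residual: np.ndarray  # (n_z, n_y, n_x) per-pixel NNLS residual norm

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.residual = np.asarray(self.residual, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("maps must have shape (k, n_z, n_y, n_x)")
        if self.maps.shape[1:] != self.residual.shape:
            raise ValueError("residual grid does not match maps")

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class BandImage:
    """Mean intensity in a wavenumber window, per z-plane."""

    center: float
    width: float
    images: np.ndarray  # (n_z, n_y, n_x)

    @property
    def window(self) -> tuple[float, float]:
        return (self.center - self.width / 2.0, self.center + self.width / 2.0)


# --------------------------------------------------------------------------
# preprocessing primitives


def _spike_flags(spectrum: np.ndarray, zmax: float) -> np.ndarray:
    """Boolean mask of channels flagged as cosmic spikes.

    Uses the modified z-score of first differences (Whitaker-Hayes style):
    a single-channel spike produces one extreme positive and one extreme
    negative difference, flagging the spike channel and its successor.
    """
    d = np.diff(spectrum)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    scale = np.max(np.abs(d), initial=0.0)
    mad = max(mad, 1e-12 * max(scale, 1.0))
    z = 0.6745 * (d - med) / mad
    bad_diff = np.abs(z) > zmax
    flags = np.zeros(spectrum.size, dtype=bool)
    flags[1:] |= bad_diff  # channel the difference enters
    flags[:-1] |= bad_diff  # channel the difference leaves
    return flags


def despike(
    spectrum: np.ndarray, zmax: float = 6.0, window: int = 5
) -> np.ndarray:
    """Remove single-channel cosmic-ray spikes from one spectrum.

    Channels whose first difference has a modified z-score above ``zmax``
    are replaced by the mean of the unflagged channels within ``window``
    channels on either side; everything else is returned unchanged.
    """
    s = np.asarray(spectrum, dtype=float)
    if s.ndim != 1:
        raise ValueError("despike expects a single spectrum")
    if s.size < 2 * window:
        raise ValueError("spectrum shorter than twice the despike window")
    flags = _spike_flags(s, zmax)
    if not flags.any():
        return s.copy()
    out = s.copy()
    good = ~flags
    for i in np.flatnonzero(flags):
        lo, hi = max(0, i - window), min(s.size, i + window + 1)
        nb = good[lo:hi]
        if nb.any():
            out[i] = s[lo:hi][nb].mean()
        else:  # whole neighborhood spiked: fall back to global unflagged mean
            out[i] = s[good].mean() if good.any() else s.mean()
    return out


def _lls(v: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(v + 1.0) + 1.0) + 1.0)


def _inv_lls(v: np.ndarray) -> np.ndarray:
    return (np.exp(np.exp(v) - 1.0) - 1.0) ** 2 - 1.0


def _snip_matrix(X: np.ndarray, iterations: int) -> np.ndarray:
    """SNIP baselines for each row of ``X`` (vectorized over rows).

    Iterative clipping v(i) <- min(v(i), (v(i-w)+v(i+w))/2) with the window
    w increasing from 1 to ``iterations``, applied in the compressive
    log-log-sqrt (LLS) domain and back-transformed.  Spectra are shifted to
    be non-negative before the transform and shifted back afterwards.
    """
    n = X.shape[1]
    if iterations >= n:
        raise ValueError("snip_iterations must be smaller than spectrum length")
    offset = np.minimum(X.min(axis=1, keepdims=True), 0.0)
    v = _lls(X - offset)
    for w in range(1, iterations + 1):
        mid = 0.5 * (v[:, : n - 2 * w] + v[:, 2 * w :])
        v[:, w : n - w] = np.minimum(v[:, w : n - w], mid)
    return _inv_lls(v) + offset


def snip_baseline(
    spectrum: np.ndarray, iterations: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract a SNIP baseline from one spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = spectrum - baseline``.
    The clipping only ever lowers the working sequence, so the baseline
    never exceeds the spectrum and the corrected signal is non-negative up
    to the round-trip error of the LLS transform.
    """
    s = np.asarray(spectrum, dtype=float)
    if s.ndim != 1:
        raise ValueError("snip_baseline expects a single spectrum")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    baseline = _snip_matrix(s[None, :], iterations)[0]
    return baseline, s - baseline


def normalize_mean(spectrum: np.ndarray) -> np.ndarray:
    """Scale one spectrum so its mean equals exactly 1.

    Raises
    ------
    DegeneratePixelError
        If the spectrum mean is not positive (e.g. an all-zero pixel).
    """
    s = np.asarray(spectrum, dtype=float)
    m = s.mean()
    if not m > 0:
        raise DegeneratePixelError(
            f"cannot mean-normalize spectrum with mean {m!r}"
        )
    return s / m


def _silent_keep_mask(
    axis: np.ndarray, region: tuple[float, float]
) -> np.ndarray:
    lo, hi = region
    # channels exactly at a bound are retained
    return ~((axis > lo) & (axis < hi))


def cut_silent_region(
    cube: RamanCube, region: tuple[float, float] = (1800.0, 2700.0)
) -> RamanCube:
    """Drop channels strictly inside the biologically silent region.

    The silent region (default 1800-2700 cm^-1) carries no bands of the
    scene components; excising it removes dead weight before unmixing.
    Channels exactly at the bounds are retained.
    """
    lo, hi = region
    if lo >= hi:
        raise ValueError("silent region must satisfy lo < hi")
    keep = _silent_keep_mask(cube.axis, region)
    if not keep.any():
        raise ValueError("silent region covers the entire wavenumber axis")
    return cube.with_data(cube.axis[keep], cube.as_matrix()[:, keep])


class RamanPreprocessor(TransformerMixin, BaseEstimator):
    """Per-spectrum preprocessing transformer.

    Applies, per row of the input matrix: cosmic-spike removal, SNIP
    baseline subtraction, silent-region excision on the wavenumber axis,
    and mean normalization on the retained channels.  Rows whose mean is
    not positive after baseline removal are degenerate: they are returned
    as all-zero and flagged in :attr:`degenerate_mask_`.

    Parameters
    ----------
    axis : array-like
        Wavenumber axis of the input spectra (cm^-1, strictly increasing).
    despike_zmax, despike_window, snip_iterations, silent_region
        See :class:`PreprocessParams`.

    Attributes
    ----------
    axis_out_ : ndarray
        Retained wavenumber axis after the silent-region cut.
    keep_mask_ : ndarray of bool
        Channels retained from the input axis.
    degenerate_mask_ : ndarray of bool
        Per-row degeneracy flags from the most recent ``transform`` call.
    """

    def __init__(
        self,
        axis=None,
        despike_zmax: float = 6.0,
        despike_window: int = 5,
        snip_iterations: int = 60,
        silent_region: tuple[float, float] = (1800.0, 2700.0),
    ):
        self.axis = axis
        self.despike_zmax = despike_zmax
        self.despike_window = despike_window
        self.snip_iterations = snip_iterations
        self.silent_region = silent_region

    def _axis(self, X: np.ndarray) -> np.ndarray:
        if self.axis is None:
            raise ValueError("RamanPreprocessor requires a wavenumber axis")
        ax = np.asarray(self.axis, dtype=float)
        if ax.size != X.shape[1]:
            raise ValueError("axis length does not match spectra")
        return ax

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        ax = self._axis(X)
        self.keep_mask_ = _silent_keep_mask(ax, tuple(self.silent_region))
        self.axis_out_ = ax[self.keep_mask_]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not hasattr(self, "keep_mask_"):
            self.fit(X)
        self._axis(X)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = despike(X[i], self.despike_zmax, self.despike_window)
        out = out - _snip_matrix(out, self.snip_iterations)
        out = out[:, self.keep_mask_]
        means = out.mean(axis=1)
        degenerate = ~(means > 0)
        if degenerate.any():
            logger.warning(
                "%d degenerate pixel(s) excluded from normalization",
                int(degenerate.sum()),
            )
            out[degenerate] = 0.0
            means[degenerate] = 1.0
        out /= means[:, None]
        self.degenerate_mask_ = degenerate
        return out


def preprocess(
    cube: RamanCube, params: PreprocessParams | None = None
) -> tuple[RamanCube, np.ndarray]:
    """Preprocess every pixel of a cube.

    Returns the preprocessed cube (on the reduced axis) and a boolean
    degenerate-pixel mask of shape ``(n_z, n_y, n_x)``.
    """
    params = params or PreprocessParams()
    pre = RamanPreprocessor(
        axis=cube.axis,
        despike_zmax=params.despike_zmax,
        despike_window=params.despike_window,
        snip_iterations=params.snip_iterations,
        silent_region=params.silent_region,
    )
    mat = pre.fit_transform(cube.as_matrix())
    out = cube.with_data(pre.axis_out_, mat)
    flags = pre.degenerate_mask_.reshape(cube.grid_shape)
    return out, flags


# --------------------------------------------------------------------------
# unmixing


class NFINDR(TransformerMixin, BaseEstimator):
    """N-FINDR endmember extraction with NNLS abundance transform.

    Under the linear mixing model with the pure-pixel assumption, the
    spectra of the purest pixels span the simplex of maximal volume in the
    (k-1)-dimensional principal-component projection of the data.  Starting
    from a random vertex set, each vertex is in turn replaced by the pixel
    that most increases the simplex volume; replacement is accepted only on
    a strict increase, so the volume sequence is strictly increasing and
    the search terminates.  The best of ``n_restarts`` seeded restarts is
    kept.  Returned endmembers are actual pixel spectra.

    Parameters
    ----------
    n_endmembers : int
        Number k of endmembers to extract (k >= 1).
    n_restarts : int
        Number of random initializations.
    random_state : int or numpy Generator or None
        Seed for the restarts.
    max_sweeps : int
        Safety bound on full replacement sweeps per restart.

    Attributes
    ----------
    endmembers_ : (k, n_channels) ndarray
        Extracted pixel spectra (also exposed as ``components_``).
    indices_ : (k,) ndarray of int
        Row indices of the selected pixels in the training matrix.
    volume_ : float
        Simplex volume attained in the PCA-reduced space.
    volume_path_ : list of float
        Volumes of accepted configurations (strictly increasing) of the
        winning restart.
    """

    def __init__(
        self,
        n_endmembers: int = 3,
        n_restarts: int = 5,
        random_state=None,
        max_sweeps: int = 50,
    ):
        self.n_endmembers = n_endmembers
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.max_sweeps = max_sweeps

    # volume of the simplex spanned by rows `idx` of the augmented matrix A
    @staticmethod
    def _abs_det(A: np.ndarray, idx: np.ndarray) -> float:
        return abs(np.linalg.det(A[idx]))

    def _run_once(
        self, A: np.ndarray, rng: np.random.Generator
    ) -> tuple[np.ndarray, float, list[float]]:
        m, k = A.shape
        for _ in range(100):
            idx = rng.choice(m, size=k, replace=False)
            if self._abs_det(A, idx) > 1e-300:
                break
        else:
            raise ValueError(
                "could not find a non-degenerate starting simplex; the cube "
                "has fewer distinct components than requested endmembers"
            )
        vol = self._abs_det(A, idx)
        path = [vol]
        for _ in range(self.max_sweeps):
            improved = False
            for j in range(k):
                M = A[idx]
                try:
                    Minv = np.linalg.inv(M)
                except np.linalg.LinAlgError:
                    break
                # |det| after replacing vertex j by pixel i is
                # |det(M)| * |A[i] @ Minv[:, j]|
                gains = np.abs(A @ Minv[:, j])
                best = int(np.argmax(gains))
                if gains[best] > 1.0 + 1e-12 and best not in idx:
                    idx = idx.copy()
                    idx[j] = best
                    vol = self._abs_det(A, idx)
                    path.append(vol)
                    improved = True
            if not improved:
                break
        return idx, vol, path

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m, n = X.shape
        k = self.n_endmembers
        if k < 1:
            raise ValueError("n_endmembers must be >= 1")
        if k > m:
            raise ValueError(
                f"n_endmembers={k} exceeds the number of pixels ({m})"
            )
        rng = np.random.default_rng(self.random_state)
        if k == 1:
            # degenerate case: the pixel closest to the data mean
            centre = X.mean(axis=0)
            i = int(np.argmin(((X - centre) ** 2).sum(axis=1)))
            self.indices_ = np.array([i])
            self.endmembers_ = X[[i]].copy()
            self.components_ = self.endmembers_
            self.volume_, self.volume_path_ = 0.0, [0.0]
            return self
        if k - 1 < n:
            pca = PCA(n_components=k - 1, svd_solver="full")
            Y = pca.fit_transform(X)
            if pca.explained_variance_[-1] <= 1e-12 * max(
                pca.explained_variance_[0], 1e-30
            ):
                raise ValueError(
                    "cube appears to contain fewer distinct components "
                    f"than k={k} (rank-deficient after projection)"
                )
        else:
            Y = X
        A = np.column_stack([np.ones(m), Y])
        best = None
        for _ in range(max(1, self.n_restarts)):
            idx, vol, path = self._run_once(A, rng)
            if best is None or vol > best[1]:
                best = (idx, vol, path)
        idx, vol, path = best
        self.indices_ = np.asarray(idx)
        self.endmembers_ = X[self.indices_].copy()
        self.components_ = self.endmembers_
        self.volume_ = vol / math.factorial(k - 1)
        self.volume_path_ = [v / math.factorial(k - 1) for v in path]
        return self

    def transform(self, X) -> np.ndarray:
        """Per-row NNLS abundances against the fitted endmembers."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        A, _ = nnls_matrix(X, self.endmembers_)
        return A


def nnls_matrix(
    X: np.ndarray, endmembers: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve min ||E^T a - s||_2, a >= 0 for every spectrum in ``X``.

    Returns ``(abundances, residual_norms)`` of shapes (m, k) and (m,).
    """
    E = np.atleast_2d(np.asarray(endmembers, dtype=float)).T  # (n, k)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != E.shape[0]:
        raise ValueError("spectra and endmembers have different lengths")
    m, k = X.shape[0], E.shape[1]
    A = np.empty((m, k))
    r = np.empty(m)
    for i in range(m):
        A[i], r[i] = _scipy_nnls(E, X[i])
    return A, r


def nfindr_extract(
    cube: RamanCube,
    k: int,
    n_restarts: int = 5,
    seed: int | None = None,
    degenerate_mask: np.ndarray | None = None,
) -> EndmemberSet:
    """Extract ``k`` endmembers from a (preprocessed) cube.

    Pixels flagged in ``degenerate_mask`` are excluded from the search.
    The restart seed is mandatory for reproducible runs and echoed in the
    log.
    """
    logger.info("N-FINDR: k=%d, n_restarts=%d, seed=%r", k, n_restarts, seed)
    X = cube.as_matrix()
    if degenerate_mask is not None:
        valid = ~np.asarray(degenerate_mask, dtype=bool).reshape(-1)
        X = X[valid]
    if k > X.shape[0]:
        raise ValueError(
            f"k={k} exceeds the number of usable pixels ({X.shape[0]})"
        )
    est = NFINDR(n_endmembers=k, n_restarts=n_restarts, random_state=seed)
    est.fit(X)
    return EndmemberSet(axis=cube.axis, spectra=est.endmembers_)


def nnls_abundances(
    cube: RamanCube, endmembers: EndmemberSet
) -> AbundanceStack:
    """Per-pixel NNLS abundances of ``endmembers`` over the whole cube."""
    if endmembers.axis.size != cube.axis.size or not np.allclose(
        endmembers.axis, cube.axis
    ):
        raise ValueError("endmember axis does not match cube axis")
    E = endmembers.spectra
    if E.shape[0] > 1:
        if np.linalg.matrix_rank(E) < E.shape[0]:
            raise ValueError("endmember spectra are linearly dependent")
    A, r = nnls_matrix(cube.as_matrix(), E)
    nz, ny, nx = cube.grid_shape
    return AbundanceStack(
        maps=A.T.reshape(E.shape[0], nz, ny, nx),
        residual=r.reshape(nz, ny, nx),
    )


# --------------------------------------------------------------------------
# imaging and identification


def band_intensity_image(
    cube: RamanCube, center: float = 1000.0, width: float = 25.0
) -> BandImage:
    """Univariate false-color image: mean intensity in a band window.

    The default window (1000 +/- 12.5 cm^-1) targets the polystyrene
    aromatic ring breathing mode.
    """
    lo, hi = center - width / 2.0, center + width / 2.0
    sel = (cube.axis >= lo) & (cube.axis <= hi)
    if not sel.any():
        raise ValueError(
            f"band window [{lo}, {hi}] cm^-1 contains no axis channel "
            "(it may fall inside the excised silent region)"
        )
    imgs = cube.intensities[..., sel].mean(axis=-1)
    return BandImage(center=center, width=width, images=imgs)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two spectra (0 if either is null)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def classify_endmembers(
    endmembers: EndmemberSet,
    library: ComponentLibrary | None = None,
    min_similarity: float = 0.5,
) -> EndmemberSet:
    """Assign each endmember the best-matching library component label.

    Each endmember gets the label of the library reference spectrum
    (evaluated on the working axis) with maximal cosine similarity, or
    ``"unassigned"`` when the best similarity falls below
    ``min_similarity``.  Several endmembers may share a label — a strongly
    scattering inclusion can appear as a second, more intense endmember of
    the same material.
    """
    library = library or default_library()
    refs = {
        lab: library.reference_spectrum(lab, endmembers.axis)
        for lab in library.labels
    }
    labels = []
    for spec in endmembers.spectra:
        sims = {lab: cosine_similarity(spec, ref) for lab, ref in refs.items()}
        best = max(sims, key=sims.get)
        labels.append(best if sims[best] >= min_similarity else "unassigned")
    return replace(endmembers, labels=labels)


def peak_positions(
    axis: np.ndarray,
    spectrum: np.ndarray,
    prominence_fraction: float = 0.1,
) -> np.ndarray:
    """Wavenumbers of local maxima with prominence above a fraction of max.

    Returns an empty array for flat or non-positive spectra.
    """
    axis = np.asarray(axis, dtype=float)
    s = np.asarray(spectrum, dtype=float)
    if axis.size != s.size:
        raise ValueError("axis and spectrum lengths differ")
    top = s.max()
    if not top > s.min():
        return np.array([])
    idx, _ = find_peaks(s, prominence=prominence_fraction * top)
    return axis[idx]
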