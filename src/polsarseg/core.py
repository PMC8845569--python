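"""Core data model for polarimetric SAR covariance rasters.

A fully polarimetric SAR pixel is summarised by its 3x3 Hermitian sample
covariance matrix C3, formed from the lexicographic scattering vector
``[S_hh, sqrt(2) S_hv, S_vv]``.  Everything downstream (mean-shift features,
the Wishart edge statistic, the synthetic scene generator) works on rasters
of such matrices, so this module owns the containers and the small set of
numerically delicate primitives they share: the Pauli change of basis,
multi-look block averaging, and a regularised Hermitian log-determinant.

Grid convention used throughout the package: 0-based, row-major ``(row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CovarianceImage",
    "PauliImage",
    "LabelMap",
    "pauli_features",
    "multilook",
    "safe_logdet",
    "batched_safe_logdet",
]


# Lexicographic -> Pauli special-unitary change of basis for the monostatic
# (reciprocal) case.  Rows are the Pauli basis vectors expressed in the
# lexicographic basis [S_hh, sqrt(2) S_hv, S_vv]:
#   (S_hh + S_vv)/sqrt(2)  -- odd-bounce / surface scattering
#   (S_hh - S_vv)/sqrt(2)  -- even-bounce / double-bounce scattering
#   sqrt(2) S_hv           -- volume scattering
# A is unitary (A A^H = I), so T3 = A C3 A^H preserves total power (trace).
PAULI_TRANSFORM = np.array(
    [
        [1.0, 0.0, 1.0],
        [1.0, 0.0, -1.0],
        [0.0, np.sqrt(2.0), 0.0],
    ],
    dtype=complex,
) / np.sqrt(2.0)


class InvalidDataError(ValueError):
    """Raised when an input raster violates its physical invariants."""


@dataclass
class CovarianceImage:
    """Per-pixel 3x3 Hermitian covariance raster (linear power units).

    Parameters
    ----------
    data : complex ndarray, shape (height, width, 3, 3)
        Per-pixel covariance matrices.
    looks : float
        Nominal number of looks (independent samples averaged per pixel).
    date_tag : str
        Free-form acquisition identifier, e.g. ``"20130523"``.
    """

    data: np.ndarray
    looks: float = 1.0
    date_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4 or self.data.shape[2:] != (3, 3):
            raise InvalidDataError(
                f"covariance data must have shape (H, W, 3, 3), got {self.data.shape}"
            )
        if self.looks < 1:
            raise InvalidDataError(f"looks must be >= 1, got {self.looks}")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def validate(self, rtol: float = 1e-9) -> None:
        """Check Hermitian symmetry and non-negative diagonals.

        Raises :class:`InvalidDataError` naming the first offending pixel.
        """
        _check_hermitian(self.data, rtol=rtol)


def _check_hermitian(data: np.ndarray, rtol: float = 1e-9) -> None:
    herm_err = np.abs(data - np.conj(np.swapaxes(data, -1, -2))).max(axis=(-1, -2))
    scale = np.abs(data).max(axis=(-1, -2))
    bad = herm_err > rtol * np.maximum(scale, 1e-300)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InvalidDataError(
            f"covariance matrix at pixel ({r}, {c}) is not Hermitian "
            f"(max asymmetry {herm_err[r, c]:.3e})"
        )
    diags = np.real(np.diagonal(data, axis1=-2, axis2=-1))
    # allow a whisker of negative round-off relative to the matrix scale
    bad = (diags < -rtol * np.maximum(scale, 1e-300)[..., None]).any(axis=-1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InvalidDataError(
            f"covariance matrix at pixel ({r}, {c}) has a negative diagonal entry"
        )
    if not np.isfinite(data).all():
        r, c = np.argwhere(~np.isfinite(data).all(axis=(-1, -2)))[0]
        raise InvalidDataError(f"non-finite covariance entries at pixel ({r}, {c})")


@dataclass
class PauliImage:
    """Per-pixel 3-vector of non-negative Pauli scattering amplitudes."""

    features: np.ndarray  # float, shape (height, width, 3)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 3 or self.features.shape[2] != 3:
            raise InvalidDataError(
                f"Pauli features must have shape (H, W, 3), got {self.features.shape}"
            )

    @property
    def height(self) -> int:
        return self.features.shape[0]

    @property
    def width(self) -> int:
        return self.features.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.features.shape[:2]


@dataclass
class LabelMap:
    """Integer partition of the pixel grid into regions with ids 1..n_regions."""

    labels: np.ndarray  # int, shape (height, width)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidDataError(f"labels must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidDataError("labels must be integers")

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_regions(self) -> int:
        return int(self.labels.max(initial=0))

    def validate(self, require_connected: bool = True) -> None:
        """Check contiguous ids 1..n and (optionally) 4-connectivity per region.

        Final segmentations produced by graph partitioning may contain
        spatially disjoint segments; validate those with
        ``require_connected=False``.
        """
        n = self.n_regions
        if self.labels.min(initial=1) < 1:
            raise InvalidDataError("label ids must be >= 1 for every pixel")
        counts = np.bincount(self.labels.ravel(), minlength=n + 1)
        missing = np.nonzero(counts[1:] == 0)[0]
        if missing.size:
            raise InvalidDataError(f"label ids have gaps: id {missing[0] + 1} unused")
        if require_connected:
            from skimage import measure

            relab = measure.label(self.labels, connectivity=1)
            if relab.max() != n:
                raise InvalidDataError(
                    f"{relab.max() - n} region(s) are not 4-connected"
                )


def pauli_features(cov: CovarianceImage) -> PauliImage:
    """Extract per-pixel Pauli scattering amplitudes from a C3 raster.

    The lexicographic covariance C3 is rotated to the Pauli-basis coherency
    matrix ``T3 = A C3 A^H`` and the square roots of its (real, non-negative)
    diagonal are returned.  These three amplitudes — surface, double-bounce
    and volume scattering — are the feature vector used by the mean-shift
    over-segmentation, in linear amplitude units.
    """
    cov.validate()
    a = PAULI_TRANSFORM
    # diag(A C A^H)_k = sum_{ij} A_ki C_ij conj(A_kj)
    diag = np.einsum("ki,rcij,kj->rck", a, cov.data, np.conj(a), optimize=True)
    diag = np.real(diag)
    return PauliImage(np.sqrt(np.clip(diag, 0.0, None)))


def multilook(cov: CovarianceImage, win_rows: int, win_cols: int) -> CovarianceImage:
    """Non-overlapping block average of covariance matrices.

    Output dimensions are the floor divisions of the input dimensions;
    trailing partial blocks are dropped.  The nominal look count is
    multiplied by the window area.
    """
    if win_rows < 1 or win_cols < 1:
        raise ValueError("multilook window sides must be >= 1")
    h, w = cov.shape
    oh, ow = h // win_rows, w // win_cols
    if oh == 0 or ow == 0:
        raise ValueError(
            f"multilook window {win_rows}x{win_cols} larger than image {h}x{w}"
        )
    d = cov.data[: oh * win_rows, : ow * win_cols]
    d = d.reshape(oh, win_rows, ow, win_cols, 3, 3).mean(axis=(1, 3))
    return CovarianceImage(d, looks=cov.looks * win_rows * win_cols, date_tag=cov.date_tag)


def _regularized(m: np.ndarray) -> np.ndarray:
    """Add the trace-scaled jitter delta*I that keeps log-determinants finite."""
    tr = np.real(np.trace(m, axis1=-2, axis2=-1))
    delta = 1e-10 * np.maximum(tr / 3.0, 1e-30)
    out = m.astype(complex, copy=True)
    idx = np.arange(3)
    out[..., idx, idx] += delta[..., None]
    return out


def safe_logdet(m: np.ndarray) -> float:
    """Regularised log-determinant of a single 3x3 Hermitian matrix.

    Computes ``ln det(m + delta*I)`` with ``delta = 1e-10 * max(tr(m)/3, 1e-30)``
    via a Cholesky factorisation; the jitter guarantees a finite result for any
    Hermitian positive semi-definite input (rank-deficient sample covariances
    included).  Falls back to clamped eigenvalues if the factorisation fails.
    """
    a = _regularized(np.asarray(m, dtype=complex))
    try:
        chol = np.linalg.cholesky(a)
        return float(2.0 * np.sum(np.log(np.real(np.diagonal(chol)))))
    except np.linalg.LinAlgError:
        tr = max(np.real(np.trace(a)) / 3.0, 1e-30)
        w = np.linalg.eigvalsh(a)
        return float(np.sum(np.log(np.maximum(w, 1e-10 * tr))))


def batched_safe_logdet(m: np.ndarray) -> np.ndarray:
    """Vectorised :func:`safe_logdet` over an (..., 3, 3) stack."""
    a = _regularized(np.asarray(m, dtype=complex))
    sign, logdet = np.linalg.slogdet(a)
    ok = (np.real(sign) > 0) & np.isfinite(logdet)
    if not ok.all():
        bad = ~ok
        tr = np.maximum(np.real(np.trace(a[bad], axis1=-2, axis2=-1)) / 3.0, 1e-30)
        w = np.linalg.eigvalsh(a[bad])
        logdet[bad] = np.sum(np.log(np.maximum(w, 1e-10 * tr[..., None])), axis=-1)
    return logdet
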