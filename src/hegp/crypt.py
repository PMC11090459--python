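"""Encryption and decryption of genotype/phenotype data by orthogonal rotation.

A private orthogonal matrix P premultiplies every data matrix:

    y* = P y,   X* = P X,   M* = P M.

Because P'P = I, every cross product a Gibbs sampler or mixed-model fit
touches is preserved exactly in real arithmetic:

    M*'M* = M'M,   M*'y* = M'y,   M*'X* = M'X,   y*'y* = y'y,

so marker-effect inference on the cyphertext equals inference on the
plaintext, while individual rows become unrecognisable random linear
combinations of the originals.  Individual identifiers never enter the
cyphertext; marker identifiers (column order) are preserved.

Column centering of genotypes is a plaintext-side step: the column means are
confidential and stay with the data owner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError, MissingDataError
from .keygen import OrthogonalKey

__all__ = [
    "PlainDataset",
    "CipherDataset",
    "center_genotypes",
    "encrypt",
    "decrypt",
    "verify_invariance",
    "InvarianceReport",
    "impute_mean",
]


def _as_matrix(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None] if name == "X" else a
    return a


def _check_complete(a: np.ndarray, name: str) -> None:
    if np.isnan(a).any():
        raise MissingDataError(
            f"{name} contains missing values; rotation encryption requires complete "
            "data — impute before encrypting (e.g. impute_mean)"
        )
    if not np.isfinite(a).all():
        raise MissingDataError(f"{name} contains non-finite values")


@dataclass
class PlainDataset:
    """Confidential plaintext: phenotypes y, fixed-effect incidence X, dosages M.

    ``X`` must already contain its intercept column if one is wanted: after
    encryption an all-ones column becomes a non-constant column, which is
    correct and required for invariant inference.
    """

    y: np.ndarray
    X: np.ndarray
    M: np.ndarray
    individual_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)
    centered: bool = False
    column_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).reshape(-1)
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.M = np.asarray(self.M, dtype=np.float64)
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.M.shape[0] != n:
            raise InvalidArgumentError(
                f"row mismatch: y has {n}, X has {self.X.shape[0]}, M has {self.M.shape[0]}"
            )
        for a, name in ((self.y, "y"), (self.X, "X"), (self.M, "M")):
            _check_complete(a, name)
        if not self.individual_ids:
            self.individual_ids = [str(i) for i in range(n)]
        if not self.marker_ids:
            self.marker_ids = [f"m{j}" for j in range(self.M.shape[1])]
        if len(self.individual_ids) != n:
            raise InvalidArgumentError("individual_ids length mismatch")
        if len(self.marker_ids) != self.M.shape[1]:
            raise InvalidArgumentError("marker_ids length mismatch")
        if self.centered:
            means = np.abs(self.M.mean(axis=0))
            if means.size and means.max() > 1e-8:
                raise InvalidArgumentError(
                    "dataset flagged centered but column means reach "
                    f"{means.max():.2e}"
                )

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.M.shape[1]


@dataclass
class CipherDataset:
    """Shareable cyphertext.  Carries no individual identifiers by construction."""

    y_star: np.ndarray
    X_star: np.ndarray
    M_star: np.ndarray
    marker_ids: list[str] = field(default_factory=list)
    contributor_tag: str | None = None
    block_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.y_star = np.asarray(self.y_star, dtype=np.float64).reshape(-1)
        self.X_star = np.asarray(self.X_star, dtype=np.float64)
        if self.X_star.ndim == 1:
            self.X_star = self.X_star[:, None]
        self.M_star = np.asarray(self.M_star, dtype=np.float64)
        n = self.y_star.shape[0]
        if self.X_star.shape[0] != n or self.M_star.shape[0] != n:
            raise InvalidArgumentError("cyphertext row dimensions inconsistent")
        if not self.marker_ids:
            self.marker_ids = [f"m{j}" for j in range(self.M_star.shape[1])]
        if len(self.marker_ids) != self.M_star.shape[1]:
            raise InvalidArgumentError("marker_ids length mismatch")

    @property
    def n(self) -> int:
        return self.y_star.shape[0]

    @property
    def p(self) -> int:
        return self.M_star.shape[1]


def impute_mean(M: np.ndarray) -> np.ndarray:
    """Fill missing dosages with the column mean (explicit pre-encryption step)."""
    M = np.asarray(M, dtype=np.float64).copy()
    for j in range(M.shape[1]):
        col = M[:, j]
        nan = np.isnan(col)
        if nan.all():
            raise MissingDataError(f"column {j} is entirely missing")
        if nan.any():
            col[nan] = col[~nan].mean()
    return M


def center_genotypes(dataset: PlainDataset) -> PlainDataset:
    """Return a copy with each genotype column centered to zero mean.

    The subtracted column means are retained on the plaintext side
    (``column_means``); they are confidential and never enter the cyphertext.
    Monomorphic (constant) columns are left at zero with a warning.
    """
    _check_complete(dataset.M, "M")
    means = dataset.M.mean(axis=0)
    centered = dataset.M - means
    mono = np.all(dataset.M == dataset.M[0:1, :], axis=0)
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic column(s) centered to all-zero",
            UserWarning,
            stacklevel=2,
        )
    return PlainDataset(
        y=dataset.y.copy(),
        X=dataset.X.copy(),
        M=centered,
        individual_ids=list(dataset.individual_ids),
        marker_ids=list(dataset.marker_ids),
        centered=True,
        column_means=means,
    )


def encrypt(dataset: PlainDataset, key: OrthogonalKey) -> CipherDataset:
    """Encrypt a plaintext dataset: y* = Py, X* = PX, M* = PM.

    Individual identifiers are dropped; marker identifiers and column order
    are preserved.  Output is always float64 — the rounding behaviour of the
    scheme (off-diagonal P'P entries ~1e-13) presumes double precision.
    """
    if key.n != dataset.n:
        raise InvalidArgumentError(
            f"key size {key.n} does not match dataset size {dataset.n}"
        )
    key.validate()
    p = key.matrix
    return CipherDataset(
        y_star=p @ dataset.y,
        X_star=p @ dataset.X,
        M_star=p @ dataset.M,
        marker_ids=list(dataset.marker_ids),
        block_sizes=key.block_sizes,
    )


def decrypt(cipher: CipherDataset, key: OrthogonalKey) -> PlainDataset:
    """Apply P' to the cyphertext.  With the correct key this recovers the
    plaintext up to ~1e-13-scale rounding; identifiers are not restored (they
    never entered the cyphertext — row labels are sequential integers)."""
    if key.n != cipher.n:
        raise InvalidArgumentError(
            f"key size {key.n} does not match cyphertext size {cipher.n}"
        )
    pt = key.inverse
    return PlainDataset(
        y=pt @ cipher.y_star,
        X=pt @ cipher.X_star,
        M=pt @ cipher.M_star,
        marker_ids=list(cipher.marker_ids),
    )


@dataclass(frozen=True)
class InvarianceReport:
    """Max-abs discrepancies of the cross products the sampler relies on."""

    mtm: float
    mty: float
    mtx: float
    yty: float
    tol: float

    @property
    def max_discrepancy(self) -> float:
        return max(self.mtm, self.mty, self.mtx, self.yty)

    @property
    def passed(self) -> bool:
        return self.max_discrepancy <= self.tol


def verify_invariance(
    plain: PlainDataset, cipher: CipherDataset, tol: float = 1e-8
) -> InvarianceReport:
    """Check that encryption preserved M'M, M'y, M'X and y'y within `tol`."""
    if plain.n != cipher.n or plain.p != cipher.p or plain.X.shape[1] != cipher.X_star.shape[1]:
        raise InvalidArgumentError("plaintext and cyphertext dimensions differ")
    m, ms = plain.M, cipher.M_star
    return InvarianceReport(
        mtm=float(np.max(np.abs(m.T @ m - ms.T @ ms))) if plain.p else 0.0,
        mty=float(np.max(np.abs(m.T @ plain.y - ms.T @ cipher.y_star))) if plain.p else 0.0,
        mtx=float(np.max(np.abs(m.T @ plain.X - ms.T @ cipher.X_star))) if plain.p else 0.0,
        yty=float(abs(plain.y @ plain.y - cipher.y_star @ cipher.y_star)),
        tol=float(tol),
    )
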