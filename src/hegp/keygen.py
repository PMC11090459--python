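"""Private-key generation for orthogonal-rotation encryption.

The encryption key is an n x n random orthogonal matrix P drawn from the Haar
measure on the orthogonal group (uniform over the Stiefel manifold), so that
the key is statistically independent of any data it will encrypt.  Sampling
follows the eigendecomposition route: draw B with i.i.d. standard-normal
entries and set

    P = B (B'B)^{-1/2} = B Q L^{-1/2} Q',     B'B = Q L Q'.

A sign flip of one row forces det(P) = +1 (Haar on SO(n)); orthogonality is
unaffected.  For large n, or for multi-party data, keys are assembled
block-diagonally from independently sampled blocks.

Keys are private.  They are persisted to a checksummed HDF5 container and
must never leave the data owner's custody.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from .exceptions import (
    CorruptKeyError,
    InvalidArgumentError,
    InvalidKeyError,
    UnsupportedFormatError,
)

__all__ = [
    "OrthogonalKey",
    "sample_key",
    "sample_block_key",
    "block_diagonal_key",
    "save_key",
    "load_key",
]

KEY_FILE_VERSION = 1

#: Tolerance used when a loaded key is re-checked for orthogonality.
LOAD_ORTHOGONALITY_TOL = 1e-8


@dataclass(frozen=True)
class OrthogonalKey:
    """A private orthogonal encryption key.

    Parameters
    ----------
    matrix
        The n x n orthogonal matrix P (float64).
    block_sizes
        Partition of n into diagonal blocks; ``(n,)`` for a monolithic key.
    seed
        RNG seed the key was generated from, if known (provenance only).
    det_corrected
        True if a row sign flip was applied to force det(P) = +1.
    """

    matrix: np.ndarray
    block_sizes: tuple[int, ...]
    seed: int | None = None
    det_corrected: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "block_sizes", tuple(int(b) for b in self.block_sizes))
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidArgumentError("key matrix must be square")
        if any(b <= 0 for b in self.block_sizes) or sum(self.block_sizes) != m.shape[0]:
            raise InvalidArgumentError(
                f"block_sizes {self.block_sizes} do not partition n={m.shape[0]}"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def orthogonality_error(self) -> float:
        """Max-abs entry of P'P - I, by direct multiplication."""
        ptp = self.matrix.T @ self.matrix
        return float(np.max(np.abs(ptp - np.eye(self.n))))

    def validate(self, tol: float = 1e-8) -> None:
        """Raise :class:`InvalidKeyError` if the matrix is not orthogonal to `tol`."""
        err = self.orthogonality_error()
        if not np.isfinite(err) or err > tol:
            raise InvalidKeyError(f"key fails orthogonality check: max|P'P - I| = {err:g}")

    @property
    def inverse(self) -> np.ndarray:
        """The decryption matrix P' (transpose equals inverse for orthogonal P)."""
        return self.matrix.T


def _haar_orthogonal(n: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """One Haar draw via the eigendecomposition of B'B; returns (P, det_corrected)."""
    for attempt in range(8):
        b = rng.standard_normal((n, n))
        btb = b.T @ b
        lam, q = np.linalg.eigh(btb)
        # B'B is a Wishart matrix: almost surely positive definite.  The clamp
        # guards the inverse square root against a pathological draw.
        if lam[0] / lam[-1] < 1e-12:
            warnings.warn(
                f"ill-conditioned B'B (ratio {lam[0] / lam[-1]:.2e}); "
                "key accuracy may be degraded",
                RuntimeWarning,
                stacklevel=3,
            )
        if lam[0] <= 0.0:
            warnings.warn(
                "numerically singular B'B draw; resampling with advanced stream",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        lam = np.clip(lam, 1e-300, None)
        p = b @ (q * (1.0 / np.sqrt(lam))) @ q.T
        # Newton-Schulz polar refinement: iterates toward the orthogonal polar
        # factor of B, which is exactly B(B'B)^{-1/2}.  Triggered only when an
        # ill-conditioned draw leaves the eigen route short of the ~1e-13
        # accuracy a well-conditioned draw attains.
        for _ in range(3):
            ptp = p.T @ p
            if np.max(np.abs(ptp - np.eye(n))) <= 1e-10:
                break
            p = 1.5 * p - 0.5 * (p @ ptp)
        sign, _ = np.linalg.slogdet(p)
        corrected = sign < 0
        if corrected:
            p[0, :] = -p[0, :]
        return p, corrected
    raise RuntimeError("could not draw a non-singular Gaussian matrix")  # pragma: no cover


def sample_key(n: int, seed: int | None = None) -> OrthogonalKey:
    """Sample an n x n Haar-distributed orthogonal key with det +1.

    Deterministic given `seed`.  Time scales as n^3 (one symmetric
    eigendecomposition); n = 3,534 takes on the order of a minute.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise InvalidArgumentError(f"n must be a positive integer, got {n!r}")
    rng = np.random.default_rng(seed)
    p, corrected = _haar_orthogonal(int(n), rng)
    return OrthogonalKey(p, (int(n),), seed=seed, det_corrected=corrected)


def sample_block_key(block_sizes: list[int] | tuple[int, ...], seed: int | None = None) -> OrthogonalKey:
    """Sample a block-diagonal key whose blocks come from independent substreams.

    Each block is itself a Haar draw; independent `SeedSequence` spawns make
    the blocks reproducible regardless of how many are generated or in what
    order.
    """
    sizes = [int(b) for b in block_sizes]
    if not sizes:
        raise InvalidArgumentError("block_sizes must be nonempty")
    if any(b < 1 for b in sizes):
        raise InvalidArgumentError(f"block sizes must be positive, got {sizes}")
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    keys = []
    for b, ss in zip(sizes, children):
        p, corrected = _haar_orthogonal(b, np.random.default_rng(ss))
        keys.append(OrthogonalKey(p, (b,), seed=None, det_corrected=corrected))
    out = block_diagonal_key(keys)
    return OrthogonalKey(out.matrix, out.block_sizes, seed=seed,
                         det_corrected=out.det_corrected)


def block_diagonal_key(keys: list[OrthogonalKey]) -> OrthogonalKey:
    """Assemble one key whose diagonal blocks are `keys`, in order.

    The result is orthogonal with det(P) = prod det(P_i) = +1, and its
    `block_sizes` records the partition (flattening any block structure the
    inputs themselves carried).
    """
    if not keys:
        raise InvalidArgumentError("need at least one key")
    sizes: list[int] = []
    for k in keys:
        sizes.extend(k.block_sizes)
    n = sum(sizes)
    m = np.zeros((n, n), dtype=np.float64)
    off = 0
    for k in keys:
        m[off : off + k.n, off : off + k.n] = k.matrix
        off += k.n
    return OrthogonalKey(
        m,
        tuple(sizes),
        seed=keys[0].seed if len(keys) == 1 else None,
        det_corrected=any(k.det_corrected for k in keys),
    )


def _checksum(matrix: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(matrix, dtype=np.float64).tobytes()).hexdigest()


def save_key(key: OrthogonalKey, path) -> None:
    """Persist a key to a versioned, checksummed HDF5 container.

    The float64 payload is stored row-major so that load restores it
    bit-exactly — a requirement for exact decryption.
    """
    warnings.warn(
        "encryption keys are private and must never be shared; "
        f"store {path} with the plaintext owner only",
        UserWarning,
        stacklevel=2,
    )
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "hegp-key"
        f.attrs["version"] = KEY_FILE_VERSION
        f.attrs["n"] = key.n
        f.attrs["seed"] = -1 if key.seed is None else int(key.seed)
        f.attrs["has_seed"] = key.seed is not None
        f.attrs["det_corrected"] = bool(key.det_corrected)
        f.attrs["checksum"] = _checksum(key.matrix)
        f.create_dataset("block_sizes", data=np.asarray(key.block_sizes, dtype=np.int64))
        f.create_dataset("matrix", data=np.ascontiguousarray(key.matrix, dtype=np.float64))


def load_key(path) -> OrthogonalKey:
    """Load a key, verifying checksum and orthogonality before returning it."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("version", -1))
        if version != KEY_FILE_VERSION:
            raise UnsupportedFormatError(
                f"unsupported key file version {version} (expected {KEY_FILE_VERSION})"
            )
        matrix = np.asarray(f["matrix"][...], dtype=np.float64)
        stored = str(f.attrs["checksum"])
        if _checksum(matrix) != stored:
            raise CorruptKeyError(f"checksum mismatch in key file {path}")
        seed = int(f.attrs["seed"]) if bool(f.attrs.get("has_seed", False)) else None
        key = OrthogonalKey(
            matrix,
            tuple(int(b) for b in f["block_sizes"][...]),
            seed=seed,
            det_corrected=bool(f.attrs.get("det_corrected", False)),
        )
    key.validate(LOAD_ORTHOGONALITY_TOL)
    return key
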