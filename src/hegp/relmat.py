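"""Marker- and individual-level relationship matrices and security diagnostics.

Orthogonal rotation preserves every dot product between marker columns, hence
the LD matrix (1/n)H'H is unchanged by encryption; the genomic relationship
matrix (1/p)HH' between individuals is conjugated to P G P' and thereby
scrambled.  The diagnostics here quantify both effects, plus the one known
leakage channel: rare/private variants, whose columns act like indicator
vectors and can expose columns of the key itself.

Genotypes are normalized VanRaden-style,

    H[i, j] = (M[i, j] - 2 p_j) / sqrt(2 p_j (1 - p_j)),

with p_j the allele frequency.  On the cyphertext path dosages are not
observable, so the caller supplies the plaintext-derived frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyResultError, InvalidArgumentError

__all__ = [
    "NormalizedGenotypes",
    "normalize",
    "ld_matrix",
    "grm",
    "plaintext_cipher_correlations",
    "CorrelationSummary",
    "risky_variant_screen",
]


@dataclass
class NormalizedGenotypes:
    """Frequency-normalized genotype matrix with per-marker frequencies."""

    H: np.ndarray
    allele_freqs: np.ndarray
    marker_ids: list[str] = field(default_factory=list)
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.H.shape[0]

    @property
    def p(self) -> int:
        return self.H.shape[1]


def normalize(
    M: np.ndarray,
    freqs: np.ndarray | None = None,
    marker_ids: list[str] | None = None,
    centered: bool = False,
) -> NormalizedGenotypes:
    """Normalize genotype columns by allele frequency.

    If `freqs` is omitted the frequencies are estimated from the dosages as
    column mean / 2 (plaintext path).  Cyphertext columns are real-valued
    rotations of dosages, so on that path the plaintext owner's frequencies
    must be passed in — using the same constants on both paths is what makes
    the two LD matrices comparable element by element.

    ``centered=True`` declares that the 2 p_j location shift has already been
    removed (column-centered plaintext, or the cyphertext of column-centered
    plaintext) and only the 1/sqrt(2 p_j (1-p_j)) rescaling is applied.  The
    shift does not commute with rotation, so encrypted data must be centered
    on the plaintext side and normalized with this flag.

    Markers with frequency 0 or 1 carry no variance and are dropped with a
    warning.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2:
        raise InvalidArgumentError("M must be 2-D")
    p = M.shape[1]
    ids = list(marker_ids) if marker_ids is not None else [f"m{j}" for j in range(p)]
    if len(ids) != p:
        raise InvalidArgumentError("marker_ids length mismatch")
    if freqs is None:
        freqs = M.mean(axis=0) / 2.0
    else:
        freqs = np.asarray(freqs, dtype=np.float64).reshape(-1)
        if freqs.shape[0] != p:
            raise InvalidArgumentError("freqs length mismatch")
    keep = (freqs > 0.0) & (freqs < 1.0)
    if not keep.any():
        raise EmptyResultError("all markers monomorphic after frequency screen")
    dropped = [ids[j] for j in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} monomorphic marker(s)", UserWarning, stacklevel=2
        )
    f = freqs[keep]
    shift = 0.0 if centered else 2.0 * f
    H = (M[:, keep] - shift) / np.sqrt(2.0 * f * (1.0 - f))
    return NormalizedGenotypes(
        H=H,
        allele_freqs=f,
        marker_ids=[ids[j] for j in np.flatnonzero(keep)],
        dropped_markers=dropped,
    )


def _as_h(H) -> np.ndarray:
    if isinstance(H, NormalizedGenotypes):
        return H.H
    return np.asarray(H, dtype=np.float64)


def ld_matrix(H: NormalizedGenotypes | np.ndarray) -> np.ndarray:
    """LD matrix (1/n) H'H — invariant under orthogonal encryption."""
    h = _as_h(H)
    n = h.shape[0]
    if n < 2:
        raise InvalidArgumentError("need at least 2 individuals for LD")
    ld = (h.T @ h) / n
    return 0.5 * (ld + ld.T)


def grm(H: NormalizedGenotypes | np.ndarray) -> np.ndarray:
    """Genomic relationship matrix (1/p) HH' — conjugated (scrambled) by encryption."""
    h = _as_h(H)
    p = h.shape[1]
    if p < 1:
        raise InvalidArgumentError("need at least 1 marker for a GRM")
    g = (h @ h.T) / p
    return 0.5 * (g + g.T)


@dataclass(frozen=True)
class CorrelationSummary:
    """Distribution of per-marker plaintext-vs-cyphertext Pearson correlations.

    Under a Haar key the correlations behave like those of independent random
    vectors, approximately N(0, 1/n); `frac_within` reports the share inside
    `interval` (default [-0.03, 0.03]).
    """

    correlations: np.ndarray
    mean: float
    sd: float
    frac_within: float
    interval: tuple[float, float]
    n_excluded: int

    @property
    def abs_mean(self) -> float:
        return abs(self.mean)


def plaintext_cipher_correlations(
    M: np.ndarray,
    M_star: np.ndarray,
    interval: tuple[float, float] = (-0.03, 0.03),
) -> CorrelationSummary:
    """Per-marker Pearson correlation between plaintext and cyphertext columns.

    Constant columns have undefined correlation; they are recorded as NaN and
    excluded from the summary statistics.
    """
    M = np.asarray(M, dtype=np.float64)
    M_star = np.asarray(M_star, dtype=np.float64)
    if M.shape != M_star.shape:
        raise InvalidArgumentError("M and M_star shapes differ")
    a = M - M.mean(axis=0)
    b = M_star - M_star.mean(axis=0)
    sa = np.sqrt((a * a).sum(axis=0))
    sb = np.sqrt((b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / (sa * sb)
    r[(sa == 0) | (sb == 0)] = np.nan
    ok = np.isfinite(r)
    if not ok.any():
        raise EmptyResultError("no non-constant marker columns")
    rv = r[ok]
    lo, hi = interval
    return CorrelationSummary(
        correlations=r,
        mean=float(rv.mean()),
        sd=float(rv.std(ddof=1)) if rv.size > 1 else 0.0,
        frac_within=float(((rv >= lo) & (rv <= hi)).mean()),
        interval=(float(lo), float(hi)),
        n_excluded=int((~ok).sum()),
    )


def risky_variant_screen(
    M: np.ndarray,
    marker_ids: list[str] | None = None,
    maf_min: float = 0.01,
    min_carriers: int = 10,
) -> list[str]:
    """Flag markers whose columns could leak key material; run BEFORE encrypting.

    A variant private to one individual makes its column an indicator vector:
    encrypting it publishes a column of P.  Markers with minor allele
    frequency below `maf_min` or carried (dosage > 0) by fewer than
    `min_carriers` individuals are flagged for removal.
    """
    M = np.asarray(M, dtype=np.float64)
    p = M.shape[1]
    ids = list(marker_ids) if marker_ids is not None else [f"m{j}" for j in range(p)]
    if len(ids) != p:
        raise InvalidArgumentError("marker_ids length mismatch")
    freq = M.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    carriers = (M > 0).sum(axis=0)
    flagged = (maf < maf_min) | (carriers < min_carriers)
    return [ids[j] for j in np.flatnonzero(flagged)]
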