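"""Window-based local genetic variance and WPPA from MCMC output.

Markers are grouped into consecutive, nonoverlapping index windows (about 20
SNPs each by convention).  For each retained draw s and window w the local
genetic variance is the quadratic form

    v_ws = g'g / (n - 1),   g = M_w alpha_w^(s),

with no mean subtraction: for column-centered M the statistic is essentially
the sample variance of the window's genetic values, and the quadratic form is
*exactly* invariant under orthogonal encryption because
(P M_w alpha)'(P M_w alpha) = (M_w alpha)'(M_w alpha).

The window posterior probability of association (WPPA) is the fraction of
draws in which a window explains more than a threshold share (default
1/n_windows) of the total genetic variance in that draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidArgumentError
from .wgr import PosteriorSamples

__all__ = ["make_windows", "window_variances", "wppa", "WindowResult"]


def make_windows(p: int, window_size: int = 20) -> list[tuple[int, int]]:
    """Consecutive half-open index windows [start, stop) covering 0..p-1.

    The final window holds the remainder (1..window_size markers); the count
    is ceil(p / window_size).
    """
    if p < 1 or window_size < 1:
        raise InvalidArgumentError("p and window_size must be positive")
    return [(s, min(s + window_size, p)) for s in range(0, p, window_size)]


@dataclass
class WindowResult:
    """Per-window genetic-variance draws and association probabilities."""

    windows: list[tuple[int, int]]
    variance_samples: np.ndarray  # draws x n_windows
    wppa: np.ndarray | None = None
    threshold_spec: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def mean_variance(self) -> np.ndarray:
        return self.variance_samples.mean(axis=0)


def _validate_windows(windows: list[tuple[int, int]], p: int) -> None:
    pos = 0
    for start, stop in windows:
        if start != pos or stop <= start:
            raise InvalidArgumentError(
                f"windows must partition 0..{p - 1} consecutively; "
                f"got [{start},{stop}) at position {pos}"
            )
        pos = stop
    if pos != p:
        raise InvalidArgumentError(f"windows cover 0..{pos - 1}, expected 0..{p - 1}")


def window_variances(
    M: np.ndarray,
    samples: PosteriorSamples | np.ndarray,
    windows: list[tuple[int, int]],
    *,
    check_centering: bool = True,
) -> WindowResult:
    """Local genetic variance per window per retained draw.

    `M` must be the column-centered genotype matrix (plaintext path) or its
    encryption (cyphertext path).  Centering is verified on the plaintext
    path; an encrypted matrix of centered columns is generally not itself
    column-centered, so cyphertext callers pass ``check_centering=False``.
    The statistic is identical either way — that is the invariance.
    """
    M = np.asarray(M, dtype=np.float64)
    alpha = samples.alpha if isinstance(samples, PosteriorSamples) else np.asarray(samples, dtype=np.float64)
    if alpha.ndim != 2 or alpha.shape[1] != M.shape[1]:
        raise InvalidArgumentError("alpha draws must be (n_draws, p) matching M")
    n, p = M.shape
    _validate_windows(windows, p)
    if check_centering:
        worst = float(np.max(np.abs(M.mean(axis=0)))) if p else 0.0
        if worst > 1e-6:
            raise InvalidArgumentError(
                f"M is not column-centered (max |column mean| = {worst:.2e}); "
                "center genotypes first, or pass check_centering=False for "
                "cyphertext input"
            )
    n_draws = alpha.shape[0]
    out = np.empty((n_draws, len(windows)))
    denom = max(n - 1, 1)
    for w, (start, stop) in enumerate(windows):
        g = M[:, start:stop] @ alpha[:, start:stop].T  # n x draws
        out[:, w] = np.einsum("ij,ij->j", g, g) / denom
    return WindowResult(windows=list(windows), variance_samples=out)


def wppa(result: WindowResult, proportion_threshold: float | None = None) -> np.ndarray:
    """Window posterior probability of association.

    WPPA_w = Pr( v_w > t * sum_w' v_w' ) over retained draws, with
    t = `proportion_threshold` (default 1/n_windows: the window explains more
    than its equal share of the genetic variance).  Monotone nonincreasing in
    the threshold.  The result is also stored on `result`.
    """
    v = result.variance_samples
    if v.size == 0:
        raise InvalidArgumentError("no variance samples")
    t = 1.0 / result.n_windows if proportion_threshold is None else float(proportion_threshold)
    if t < 0:
        raise InvalidArgumentError("proportion_threshold must be nonnegative")
    total = v.sum(axis=1, keepdims=True)
    probs = (v > t * total).mean(axis=0)
    result.wppa = probs
    result.threshold_spec = {"rule": "share_of_total_genetic_variance", "threshold": t}
    return probs
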