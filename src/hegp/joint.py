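"""Joint analysis of independently encrypted contributions.

Each contributor centers its own genotypes, samples its own private key P_t,
and shares only the cyphertext (y_t*, X_t*, M_t*).  Row-stacking the
cyphertexts equals encrypting the stacked plaintexts with the block-diagonal
orthogonal key diag(P_1, ..., P_T), so every invariance that holds for a
single key carries over to the merged data and one ordinary fit on the
merged cyphertext reproduces the joint plaintext analysis.

The merged model assumes variance components are shared across parties;
heterogeneous variances are refused explicitly, not silently absorbed.
Marker panels must match exactly (same ids, same order) — harmonization of
strand/allele coding is a pre-encryption responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crypt import CipherDataset, PlainDataset
from .exceptions import HarmonizationError, InvalidArgumentError
from .wgr import GibbsConfig, PosteriorSamples, ebv, fit

__all__ = ["Contribution", "merge", "joint_fit", "contributor_ebv"]


@dataclass
class Contribution:
    """One party's shareable cyphertext.  Holds no key material by construction."""

    cipher: CipherDataset
    contributor_tag: str
    centered_within: bool = True

    @property
    def n_t(self) -> int:
        return self.cipher.n

    @property
    def marker_ids(self) -> list[str]:
        return self.cipher.marker_ids


def merge(contributions: list[Contribution]) -> CipherDataset:
    """Row-stack contributions in order into one analysis-ready cyphertext.

    Equals encryption of the stacked plaintexts by the assembled
    block-diagonal key (verified in the test suite; production never forms
    the stacked key).  Block boundaries are recorded in ``block_sizes``.
    """
    if not contributions:
        raise InvalidArgumentError("need at least one contribution")
    ref = contributions[0]
    q = ref.cipher.X_star.shape[1]
    for c in contributions[1:]:
        if c.marker_ids != ref.marker_ids:
            bad = [
                (a, b)
                for a, b in zip(ref.marker_ids, c.marker_ids)
                if a != b
            ][:5]
            extra = set(c.marker_ids) ^ set(ref.marker_ids)
            raise HarmonizationError(
                f"marker panels differ between {ref.contributor_tag!r} and "
                f"{c.contributor_tag!r}: first mismatches {bad}, "
                f"symmetric difference size {len(extra)}"
            )
        if c.cipher.X_star.shape[1] != q:
            raise InvalidArgumentError("contributions have different covariate counts")
    return CipherDataset(
        y_star=np.concatenate([c.cipher.y_star for c in contributions]),
        X_star=np.vstack([c.cipher.X_star for c in contributions]),
        M_star=np.vstack([c.cipher.M_star for c in contributions]),
        marker_ids=list(ref.marker_ids),
        contributor_tag="+".join(c.contributor_tag for c in contributions),
        block_sizes=tuple(c.n_t for c in contributions),
    )


def joint_fit(merged: CipherDataset, config: GibbsConfig) -> PosteriorSamples:
    """Fit the merged cyphertext.  Marker-effect estimates are plaintext-
    interpretable and usable by every contributor for their own predictions."""
    return fit(merged, config)


def contributor_ebv(contribution_plain: PlainDataset, alpha_hat: np.ndarray) -> np.ndarray:
    """Breeding values for one contributor's own individuals, M_t alpha-hat.

    Only the party holding the plaintext genotypes can compute interpretable
    EBV — here from marker effects estimated on the combined data.
    """
    return ebv(contribution_plain.M, alpha_hat)
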