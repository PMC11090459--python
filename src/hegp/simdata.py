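"""Synthetic genotype/phenotype generator mirroring the validation study design.

Genotypes are binomial dosages built from two haplotypes per individual.
Linkage disequilibrium is induced by a first-order copying process: within a
block of ``ld_block_len`` markers, each haplotype copies its allele from the
previous locus with probability ``rho`` (default 0.9) and otherwise draws a
fresh Bernoulli(p_j) allele; blocks are independent, and ``ld_block_len=1``
gives fully independent markers.

Phenotypes follow the 16-scenario factorial used to validate the encryption
scheme: narrow-sense heritability h2 in {0.1, 0.3, 0.5, 0.7} crossed with
QTL fractions {1, 10, 50, 100}% of markers, with contemporary-group fixed
effects on individuals from 4 groups and 10 replicates per scenario.  QTL
effects are i.i.d. standard normal; the genetic values u = M_qtl alpha_qtl
are rescaled so the realized sample variance of u equals h2 exactly (with
residuals N(0, 1 - h2), phenotypic variance is ~1 and realized heritability
is sharp per replicate, which tightens recovery tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .crypt import PlainDataset
from .exceptions import InvalidArgumentError

__all__ = [
    "SimScenario",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "scenario_grid",
    "H2_LEVELS",
    "QTL_PROPS",
]

H2_LEVELS = (0.1, 0.3, 0.5, 0.7)
QTL_PROPS = (0.01, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class SimScenario:
    """One simulation condition.

    ``maf_range`` bounds the per-marker allele frequency (drawn uniformly);
    ``ld_block_len``/``rho`` control the haplotype-copying LD process.
    """

    n: int = 1000
    p: int = 2000
    h2: float = 0.5
    qtl_prop: float = 0.1
    n_groups: int = 4
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_len: int = 1
    rho: float = 0.9
    group_effect_var: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1:
            raise InvalidArgumentError("n and p must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise InvalidArgumentError("h2 must be in [0, 1]")
        if not 0.0 < self.qtl_prop <= 1.0:
            raise InvalidArgumentError("qtl_prop must be in (0, 1]")
        if self.n_groups < 1:
            raise InvalidArgumentError("n_groups must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidArgumentError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.ld_block_len < 1:
            raise InvalidArgumentError("ld_block_len must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise InvalidArgumentError("rho must be in [0, 1)")


@dataclass
class SimTruth:
    """Simulated phenotypes plus every generating quantity, for recovery tests."""

    y: np.ndarray
    X: np.ndarray
    beta: np.ndarray
    alpha: np.ndarray        # length p, zero off-QTL
    u: np.ndarray            # genetic values, sample variance = h2 exactly
    e: np.ndarray
    qtl_indices: np.ndarray
    group_assignments: np.ndarray

    @property
    def realized_h2(self) -> float:
        vu = float(np.var(self.u, ddof=1))
        ve = float(np.var(self.e, ddof=1))
        return vu / (vu + ve) if vu + ve > 0 else 0.0


def simulate_genotypes(scenario: SimScenario) -> tuple[np.ndarray, np.ndarray]:
    """Dosage matrix (n x p, values 0/1/2) and the target allele frequencies."""
    rng = np.random.default_rng(scenario.seed)
    n, p = scenario.n, scenario.p
    lo, hi = scenario.maf_range
    freqs = rng.uniform(lo, hi, size=p)
    haps = np.empty((n, 2, p), dtype=np.int8)
    for j in range(p):
        fresh = rng.random((n, 2)) < freqs[j]
        if scenario.ld_block_len > 1 and j % scenario.ld_block_len != 0:
            copy = rng.random((n, 2)) < scenario.rho
            haps[:, :, j] = np.where(copy, haps[:, :, j - 1], fresh)
        else:
            haps[:, :, j] = fresh
    M = haps.sum(axis=1).astype(np.float64)
    return M, freqs


def simulate_phenotypes(M: np.ndarray, scenario: SimScenario) -> SimTruth:
    """Simulate phenotypes y = X beta + u + e on the given dosage matrix.

    Uses an independent substream of the scenario seed so phenotype
    replicates can share genotypes.  Group effects are N(0, group_effect_var)
    on the phenotypic scale; X carries an intercept plus treatment-coded
    group indicators (full rank).
    """
    M = np.asarray(M, dtype=np.float64)
    n, p = M.shape
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(2)[1])
    Mc = M - M.mean(axis=0)

    n_qtl = int(round(scenario.qtl_prop * p))
    if n_qtl == 0:
        warnings.warn("qtl_prop rounds to 0 QTL; forcing 1", UserWarning, stacklevel=2)
        n_qtl = 1
    qtl = np.sort(rng.choice(p, size=n_qtl, replace=False))
    alpha = np.zeros(p)
    alpha[qtl] = rng.standard_normal(n_qtl)

    u = Mc @ alpha
    vu = float(np.var(u, ddof=1))
    if scenario.h2 > 0 and vu > 0:
        scale = np.sqrt(scenario.h2 / vu)
        alpha *= scale
        u = u * scale
    else:
        alpha[:] = 0.0
        u = np.zeros(n)
    e = rng.standard_normal(n) * np.sqrt(max(1.0 - scenario.h2, 0.0))

    groups = rng.permutation(np.arange(n) % scenario.n_groups)
    g_eff = rng.standard_normal(scenario.n_groups) * np.sqrt(scenario.group_effect_var)
    X = np.ones((n, scenario.n_groups))
    # treatment coding: intercept = group 0 effect, columns k>=1 are offsets
    beta = np.empty(scenario.n_groups)
    beta[0] = g_eff[0]
    for k in range(1, scenario.n_groups):
        X[:, k] = (groups == k).astype(np.float64)
        beta[k] = g_eff[k] - g_eff[0]
    y = X @ beta + u + e
    return SimTruth(
        y=y, X=X, beta=beta, alpha=alpha, u=u, e=e,
        qtl_indices=qtl, group_assignments=groups,
    )


def simulate_dataset(scenario: SimScenario, center: bool = True) -> tuple[PlainDataset, SimTruth]:
    """Genotypes + phenotypes bundled as a ready-to-encrypt PlainDataset."""
    M, _ = simulate_genotypes(scenario)
    truth = simulate_phenotypes(M, scenario)
    ds = PlainDataset(y=truth.y, X=truth.X, M=M)
    if center:
        from .crypt import center_genotypes

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ds = center_genotypes(ds)
    return ds, truth


def scenario_grid(
    n: int = 1000,
    p: int = 2000,
    replicates: int = 1,
    base_seed: int = 0,
    **overrides,
) -> list[SimScenario]:
    """Full factorial of h2 x QTL-fraction conditions (16 scenarios).

    With ``replicates`` > 1 each condition is repeated with distinct seeds
    (16 x replicates scenarios; the study design used 10 replicates).
    """
    if replicates < 1:
        raise InvalidArgumentError("replicates must be >= 1")
    out = []
    idx = 0
    for h2 in H2_LEVELS:
        for qp in QTL_PROPS:
            for _ in range(replicates):
                out.append(
                    SimScenario(
                        n=n, p=p, h2=h2, qtl_prop=qp,
                        seed=base_seed + idx, **overrides,
                    )
                )
                idx += 1
    return out
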