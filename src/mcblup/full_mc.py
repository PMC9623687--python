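"""Full Monte Carlo SNP-BLUP reliability approximation.

Instead of fitting one effect per marker plus one residual polygenic (RPG)
effect per animal, the genetic part of the model is replaced by a regression
on ``n_mc`` simulated columns,

    y = 1 mu + U s + e,        s ~ N(0, I sigma_u^2),

where column ``i`` of ``U`` is ``(Zc g_i + a_i)/sqrt(n_mc)`` with marker
draws ``g_i ~ N(0, (1-w) I)`` and polygenic draws ``a_i = sqrt(w) L z_i``,
``z_i ~ N(0, I)``.  Each column is then a draw from ``N(0, G_w / n_mc)``, so
``E[U U'] = G_w`` and the mixed model equations shrink to order
``1 + n_mc`` regardless of the number of markers or animals.  Prediction
error variances come from the quadratic form ``PEV_j = t_j C_uss t_j'``
with ``t_j`` the j-th row of ``U`` and ``C_uss`` the genetic block of the
inverse coefficient matrix.

When ``n_mc`` greatly exceeds the number of genotyped animals ``n`` the
same quadratic forms are computed through an algebraically identical rank
reduction that only ever factorises ``n x n`` matrices (see
``full_mc_reliability_pipeline``); the direct route materialises the
``(1 + n_mc)``-order system exactly as written above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg

from .exact_models import (
    ModelParams,
    PhenotypeData,
    ReliabilityResult,
    _mme_coefficient,
    _sym_inverse,
)
from .genotypes import BlendedRelationship, CenteredGenotypeMatrix
from .pedigree import CholeskyFactor, InbreedingVector

logger = logging.getLogger(__name__)

#: above this many MC samples the pipeline switches to the reduced solver
REDUCED_ENGINE_THRESHOLD = 3000


@dataclass(frozen=True)
class MCSampleMatrix:
    """``n x n_mc`` matrix of simulated genetic-effect columns.

    Columns carry the 1/sqrt(n_mc) factor (``column_scaled``), so the
    cross-product ``U U'`` is the Monte Carlo estimate of ``G_w`` itself.
    """

    ids: tuple[str, ...]
    U: np.ndarray
    n_mc: int
    seed: int | None
    w: float
    column_scaled: bool = True

    def __post_init__(self) -> None:
        if self.U.shape != (len(self.ids), self.n_mc):
            raise ValueError("U shape does not match (n animals, n_mc)")


@dataclass(frozen=True)
class MMESystem:
    """Symmetric coefficient matrix of the full-MC mixed model equations."""

    C: np.ndarray
    rhs: np.ndarray | None
    lambda_: float

    @property
    def order(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class PEVBlock:
    """Genetic (``n_mc x n_mc``) block of the inverse MME coefficient matrix."""

    C_uss: np.ndarray


def column_normals(n_rows: int, n_cols: int, seed: int, stream: int = 0) -> np.ndarray:
    """Standard normals with one RNG substream per column.

    Column ``i`` is drawn from ``SeedSequence(seed, spawn_key=(stream, i))``,
    so the values of a column do not depend on how many other columns are
    generated or in what order.
    """
    out = np.empty((n_rows, n_cols))
    for i in range(n_cols):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, i)))
        out[:, i] = rng.standard_normal(n_rows)
    return out


def sample_U(Zc: CenteredGenotypeMatrix, L: CholeskyFactor, w: float,
             n_mc: int, seed: int) -> MCSampleMatrix:
    """Sample the MC regression matrix ``U`` (columns scaled by 1/sqrt(n_mc)).

    Column ``i`` uses a single per-column substream for both the marker draw
    ``g_i ~ N(0, (1-w) I_m)`` and the polygenic draw ``z_i ~ N(0, I_n)``.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"RPG proportion w must be in [0, 1], got {w}")
    if n_mc < 1:
        raise ValueError("n_mc must be at least 1")
    if Zc.ids != tuple(L.ids):
        raise ValueError("animal order of Zc and L differ")
    n = len(Zc.ids)
    m = Zc.Zc.shape[1]
    G = np.empty((m, n_mc))
    Zstd = np.empty((n, n_mc))
    for i in range(n_mc):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        v = rng.standard_normal(m + n)
        G[:, i] = v[:m]
        Zstd[:, i] = v[m:]
    U = (np.sqrt(1.0 - w) * (Zc.Zc @ G) + np.sqrt(w) * (L.values @ Zstd)) / np.sqrt(n_mc)
    return MCSampleMatrix(Zc.ids, U, n_mc, seed, w)


def deterministic_U_from_cholesky(Gw: BlendedRelationship) -> MCSampleMatrix:
    """Exact-covariance oracle hook: ``U = chol(Gw)`` so ``U U' = Gw`` exactly.

    Substituting this ``U`` makes the full-MC model identical to GBLUP, which
    validates the MME assembly, block inversion and reliability formula
    end-to-end without Monte Carlo noise.
    """
    try:
        Uchol = np.linalg.cholesky(Gw.Gw)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("Gw is not positive definite") from exc
    n = len(Gw.ids)
    return MCSampleMatrix(Gw.ids, Uchol, n, None, Gw.w)


def build_full_mc_mme(U: MCSampleMatrix, pheno: PhenotypeData,
                      params: ModelParams) -> MMESystem:
    """Assemble the order ``1 + n_mc`` coefficient matrix and right-hand side."""
    if tuple(pheno.ids) != U.ids:
        pheno = pheno.reorder(U.ids)
    lam = params.lambda_
    C = _mme_coefficient(U.U, pheno.weights, lam)
    wy = pheno.weights * pheno.y
    rhs = np.concatenate([[wy.sum()], U.U.T @ wy])
    return MMESystem(C, rhs, lam)


def solve_pev_block(mme: MMESystem) -> PEVBlock:
    """Genetic block of the inverse coefficient matrix.

    Computed as the inverse of the Schur complement of the mean equation,
    via symmetric (Cholesky) factorisation.
    """
    a = mme.C[0, 0]
    c = mme.C[1:, 0]
    S = mme.C[1:, 1:] - np.outer(c, c) / a
    try:
        C_uss = _sym_inverse(S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("full-MC MME factorisation failed") from exc
    return PEVBlock(C_uss)


def animal_variance(U: MCSampleMatrix | None = None,
                    Zc: CenteredGenotypeMatrix | None = None,
                    inbreeding: InbreedingVector | None = None,
                    w: float | None = None,
                    mode: str = "mc",
                    convention: str = "a22-diagonal") -> np.ndarray:
    """Per-animal genetic variance ``sigma_j^2`` on the relationship scale.

    ``mode="mc"`` takes the diagonal of ``U U'`` (computed as row norms,
    never materialising the full matrix); ``mode="exact"`` uses
    ``(1-w)(Zc Zc')_jj + w (1 + F_j)``, the actual ``G_w`` diagonal.  The
    ``convention="paper-literal"`` switch replaces ``1 + F_j`` by ``1 - F_j``.
    """
    if mode == "mc":
        if U is None:
            raise ValueError("mode 'mc' requires the MC sample matrix U")
        sigma = (U.U ** 2).sum(axis=1)
    elif mode == "exact":
        if Zc is None or inbreeding is None or w is None:
            raise ValueError("mode 'exact' requires Zc, inbreeding and w")
        if Zc.ids != tuple(inbreeding.ids):
            raise ValueError("animal order of Zc and inbreeding vector differ")
        if convention == "a22-diagonal":
            a_diag = 1.0 + inbreeding.F
        elif convention == "paper-literal":
            a_diag = 1.0 - inbreeding.F
        else:
            raise ValueError(f"unknown convention {convention!r}")
        sigma = (1.0 - w) * (Zc.Zc ** 2).sum(axis=1) + w * a_diag
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if (sigma <= 0).any():
        j = int(np.flatnonzero(sigma <= 0)[0])
        raise ValueError(f"nonpositive genetic variance for animal index {j}")
    return sigma


def full_mc_reliability(U: MCSampleMatrix, pev: PEVBlock, sigma_j2: np.ndarray,
                        params: ModelParams, ids: Sequence[str] | None = None) -> ReliabilityResult:
    """Reliabilities from the PEV quadratic forms ``t_j C_uss t_j'``.

    The product is evaluated in two steps from left to right for every
    animal; the ``n x n`` matrix ``U C_uss U'`` is never materialised.
    Raw values are stored: approximate reliabilities may fall outside [0, 1].
    """
    if len(sigma_j2) != len(U.ids):
        raise ValueError("sigma_j2 length does not match number of animals")
    lam = params.lambda_
    H = U.U @ pev.C_uss            # step 1: t_j C_uss for all animals
    pev_j = np.einsum("ij,ij->i", H, U.U)  # step 2: ... t_j'
    r2 = 1.0 - lam * pev_j / sigma_j2
    return ReliabilityResult(tuple(ids) if ids is not None else U.ids,
                             pev_j, np.asarray(sigma_j2, dtype=float), r2, "full_mc")


def _reduced_pev(Umat: np.ndarray, weights: np.ndarray, lam: float) -> np.ndarray:
    """PEV quadratic forms via an n x n rank reduction (exact algebra).

    With ``M = R^-1 - R^-1 1 1' R^-1 / (1'R^-1 1)`` the mean equation is
    absorbed and ``C_uss = (lam I + U'MU)^-1``.  Writing ``M = K K'`` with
    ``K = R^-1/2 (I - uu')`` and applying the push-through identity,

        U C_uss U' = [P - P K (lam I + K'PK)^-1 K'P] / lam,   P = U U',

    so only ``n x n`` systems are ever factorised.  Identical (to rounding)
    to the direct route through the order ``1 + n_mc`` equations.
    """
    n = Umat.shape[0]
    P = Umat @ Umat.T
    dh = np.sqrt(weights)
    u = dh / np.linalg.norm(dh)
    K = dh[:, None] * (np.eye(n) - np.outer(u, u))
    PK = P @ K
    S = lam * np.eye(n) + K.T @ PK
    cf = linalg.cho_factor(S, lower=True, check_finite=False)
    X = linalg.cho_solve(cf, PK.T, check_finite=False)
    return (np.diag(P) - np.einsum("ij,ji->i", PK, X)) / lam


def full_mc_reliability_pipeline(U: MCSampleMatrix, pheno: PhenotypeData,
                                 params: ModelParams,
                                 sigma_j2: np.ndarray | None = None,
                                 engine: str = "auto") -> ReliabilityResult:
    """End-to-end full-MC reliabilities from a sampled ``U``.

    ``engine="direct"`` assembles and factorises the order ``1 + n_mc``
    system; ``engine="reduced"`` uses the algebraically identical n x n
    reduction, preferable when ``n_mc >> n``; ``"auto"`` picks by size.
    """
    if tuple(pheno.ids) != U.ids:
        pheno = pheno.reorder(U.ids)
    if sigma_j2 is None:
        sigma_j2 = animal_variance(U=U, mode="mc")
    if engine == "auto":
        engine = "reduced" if U.n_mc > REDUCED_ENGINE_THRESHOLD else "direct"
    if engine == "direct":
        mme = build_full_mc_mme(U, pheno, params)
        block = solve_pev_block(mme)
        return full_mc_reliability(U, block, sigma_j2, params)
    if engine == "reduced":
        lam = params.lambda_
        pev_j = _reduced_pev(U.U, pheno.weights, lam)
        r2 = 1.0 - lam * pev_j / sigma_j2
        return ReliabilityResult(U.ids, pev_j, np.asarray(sigma_j2, dtype=float),
                                 r2, "full_mc")
    raise ValueError(f"unknown engine {engine!r}")
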