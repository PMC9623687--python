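"""Exact reliability models: GBLUP and SNP-BLUP with a residual polygenic term.

Both fit a single-record animal model with an overall mean,

    y = 1 mu + genetic + e,      e ~ N(0, R sigma_e^2),  R_ii = 1/w_i,

and differ only in how the genetic term is parameterised: GBLUP puts an
animal effect with covariance ``G_w sigma_u^2`` directly in the equations,
while SNP-BLUP regresses on ``Z = [sqrt(1-w) Zc, sqrt(w) L]`` with i.i.d.
effects.  The two are equivalent and yield identical prediction error
variances, which makes GBLUP the gold standard that the Monte Carlo
approximations are judged against.  Reliability of animal ``j`` is

    r_j^2 = 1 - lambda * PEV_j / sigma_j^2,      lambda = sigma_e^2 / sigma_u^2,

with ``PEV_j`` on the lambda-scaled (inverse-coefficient-matrix) scale and
``sigma_j^2`` the relationship-matrix diagonal for that animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .genotypes import BlendedRelationship, CenteredGenotypeMatrix
from .pedigree import JITTER_LADDER, CholeskyFactor


@dataclass(frozen=True)
class PhenotypeData:
    """One record per genotyped animal, with optional per-record weights."""

    ids: tuple[str, ...]
    y: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.shape != (len(self.ids),):
            raise ValueError("phenotype vector length does not match ids")
        w = self.weights
        w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weight vector length does not match ids")
        if (w <= 0).any():
            raise ValueError("record weights must be strictly positive")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "weights", w)

    def reorder(self, ids: Sequence[str]) -> "PhenotypeData":
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            idx = np.array([pos[a] for a in ids])
        except KeyError as exc:
            raise KeyError(f"no phenotype record for animal {exc.args[0]!r}") from None
        return PhenotypeData(tuple(ids), self.y[idx], self.weights[idx])


@dataclass(frozen=True)
class ModelParams:
    """Variance components: total genetic sigma_u^2, residual sigma_e^2, RPG w."""

    w: float
    sigma_u2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"RPG proportion w must be in [0, 1], got {self.w}")
        if self.sigma_u2 <= 0 or self.sigma_e2 <= 0:
            raise ValueError("variance components must be strictly positive")

    @property
    def lambda_(self) -> float:
        """Shrinkage ratio lambda = sigma_e^2 / sigma_u^2."""
        return self.sigma_e2 / self.sigma_u2

    @classmethod
    def from_heritability(cls, h2: float, w: float) -> "ModelParams":
        """Unit phenotypic variance: sigma_u^2 = h^2, sigma_e^2 = 1 - h^2."""
        if not 0.0 < h2 < 1.0:
            raise ValueError(f"heritability must be in (0, 1), got {h2}")
        return cls(w=w, sigma_u2=h2, sigma_e2=1.0 - h2)

    @classmethod
    def from_lambda(cls, lam: float, w: float) -> "ModelParams":
        if lam <= 0:
            raise ValueError(f"lambda must be positive, got {lam}")
        return cls(w=w, sigma_u2=1.0, sigma_e2=lam)


@dataclass(frozen=True)
class ReliabilityResult:
    """Per-animal PEV, genetic variance and reliability from one model path."""

    ids: tuple[str, ...]
    pev: np.ndarray
    sigma_j2: np.ndarray
    r2: np.ndarray
    model_tag: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "animal": self.ids,
            "pev": self.pev,
            "sigma_j2": self.sigma_j2,
            "r2": self.r2,
            "model": self.model_tag,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReliabilityResult":
        df = pd.read_csv(path, dtype={"animal": str})
        tags = df["model"].unique()
        return cls(tuple(df["animal"]), df["pev"].to_numpy(),
                   df["sigma_j2"].to_numpy(), df["r2"].to_numpy(),
                   model_tag=str(tags[0]) if len(tags) == 1 else "mixed")


def read_phenotypes(path: str | Path) -> PhenotypeData:
    """Read animal,value[,weight] CSV; header optional; weights default to 1."""
    df = pd.read_csv(path, header=None, dtype=str, sep=None, engine="python",
                     comment="#", skip_blank_lines=True)
    first = str(df.iloc[0, 1]).strip()
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    ids = tuple(str(a).strip() for a in df.iloc[:, 0])
    y = df.iloc[:, 1].astype(float).to_numpy()
    weights = df.iloc[:, 2].astype(float).to_numpy() if df.shape[1] > 2 else None
    return PhenotypeData(ids, y, weights)


def _sym_inverse(C: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric PD matrix via Cholesky."""
    try:
        cf = linalg.cho_factor(C, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "mixed model equations are singular; check lambda and relationship "
            "matrix conditioning (jitter may be needed)"
        ) from exc
    return linalg.cho_solve(cf, np.eye(C.shape[0]), check_finite=False)


def _pd_inverse_with_jitter(M: np.ndarray, jitter: Sequence[float] = JITTER_LADDER) -> np.ndarray:
    for jit in jitter:
        try:
            cf = linalg.cho_factor(M + jit * np.eye(M.shape[0]), lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            continue
        return linalg.cho_solve(cf, np.eye(M.shape[0]), check_finite=False)
    raise np.linalg.LinAlgError("relationship matrix not invertible within the jitter ladder")


def _mme_coefficient(Z: np.ndarray, weights: np.ndarray, lam: float) -> np.ndarray:
    """[[1'R^-1 1, 1'R^-1 Z], [Z'R^-1 1, Z'R^-1 Z + lambda I]] with R^-1 = diag(weights)."""
    q = Z.shape[1]
    C = np.empty((1 + q, 1 + q))
    C[0, 0] = weights.sum()
    C[0, 1:] = weights @ Z
    C[1:, 0] = C[0, 1:]
    C[1:, 1:] = (Z.T * weights) @ Z + lam * np.eye(q)
    return C


def _random_regression_reliability(Z: np.ndarray, sigma_j2: np.ndarray,
                                   pheno: PhenotypeData, params: ModelParams,
                                   model_tag: str) -> ReliabilityResult:
    lam = params.lambda_
    C = _mme_coefficient(Z, pheno.weights, lam)
    Cinv = _sym_inverse(C)
    Cgg = Cinv[1:, 1:]
    pev = np.einsum("ij,jk,ik->i", Z, Cgg, Z)
    r2 = 1.0 - lam * pev / sigma_j2
    return ReliabilityResult(pheno.ids, pev, sigma_j2, r2, model_tag)


def gblup_reliability(Gw: BlendedRelationship, pheno: PhenotypeData,
                      params: ModelParams) -> ReliabilityResult:
    """Exact animal-model reliabilities from the GBLUP mixed model equations.

    The coefficient matrix is ``[[1'R^-1 1, 1'R^-1], [R^-1 1, R^-1 + Gw^-1 lambda]]``;
    ``PEV_j`` is the j-th diagonal of the animal block of its inverse and
    ``sigma_j^2 = (Gw)_jj``.
    """
    if tuple(pheno.ids) != tuple(Gw.ids):
        pheno = pheno.reorder(Gw.ids)
    lam = params.lambda_
    n = len(Gw.ids)
    Gw_inv = _pd_inverse_with_jitter(Gw.Gw)
    C = np.empty((1 + n, 1 + n))
    C[0, 0] = pheno.weights.sum()
    C[0, 1:] = pheno.weights
    C[1:, 0] = pheno.weights
    C[1:, 1:] = np.diag(pheno.weights) + lam * Gw_inv
    Cinv = _sym_inverse(C)
    pev = np.diag(Cinv)[1:].copy()
    sigma_j2 = np.diag(Gw.Gw).copy()
    r2 = 1.0 - lam * pev / sigma_j2
    return ReliabilityResult(Gw.ids, pev, sigma_j2, r2, "gblup")


def snpblup_exact_reliability(Zc: CenteredGenotypeMatrix, L: CholeskyFactor,
                              pheno: PhenotypeData, params: ModelParams) -> ReliabilityResult:
    """Exact SNP-BLUP-with-RPG reliabilities (equivalent to GBLUP).

    Fits ``y = 1 mu + Z g_R + e`` with ``Z = [sqrt(1-w) Zc, sqrt(w) L]`` and
    i.i.d. genetic effects; ``PEV_j = z_j C_gg z_j'`` from the genetic block
    of the inverse coefficient matrix, ``sigma_j^2 = (Z Z')_jj``.
    """
    if Zc.ids != tuple(L.ids):
        raise ValueError("animal order of Zc and L differ")
    if tuple(pheno.ids) != Zc.ids:
        pheno = pheno.reorder(Zc.ids)
    w = params.w
    Z = np.hstack([np.sqrt(1.0 - w) * Zc.Zc, np.sqrt(w) * L.values])
    sigma_j2 = (Z ** 2).sum(axis=1)
    return _random_regression_reliability(Z, sigma_j2, pheno, params, "snpblup")


def mc_rpg_snpblup_reliability(Zc: CenteredGenotypeMatrix, L: CholeskyFactor,
                               pheno: PhenotypeData, params: ModelParams,
                               n_mc: int, seed: int,
                               z_columns: np.ndarray | None = None) -> ReliabilityResult:
    """The earlier MC-SNP-BLUP: exact marker effects, Monte Carlo RPG only.

    The ``n`` RPG equations are replaced by ``n_mc`` regression columns
    ``sqrt(w) L z_i / sqrt(n_mc)`` with standard-normal ``z_i``, so the
    coefficient matrix has order ``1 + m + n_mc``.  ``z_columns`` is a
    deterministic test hook replacing the sampled standard normals.
    """
    from .full_mc import column_normals  # deferred: full_mc owns the sampler

    if n_mc < 1:
        raise ValueError("n_mc must be at least 1")
    if Zc.ids != tuple(L.ids):
        raise ValueError("animal order of Zc and L differ")
    if tuple(pheno.ids) != Zc.ids:
        pheno = pheno.reorder(Zc.ids)
    n = len(Zc.ids)
    if z_columns is None:
        z_columns = column_normals(n, n_mc, seed, stream=1)
    elif z_columns.shape != (n, n_mc):
        raise ValueError("z_columns must have shape (n, n_mc)")
    w = params.w
    U_rpg = np.sqrt(w) * (L.values @ z_columns) / np.sqrt(n_mc)
    Z = np.hstack([np.sqrt(1.0 - w) * Zc.Zc, U_rpg])
    sigma_j2 = (1.0 - w) * (Zc.Zc ** 2).sum(axis=1) + (U_rpg ** 2).sum(axis=1)
    return _random_regression_reliability(Z, sigma_j2, pheno, params, "mc_rpg")
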