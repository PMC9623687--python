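"""Comparison statistics between exact and approximate reliabilities.

An unbiased approximation gives correlation 1, zero maximum difference and
mean squared error, and an exact-on-approximate regression with intercept 0
and slope 1; a slope above 1 means the approximation is inflated (too large)
for the low-reliability animals and the inflation shrinks as the slope moves
back toward 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exact_models import ModelParams, PhenotypeData, ReliabilityResult
from .full_mc import full_mc_reliability_pipeline, sample_U
from .genotypes import CenteredGenotypeMatrix, blended_relationship
from .pedigree import CholeskyFactor, RelationshipMatrix


@dataclass(frozen=True)
class ComparisonStats:
    """Agreement statistics between two reliability vectors on the same animals."""

    r: float          # Pearson correlation
    max_diff: float   # max |exact - approx|
    mse: float        # mean squared difference
    b0: float         # intercept of exact-on-approx OLS
    b1: float         # slope of exact-on-approx OLS
    n_animals: int

    @property
    def mse_e5(self) -> float:
        """MSE in display units of 1e-5."""
        return self.mse * 1e5


def compare_reliabilities(exact: ReliabilityResult, approx: ReliabilityResult) -> ComparisonStats:
    """Correlation, max difference, MSE and exact-on-approx OLS regression.

    The two results are joined on animal ID (approx is reordered to the
    exact ordering); the regression response is the exact reliability.
    """
    if set(exact.ids) != set(approx.ids):
        missing = set(exact.ids) ^ set(approx.ids)
        raise ValueError(f"animal sets differ; {len(missing)} unmatched ID(s), "
                         f"e.g. {sorted(missing)[:3]}")
    pos = {a: i for i, a in enumerate(approx.ids)}
    idx = np.array([pos[a] for a in exact.ids])
    y = np.asarray(exact.r2, dtype=float)
    x = np.asarray(approx.r2, dtype=float)[idx]
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 animals to compare reliabilities")
    if np.ptp(x) == 0:
        raise ValueError("approximate reliabilities have zero variance; regression undefined")
    fit = stats.linregress(x, y)
    diff = y - x
    return ComparisonStats(
        r=float(fit.rvalue),
        max_diff=float(np.abs(diff).max()),
        mse=float(np.mean(diff ** 2)),
        b0=float(fit.intercept),
        b1=float(fit.slope),
        n_animals=n,
    )


def reliability_sweep(Zc: CenteredGenotypeMatrix, L: CholeskyFactor,
                      pheno: PhenotypeData, h2: float,
                      w_values: Sequence[float], n_mc_values: Sequence[int],
                      seeds: Iterable[int], sigma_mode: str = "mc",
                      engine: str = "auto") -> pd.DataFrame:
    """Exact-vs-full-MC comparison grid, one row per (w, n_mc, seed).

    For each RPG proportion the exact GBLUP reliabilities are computed once,
    then full-MC runs at every MC sample count and sampling seed are scored
    against them.  Returns a table with columns
    ``w, n_mc, seed, r, max, mse, mse_e5, b0, b1``.
    """
    from .exact_models import gblup_reliability

    A22 = RelationshipMatrix(tuple(L.ids), L.values @ L.values.T)
    rows = []
    seeds = list(seeds)
    for w in w_values:
        params = ModelParams.from_heritability(h2, w)
        Gw = blended_relationship(Zc, A22, w)
        exact = gblup_reliability(Gw, pheno, params)
        for n_mc in n_mc_values:
            for seed in seeds:
                U = sample_U(Zc, L, w, n_mc, seed)
                if sigma_mode == "mc":
                    sigma_j2 = None
                elif sigma_mode == "exact":
                    # A22 diagonal is 1 + F, so no pedigree lookup is needed
                    sigma_j2 = (1.0 - w) * (Zc.Zc ** 2).sum(axis=1) + w * np.diag(A22.values)
                else:
                    raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
                approx = full_mc_reliability_pipeline(U, pheno, params,
                                                      sigma_j2=sigma_j2, engine=engine)
                st = compare_reliabilities(exact, approx)
                rows.append({"w": w, "n_mc": n_mc, "seed": seed, "r": st.r,
                             "max": st.max_diff, "mse": st.mse, "mse_e5": st.mse_e5,
                             "b0": st.b0, "b1": st.b1})
    return pd.DataFrame(rows)


def table1_summary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Average the sweep over seeds into one row per (n_mc, w)."""
    cols = ["r", "max", "mse_e5", "b0", "b1"]
    out = (sweep.groupby(["n_mc", "w"], as_index=False)[cols].mean()
           .sort_values(["n_mc", "w"], ignore_index=True))
    return out
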