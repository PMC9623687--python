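"""Marker genotypes, centering/scaling, and the blended relationship matrix.

The centered/scaled marker matrix ``Zc`` carries entries ``(x - 2p_k)/sqrt(S_k)``
for allele count ``x`` and allele frequency ``p_k``, with the two standard
scalings: a single global scale ``S = sum_l 2 p_l (1 - p_l)`` (VanRaden
method 1) or a per-marker scale ``S_k = m * 2 p_k (1 - p_k)`` (method 2).
Blending the marker relationship with the pedigree one gives

    G_w = (1 - w) Zc Zc' + w A22,

where ``w`` is the residual polygenic (RPG) proportion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)

#: file tokens treated as a missing genotype
MISSING_CODES = {"5", "na", "nan", ""}

_VALID = {"0", "1", "2"}


@dataclass(frozen=True)
class GenotypeMatrix:
    """Biallelic allele-count matrix (animals x markers), entries in {0,1,2}."""

    ids: tuple[str, ...]
    counts: np.ndarray
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.ids), len(self.marker_ids)):
            raise ValueError("genotype matrix shape does not match ids/marker_ids")
        if c.size and not np.isin(c, (0, 1, 2)).all():
            raise ValueError("genotype counts must be 0, 1 or 2")
        object.__setattr__(self, "counts", c.astype(np.int8))

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([pos[a] for a in ids])
        return GenotypeMatrix(tuple(ids), self.counts[idx], self.marker_ids)


@dataclass(frozen=True)
class AlleleFrequencies:
    p: np.ndarray
    source: str = "observed"  # observed | supplied

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class CenteredGenotypeMatrix:
    """Centered/scaled marker coefficients ``Zc`` plus the scaling used."""

    ids: tuple[str, ...]
    Zc: np.ndarray
    method: str
    p: np.ndarray
    kept_marker_ids: tuple[str, ...]


@dataclass(frozen=True)
class BlendedRelationship:
    """``G_w = (1-w) Zc Zc' + w A22`` for the genotyped animals."""

    ids: tuple[str, ...]
    Gw: np.ndarray
    w: float


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read an ID + allele-count matrix; ``5``/``NA`` are missing.

    Missing entries are imputed to the column mean rounded half-up to the
    nearest integer; the number of imputations is logged.
    """
    df = pd.read_csv(path, header=None, dtype=str, sep=None, engine="python",
                     comment="#", skip_blank_lines=True)
    df = df.fillna("")
    row0 = [str(v).strip().lower() for v in df.iloc[0, 1:]]
    has_header = any(tok not in _VALID | MISSING_CODES for tok in row0)
    if has_header:
        marker_ids = tuple(str(v).strip() for v in df.iloc[0, 1:])
        df = df.iloc[1:]
    else:
        marker_ids = tuple(f"m{k + 1}" for k in range(df.shape[1] - 1))
    ids: list[str] = []
    vals = np.empty((df.shape[0], len(marker_ids)))
    for i, row in enumerate(df.itertuples(index=False)):
        animal = str(row[0]).strip()
        if animal in ids:
            raise ValueError(f"duplicate animal ID {animal!r} in {path}")
        ids.append(animal)
        for k, tok in enumerate(row[1:]):
            tok = str(tok).strip().lower()
            if tok in _VALID:
                vals[i, k] = float(tok)
            elif tok in MISSING_CODES:
                vals[i, k] = np.nan
            else:
                raise ValueError(
                    f"{path}: invalid genotype {tok!r} for animal {animal!r}, "
                    f"marker {marker_ids[k]!r} (row {i + 1}, column {k + 2})"
                )
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        col_mean = np.nanmean(np.where(np.isnan(vals), np.nan, vals), axis=0)
        if np.isnan(col_mean).any():
            bad = marker_ids[int(np.flatnonzero(np.isnan(col_mean))[0])]
            raise ValueError(f"{path}: marker {bad!r} has no observed genotypes")
        fill = np.floor(col_mean + 0.5)  # deterministic half-up rounding
        idx = np.where(np.isnan(vals))
        vals[idx] = fill[idx[1]]
        logger.info("imputed %d missing genotype(s) to rounded column means", n_missing)
    return GenotypeMatrix(tuple(ids), vals.astype(np.int8), marker_ids)


def allele_frequencies(G: GenotypeMatrix) -> AlleleFrequencies:
    """Observed allele frequency of the counted allele: column sum / 2n."""
    if G.n_animals < 1:
        raise ValueError("need at least one animal")
    p = G.counts.sum(axis=0, dtype=float) / (2.0 * G.n_animals)
    return AlleleFrequencies(p, source="observed")


def read_allele_frequencies(path: str | Path, marker_ids: Sequence[str]) -> AlleleFrequencies:
    """Read a supplied (e.g. base-population) frequency file: marker_id,p."""
    df = pd.read_csv(path, header=None, dtype=str, sep=None, engine="python")
    if str(df.iloc[0, 0]).strip().lower() in {"marker", "marker_id", "snp", "id"}:
        df = df.iloc[1:]
    table = {str(m).strip(): float(v) for m, v in df.iloc[:, :2].itertuples(index=False)}
    try:
        p = np.array([table[m] for m in marker_ids])
    except KeyError as exc:
        raise KeyError(f"marker {exc.args[0]!r} missing from frequency file") from None
    return AlleleFrequencies(p, source="supplied")


def center_scale(G: GenotypeMatrix, p: AlleleFrequencies, method: str = "vanraden1") -> CenteredGenotypeMatrix:
    """Center allele counts at ``2p_k`` and scale by the chosen ``S_k``.

    Monomorphic markers are dropped (with a warning) under method 2, whose
    per-marker scale would divide by zero; under method 1 they are retained
    and simply center to zero.
    """
    if len(p.p) != G.n_markers:
        raise ValueError("allele-frequency vector length does not match marker count")
    het = 2.0 * p.p * (1.0 - p.p)
    counts = G.counts.astype(float)
    if method == "vanraden1":
        S = het.sum()
        if S <= 0:
            raise ValueError("all markers are monomorphic; cannot scale")
        Zc = (counts - 2.0 * p.p) / np.sqrt(S)
        kept = G.marker_ids
        p_used = p.p
    elif method == "vanraden2":
        keep = het > 0
        if not keep.any():
            raise ValueError("all markers are monomorphic; cannot scale")
        n_drop = int((~keep).sum())
        if n_drop:
            warnings.warn(f"dropped {n_drop} monomorphic marker(s) under vanraden2 scaling",
                          stacklevel=2)
        m_kept = int(keep.sum())
        p_used = p.p[keep]
        Zc = (counts[:, keep] - 2.0 * p_used) / np.sqrt(m_kept * het[keep])
        kept = tuple(np.asarray(G.marker_ids)[keep])
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return CenteredGenotypeMatrix(G.ids, Zc, method, p_used, tuple(kept))


def blended_relationship(Zc: CenteredGenotypeMatrix, A22: RelationshipMatrix, w: float) -> BlendedRelationship:
    """``G_w = (1-w) Zc Zc' + w A22`` with a matching-order check."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"RPG proportion w must be in [0, 1], got {w}")
    if Zc.ids != tuple(A22.ids):
        raise ValueError("animal order of Zc and A22 differ; refusing to blend")
    Gw = (1.0 - w) * (Zc.Zc @ Zc.Zc.T) + w * A22.values
    return BlendedRelationship(Zc.ids, Gw, w)
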