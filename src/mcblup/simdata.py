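"""Synthetic populations: random pedigrees, gene-dropped genotypes, phenotypes.

The generator builds exactly the world the reliability models assume: a
discrete-generation random-mating pedigree, unlinked biallelic markers
transmitted by Mendelian gene dropping (so realized identity-by-descent is
consistent with the numerator relationship matrix in expectation), and
phenotypes ``y = mu + u + e`` with a true genetic value

    u = sqrt(sigma_u^2) [ sqrt(1-w) Zc g + sqrt(w) L a ],   g, a ~ N(0, I),

under unit phenotypic variance (``sigma_u^2 = h^2``, ``sigma_e^2 = 1 - h^2``).
Defaults give a 300-animal pedigree with the last 150 animals genotyped at
400 markers and a moderately heritable trait (h^2 = 0.3) - a desk-scale
stand-in for a dairy-cattle evaluation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exact_models import ModelParams, PhenotypeData
from .genotypes import (
    AlleleFrequencies,
    BlendedRelationship,
    CenteredGenotypeMatrix,
    GenotypeMatrix,
    allele_frequencies,
    blended_relationship,
    center_scale,
)
from .pedigree import (
    CholeskyFactor,
    Pedigree,
    RelationshipMatrix,
    cholesky_factor,
    numerator_relationship_matrix,
    subset_A22,
)


@dataclass(frozen=True)
class SimulationConfig:
    n_founders: int = 60
    n_generations: int = 4
    matings_per_generation: int = 60
    m: int = 400
    maf_low: float = 0.05
    maf_high: float = 0.5
    h2: float = 0.3
    w: float = 0.5
    mu: float = 0.0
    seed: int = 1
    n_genotyped: int | None = 150   # last animals in pedigree order; None = last generation
    scaling: str = "vanraden1"

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_generations < 0 or self.matings_per_generation < 1 or self.m < 1:
            raise ValueError("counts must be positive")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("RPG proportion must be in [0, 1]")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Discrete generations; each offspring draws distinct sire/dam from the previous one."""
    rng = _rng(cfg, 0)
    records: list[tuple[str, str | None, str | None]] = [
        (str(i + 1), None, None) for i in range(cfg.n_founders)
    ]
    prev = [str(i + 1) for i in range(cfg.n_founders)]
    next_id = cfg.n_founders + 1
    for _ in range(cfg.n_generations):
        cur: list[str] = []
        for _ in range(cfg.matings_per_generation):
            sire, dam = rng.choice(len(prev), size=2, replace=False)
            records.append((str(next_id), prev[sire], prev[dam]))
            cur.append(str(next_id))
            next_id += 1
        prev = cur
    return Pedigree(tuple(records))


def gene_drop_genotypes(ped: Pedigree, cfg: SimulationConfig) -> GenotypeMatrix:
    """Drop founder alleles down the pedigree at unlinked loci.

    Founder allele frequencies are uniform on [maf_low, maf_high]; each
    non-founder inherits one uniformly chosen allele from each parent per
    marker.  Returns allele counts for every animal in pedigree order.
    """
    rng = _rng(cfg, 1)
    n, m = len(ped), cfg.m
    p = cfg.maf_low + (cfg.maf_high - cfg.maf_low) * rng.random(m)
    par = ped.parent_indices()
    H = np.zeros((n, 2, m), dtype=np.int8)  # paternal/maternal haplotypes
    for j in range(n):
        s, d = par[j]
        for slot, parent in enumerate((s, d)):
            if parent < 0:
                H[j, slot] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                H[j, slot] = H[parent, pick, np.arange(m)]
    counts = H.sum(axis=1)
    marker_ids = tuple(f"m{k + 1}" for k in range(m))
    return GenotypeMatrix(ped.ids, counts, marker_ids)


def simulate_phenotypes(ped: Pedigree, G: GenotypeMatrix, Zc: CenteredGenotypeMatrix,
                        L: CholeskyFactor, cfg: SimulationConfig) -> tuple[PhenotypeData, np.ndarray]:
    """Phenotypes and true genetic values for the genotyped animals.

    Returns ``(PhenotypeData, u)`` where ``u`` is the simulated true genetic
    value, useful for diagnostics; weights are all 1.
    """
    if Zc.ids != tuple(L.ids):
        raise ValueError("animal order of Zc and L differ")
    rng = _rng(cfg, 2)
    n = len(Zc.ids)
    m = Zc.Zc.shape[1]
    su2, se2 = cfg.h2, 1.0 - cfg.h2
    g = rng.standard_normal(m)
    a = rng.standard_normal(n)
    u = np.sqrt(su2) * (np.sqrt(1.0 - cfg.w) * (Zc.Zc @ g) + np.sqrt(cfg.w) * (L.values @ a))
    e = rng.standard_normal(n) * np.sqrt(se2)
    y = cfg.mu + u + e
    return PhenotypeData(Zc.ids, y), u


@dataclass(frozen=True)
class SimulatedDataset:
    """Everything the reliability models need, plus the simulation truth."""

    config: SimulationConfig
    pedigree: Pedigree
    A: RelationshipMatrix
    genotypes_all: GenotypeMatrix
    genotyped_ids: tuple[str, ...]
    genotypes: GenotypeMatrix
    freqs: AlleleFrequencies
    Zc: CenteredGenotypeMatrix
    A22: RelationshipMatrix
    L: CholeskyFactor
    phenotypes: PhenotypeData
    true_u: np.ndarray

    @property
    def params(self) -> ModelParams:
        return ModelParams.from_heritability(self.config.h2, self.config.w)

    def blended(self, w: float | None = None) -> BlendedRelationship:
        return blended_relationship(self.Zc, self.A22, self.config.w if w is None else w)


def simulate_dataset(cfg: SimulationConfig = SimulationConfig()) -> SimulatedDataset:
    """Run the full generator: pedigree -> genotypes -> phenotypes.

    The genotyped set is the last ``n_genotyped`` animals in pedigree order
    (the youngest ones, as in routine evaluations); allele frequencies are
    observed in that set.
    """
    ped = simulate_pedigree(cfg)
    A = numerator_relationship_matrix(ped)
    G_all = gene_drop_genotypes(ped, cfg)
    k = cfg.n_genotyped if cfg.n_genotyped is not None else \
        (cfg.matings_per_generation if cfg.n_generations > 0 else len(ped))
    if k > len(ped):
        raise ValueError("n_genotyped exceeds pedigree size")
    genotyped_ids = ped.ids[-k:]
    G = G_all.subset(genotyped_ids)
    freqs = allele_frequencies(G)
    Zc = center_scale(G, freqs, cfg.scaling)
    A22 = subset_A22(A, genotyped_ids)
    L = cholesky_factor(A22)
    pheno, u = simulate_phenotypes(ped, G, Zc, L, cfg)
    return SimulatedDataset(cfg, ped, A, G_all, genotyped_ids, G, freqs, Zc,
                            A22, L, pheno, u)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write pedigree/genotype/phenotype CSVs plus a manifest of the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "genotypes": outdir / "genotypes.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "manifest": outdir / "manifest.json",
    }
    ped_rows = [(a, s or "0", d or "0") for a, s, d in ds.pedigree.records]
    pd.DataFrame(ped_rows, columns=["animal", "sire", "dam"]).to_csv(
        paths["pedigree"], index=False)
    geno = pd.DataFrame(ds.genotypes.counts, columns=list(ds.genotypes.marker_ids))
    geno.insert(0, "animal", list(ds.genotypes.ids))
    geno.to_csv(paths["genotypes"], index=False)
    pd.DataFrame({
        "animal": ds.phenotypes.ids,
        "value": ds.phenotypes.y,
        "weight": ds.phenotypes.weights,
    }).to_csv(paths["phenotypes"], index=False)
    manifest = {
        "config": dataclasses.asdict(ds.config),
        "lambda": ds.params.lambda_,
        "n_animals": len(ds.pedigree),
        "n_genotyped": len(ds.genotyped_ids),
        "n_markers_kept": len(ds.Zc.kept_marker_ids),
        "true_u_variance": float(np.var(ds.true_u)),
        "files": {k: v.name for k, v in paths.items() if k != "manifest"},
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
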