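"""Spatial colocalization of predicted interactions with a permutation null.

For spot-based spatial transcriptomics with per-spot cell-type probabilities
(e.g. from deconvolution), an interaction (ligand, receptor, target cell type)
is scored by summing log1p(ligand expression) x Pr(target cell type) x
1[receptor expressed] over spots; the null distribution is obtained by
permuting the ligand expression vector across spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

PROB_TOL = 1e-6


@dataclass
class SpatialDataset:
    """Spot coordinates (um), spot x gene expression, spot x cell-type probabilities."""

    spots: pd.DataFrame          # columns: spot_id, x, y (um)
    expr: pd.DataFrame           # index: spot_id, columns: genes
    celltype_prob: pd.DataFrame  # index: spot_id, columns: cell types, rows sum to 1

    def __post_init__(self):
        if not np.isfinite(self.spots[["x", "y"]].to_numpy()).all():
            raise ValueError("spot coordinates must be finite")
        p = self.celltype_prob.to_numpy()
        if (p < -PROB_TOL).any() or (p > 1 + PROB_TOL).any():
            raise ValueError("cell-type probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=PROB_TOL):
            raise ValueError("cell-type probability rows must sum to 1")
        if (self.expr.to_numpy() < 0).any():
            raise ValueError("expression must be non-negative")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def coords(self) -> np.ndarray:
        return self.spots[["x", "y"]].to_numpy(dtype=float)


def _columns(sp: SpatialDataset, ligand: str, receptor: str, target_cell_type: str):
    for gene in (ligand, receptor):
        if gene not in sp.expr.columns:
            raise KeyError(f"gene {gene!r} not in spatial expression")
    if target_cell_type not in sp.celltype_prob.columns:
        raise KeyError(f"cell type {target_cell_type!r} not in probabilities")
    lig = sp.expr[ligand].to_numpy(dtype=float)
    rec = (sp.expr[receptor].to_numpy(dtype=float) > 0).astype(float)
    prob = sp.celltype_prob[target_cell_type].to_numpy(dtype=float)
    return lig, rec, prob


def coloc_statistic(sp: SpatialDataset, ligand: str, receptor: str,
                    target_cell_type: str, ligand_values=None) -> float:
    """sum over spots of log1p(ligand) x Pr(target type) x 1[receptor expressed]."""
    lig, rec, prob = _columns(sp, ligand, receptor, target_cell_type)
    if ligand_values is not None:
        lig = np.asarray(ligand_values, dtype=float)
    return float(np.sum(np.log1p(lig) * prob * rec))


def permutation_pvalue(sp: SpatialDataset, ligand: str, receptor: str,
                       target_cell_type: str, n_perm: int = 100,
                       seed: int | None = 0, ligand_values=None):
    """One-sided permutation p for the colocalization statistic.

    The ligand expression vector is permuted across spots (receptor indicator
    and probabilities fixed); p = (1 + #{perm stat >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if sp.n_spots < 2:
        raise ValueError("need >=2 spots")
    lig, rec, prob = _columns(sp, ligand, receptor, target_cell_type)
    if ligand_values is not None:
        lig = np.asarray(ligand_values, dtype=float)
    w = np.log1p(lig)
    fixed = prob * rec
    obs = float(w @ fixed)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        exceed += float(rng.permutation(w) @ fixed) >= obs
    return obs, (1 + exceed) / (1 + n_perm)


def neighborhood_ligand(sp: SpatialDataset, ligand: str, radius: float) -> np.ndarray:
    """Replace each spot's ligand signal by the sum over spots within ``radius``
    um (Euclidean, inclusive of the focal spot); radius 0 reproduces the
    spot-level values."""
    lig = sp.expr[ligand].to_numpy(dtype=float)
    if radius <= 0:
        return lig
    D = cdist(sp.coords(), sp.coords())
    return (D <= radius) @ lig


def fraction_colocalized(sp: SpatialDataset, ranked_interactions, top_n_grid, *,
                         radius: float | None = None, alpha: float = 0.05,
                         n_perm: int = 100, seed: int = 0) -> pd.DataFrame:
    """Fraction of the top-N ranked interactions with permutation p < alpha.

    ``ranked_interactions`` is an ordered list of (ligand, receptor, target
    cell type) triples; with ``radius`` set, ligand signal is first pooled over
    the radius-neighbourhood of each spot.  Returns a DataFrame (top_n,
    fraction_colocalized).
    """
    if not len(ranked_interactions):
        raise ValueError("ranked interaction list is empty")
    pvals = []
    for i, (lig, rec, ct) in enumerate(ranked_interactions):
        values = neighborhood_ligand(sp, lig, radius) if radius else None
        _, p = permutation_pvalue(sp, lig, rec, ct, n_perm=n_perm,
                                  seed=seed + i, ligand_values=values)
        pvals.append(p)
    pvals = np.asarray(pvals)
    rows = [{"top_n": n, "fraction_colocalized": float((pvals[:n] < alpha).mean())}
            for n in top_n_grid if n >= 1]
    return pd.DataFrame(rows)
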