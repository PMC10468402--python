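"""Ground-truth-annotated synthetic data generators.

``simulate_tme`` emulates the statistical structure the interaction tests
exploit in a multi-condition tumour microenvironment: negative-binomial counts
with per-cell size factors (detection-rate heterogeneity), bimodal receptor
detection in target cell types, condition-specific ligand availability in donor
cell types, ligand-effect genes shifted only in receptor-positive cells of the
ligand-available condition, and receptor-correlated confounder genes shifted in
receptor-positive cells of every condition.  ``simulate_spatial`` plants
colocalized and background interaction triples on a spot grid, and
``simulate_cnv`` produces variant profiles with requested frequencies and
alteration magnitudes.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cnv import DEFAULT_NEUTRAL_STATE, CNVVariantProfile
from .expression import ExpressionDataset
from .lrdb import InteractionDatabase, InteractionRecord
from .spatial import SpatialDataset

__all__ = [
    "PlantedInteraction", "TMEConfig", "SyntheticTruth", "simulate_tme",
    "SpatialConfig", "simulate_spatial", "simulate_cnv",
]


@dataclass(frozen=True)
class PlantedInteraction:
    """One ground-truth ligand-receptor interaction to plant."""

    ligand: str
    donor_type: str
    receptor: str
    target_type: str
    condition_dependent: bool = True
    n_effect_genes: int = 15
    n_confounder_genes: int = 10


@dataclass
class TMEConfig:
    """Study conditions for the synthetic tumour microenvironment.

    Defaults describe a three-condition design (high chromosomal instability,
    low instability, and STING-depleted high instability) with one donor and
    one target cell type, 500 cells per cell type per condition, receptors
    detected in half the target cells, ligands ~2.8x up (log2FC 1.5) in the
    ligand-available condition, and ligand-effect/confounder genes shifted by
    log2FC 1.
    """

    cell_types: tuple = ("Tumor", "Macrophage")
    conditions: tuple = ("CINhigh", "CINlow", "STINGkd")
    ligand_high_condition: str = "CINhigh"
    n_cells_per_type_per_condition: int = 500
    n_background_genes: int = 150
    n_housekeeping_genes: int = 30   # highly expressed, stabilize library sizes
    receptor_detect_prob: float = 0.5
    ligand_log2fc: float = 1.5
    effect_log2fc: float = 1.0
    confounder_log2fc: float = 1.0
    dispersion: float = 0.5          # NB: var = mu + dispersion * mu^2
    cdr_sigma: float = 0.35          # lognormal sd of per-cell size factors
    n_subclusters: int = 2
    interactions: tuple = ()

    def __post_init__(self):
        if len(self.conditions) < 2 or len(self.cell_types) < 2:
            raise ValueError("need >=2 conditions and >=2 cell types")
        if self.ligand_high_condition not in self.conditions:
            raise ValueError("ligand_high_condition must be one of conditions")
        if not self.interactions:
            self.interactions = (PlantedInteraction(
                "LIG1", self.cell_types[0], "RCPT1", self.cell_types[1]),)
        for pi in self.interactions:
            if pi.donor_type not in self.cell_types or pi.target_type not in self.cell_types:
                raise ValueError(f"interaction {pi.ligand}->{pi.receptor} references "
                                 "unknown cell types")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    effect_genes: dict = field(default_factory=dict)      # (receptor, target_type) -> {gene: log2fc}
    confounder_genes: dict = field(default_factory=dict)  # receptor -> [genes]
    true_interactions: list = field(default_factory=list) # PlantedInteraction list
    seed: int | None = None

    def condition_dependent(self) -> list:
        return [pi for pi in self.true_interactions if pi.condition_dependent]

    def condition_independent(self) -> list:
        return [pi for pi in self.true_interactions if not pi.condition_dependent]


def _nb_counts(rng, mu, dispersion):
    """Gamma-Poisson (negative binomial) sampling with mean mu elementwise."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_tme(config: TMEConfig | None = None, seed: int = 0):
    """Generate (ExpressionDataset, InteractionDatabase, SyntheticTruth)."""
    cfg = config or TMEConfig()
    rng = np.random.default_rng(seed)

    # cells ------------------------------------------------------------
    rows = []
    for ct in cfg.cell_types:
        for cond in cfg.conditions:
            for i in range(cfg.n_cells_per_type_per_condition):
                rows.append((ct, cond))
    obs = pd.DataFrame(rows, columns=["cell_type", "condition"])
    obs["cell_id"] = [f"cell{i:05d}" for i in range(len(obs))]
    obs["sample_id"] = obs["condition"].astype(str) + "_s1"
    obs["subcluster"] = [f"sc{j}" for j in rng.integers(0, cfg.n_subclusters, len(obs))]
    n_cells = len(obs)
    sf = rng.lognormal(mean=0.0, sigma=cfg.cdr_sigma, size=n_cells)

    # gene panel ---------------------------------------------------------
    genes: list = [f"G{i:04d}" for i in range(cfg.n_background_genes)]
    genes += [f"HK{i:03d}" for i in range(cfg.n_housekeeping_genes)]
    truth = SyntheticTruth(seed=seed, true_interactions=list(cfg.interactions))
    eff_names: dict = {}
    cnf_names: dict = {}
    for k, pi in enumerate(cfg.interactions):
        eff = [f"EFF{k}_{j}" for j in range(pi.n_effect_genes)]
        cnf = [f"CNF{k}_{j}" for j in range(pi.n_confounder_genes)]
        eff_names[pi], cnf_names[pi] = eff, cnf
        genes += [pi.ligand, pi.receptor] + eff + cnf
    if len(set(genes)) != len(genes):
        raise ValueError("inconsistent config: duplicate gene names")

    counts = np.zeros((n_cells, len(genes)), dtype=np.int64)
    gidx = {g: j for j, g in enumerate(genes)}
    is_type = {ct: (obs["cell_type"] == ct).to_numpy() for ct in cfg.cell_types}
    is_cond = {c: (obs["condition"] == c).to_numpy() for c in cfg.conditions}

    # background genes: lognormal means shared across all cells; a block of
    # highly expressed housekeeping genes dominates library size, as in real
    # cells, so planted genes perturb normalization only marginally
    n_base = cfg.n_background_genes + cfg.n_housekeeping_genes
    mu_bg = np.concatenate([
        rng.lognormal(np.log(0.3), 1.0, size=cfg.n_background_genes),
        rng.lognormal(np.log(10.0), 0.5, size=cfg.n_housekeeping_genes),
    ])
    counts[:, :n_base] = _nb_counts(rng, sf[:, None] * mu_bg[None, :], cfg.dispersion)

    # receptors: bimodal detection in the target cell type
    target_pos: dict = {}
    for pi in cfg.interactions:
        col = np.zeros(n_cells, dtype=np.int64)
        tmask = is_type[pi.target_type]
        z = rng.random(int(tmask.sum())) < cfg.receptor_detect_prob
        col[tmask] = z * (1 + rng.poisson(0.7, size=z.size))
        off = ~tmask
        col[off] = _nb_counts(rng, sf[off] * 0.02, cfg.dispersion)
        counts[:, gidx[pi.receptor]] = col
        target_pos[pi] = (col > 0) & tmask

    # ligands: donor-type expression, condition-dependent when planted so
    for pi in cfg.interactions:
        mu = np.full(n_cells, 0.05)
        dmask = is_type[pi.donor_type]
        mu[dmask] = 2.0
        if pi.condition_dependent:
            hi = dmask & is_cond[cfg.ligand_high_condition]
            mu[hi] *= 2.0 ** cfg.ligand_log2fc
        counts[:, gidx[pi.ligand]] = _nb_counts(rng, sf * mu, cfg.dispersion)

    # effect genes and confounders
    for pi in cfg.interactions:
        pos = target_pos[pi]
        hi = is_cond[cfg.ligand_high_condition]
        for g in eff_names[pi]:
            mu = np.full(n_cells, 1.0) * rng.lognormal(np.log(0.8), 0.3)
            if pi.condition_dependent:
                mu[pos & hi] *= 2.0 ** cfg.effect_log2fc
            else:
                mu[pos] *= 2.0 ** cfg.effect_log2fc
            counts[:, gidx[g]] = _nb_counts(rng, sf * mu, cfg.dispersion)
        for g in cnf_names[pi]:
            mu = np.full(n_cells, 1.0) * rng.lognormal(np.log(0.8), 0.3)
            mu[pos] *= 2.0 ** cfg.confounder_log2fc
            counts[:, gidx[g]] = _nb_counts(rng, sf * mu, cfg.dispersion)

        key = (pi.receptor, pi.target_type)
        lfc = cfg.effect_log2fc
        truth.effect_genes[key] = {g: lfc for g in eff_names[pi]}
        truth.confounder_genes[pi.receptor] = list(cnf_names[pi])

    ds = ExpressionDataset.from_counts(sp.csr_matrix(counts), genes, obs)
    db = InteractionDatabase()
    for pi in cfg.interactions:
        db.add(InteractionRecord(pi.ligand, pi.receptor, frozenset(["synthetic"])))
    return ds, db, truth


# ---------------------------------------------------------------------------
# spatial
# ---------------------------------------------------------------------------

@dataclass
class SpatialConfig:
    """Spot-grid layout with planted colocalized and background triples."""

    grid_size: int = 15
    spacing_um: float = 100.0
    cell_types: tuple = ("Tumor", "Macrophage", "Stroma")
    n_colocalized: int = 3
    n_background: int = 3
    patch_radius_um: float = 300.0
    ligand_mu_in: float = 6.0
    ligand_mu_out: float = 0.2
    receptor_mu_in: float = 3.0
    receptor_mu_out: float = 0.1
    prob_boost: float = 8.0

    def __post_init__(self):
        if self.grid_size < 2:
            raise ValueError("grid must be at least 2x2")


def simulate_spatial(config: SpatialConfig | None = None, seed: int = 0):
    """Generate (SpatialDataset, truth DataFrame with a ``colocalized`` flag).

    Colocalized triples concentrate ligand expression, receptor detection and
    target-cell-type probability inside a shared circular patch; background
    triples place ligand and receptor uniformly at random, independent of the
    cell-type probability field.
    """
    cfg = config or SpatialConfig()
    rng = np.random.default_rng(seed)
    g = cfg.grid_size
    xx, yy = np.meshgrid(np.arange(g), np.arange(g))
    coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float) * cfg.spacing_um
    n = len(coords)
    spots = pd.DataFrame({"spot_id": [f"spot{i:04d}" for i in range(n)],
                          "x": coords[:, 0], "y": coords[:, 1]})

    # one spatial patch per cell type; probabilities from patch-boosted Dirichlet
    centers = coords[rng.choice(n, size=len(cfg.cell_types), replace=False)]
    in_patch = {}
    alpha = np.ones((n, len(cfg.cell_types)))
    for j, ct in enumerate(cfg.cell_types):
        d = np.linalg.norm(coords - centers[j], axis=1)
        in_patch[ct] = d <= cfg.patch_radius_um
        alpha[in_patch[ct], j] += cfg.prob_boost
    prob = np.stack([rng.dirichlet(a) for a in alpha])

    expr = {}
    truth_rows = []
    for i in range(cfg.n_colocalized):
        ct = cfg.cell_types[i % len(cfg.cell_types)]
        mask = in_patch[ct]
        lig, rec = f"CLIG{i}", f"CRCPT{i}"
        expr[lig] = rng.poisson(np.where(mask, cfg.ligand_mu_in, cfg.ligand_mu_out))
        expr[rec] = rng.poisson(np.where(mask, cfg.receptor_mu_in, cfg.receptor_mu_out))
        truth_rows.append({"ligand": lig, "receptor": rec, "target_type": ct,
                           "colocalized": True})
    for i in range(cfg.n_background):
        ct = cfg.cell_types[i % len(cfg.cell_types)]
        lig, rec = f"BLIG{i}", f"BRCPT{i}"
        expr[lig] = rng.poisson(1.0, size=n)
        expr[rec] = rng.poisson(1.0, size=n)
        truth_rows.append({"ligand": lig, "receptor": rec, "target_type": ct,
                           "colocalized": False})

    sp_ds = SpatialDataset(
        spots=spots,
        expr=pd.DataFrame(expr, index=spots["spot_id"]).astype(float),
        celltype_prob=pd.DataFrame(prob, index=spots["spot_id"], columns=cfg.cell_types),
    )
    return sp_ds, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# CNV
# ---------------------------------------------------------------------------

def simulate_cnv(freqs, deltas=None, state_matrices=None, seed: int = 0,
                 n_bins: int = 50, neutral_state: int = DEFAULT_NEUTRAL_STATE) -> list:
    """Variant profiles with exactly the requested frequencies and magnitudes.

    Provide either per-variant ``deltas`` (integer state vectors are generated
    by scattering that many unit deviations over ``n_bins``) or explicit
    ``state_matrices`` (list of per-bin state vectors).
    """
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {freqs.sum():.6f}, expected 1")
    rng = np.random.default_rng(seed)
    out = []
    if state_matrices is not None:
        for i, (f, states) in enumerate(zip(freqs, state_matrices, strict=True)):
            out.append(CNVVariantProfile(f"v{i}", float(f), states=np.asarray(states),
                                         neutral_state=neutral_state))
        return out
    if deltas is None:
        raise ValueError("provide deltas or state_matrices")
    for i, (f, d) in enumerate(zip(freqs, deltas, strict=True)):
        d = int(d)
        states = np.full(n_bins, neutral_state, dtype=int)
        for _ in range(d):  # scatter unit deviations; signs random
            j = rng.integers(0, n_bins)
            states[j] += rng.choice([-1, 1])
        delta = float(np.abs(states - neutral_state).sum())
        if delta != d:  # deviations may cancel in one bin; rebuild deterministically
            states = np.full(n_bins, neutral_state, dtype=int)
            states[: d % n_bins] += 1
            states += (d // n_bins)
        out.append(CNVVariantProfile(f"v{i}", float(f), states=states,
                                     neutral_state=neutral_state))
    return out
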