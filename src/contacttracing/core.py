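"""Condition-dependent interaction inference over a ligand-receptor database.

Three hurdle-model likelihood-ratio tests are orchestrated per putative
interaction:

* **target test** — within the target cell type, does a gene's expression differ
  between receptor-detected (target+) and receptor-null (target-) cells?
  Model: Y ~ CDR + condition + target, dropping ``target``.
* **ligand condition test** — is the ligand differentially expressed between
  two conditions within the donor cell type? Model: Y ~ CDR + condition,
  dropping ``condition`` (positive log2FC = higher in the first contrast level).
* **interaction test** — restricted to the two contrast conditions, does adding
  an indicator for (target+ AND condition == condition-of-interest) improve the
  fit?  Genes passing it respond to receptor engagement only when the ligand is
  conditionally available, which separates true ligand effects from genes
  merely co-expressed with the receptor.

Per-gene target-test scores (-log10 Bonferroni p x log2FC) are assembled into a
response matrix whose rows are (receptor, target cell type) pairs; rows are
embedded with PCA (kneepoint-selected dimensionality) and ordered by the first
diffusion component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

from .expression import ExpressionDataset
from .hurdle import DesignSpec, adjust_pvalues, hurdle_lrt_table
from .lrdb import InteractionDatabase

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["gene", "chisq", "df", "p", "log2fc", "status", "fdr"]


@dataclass
class Thresholds:
    """Significance rule for a conditionally dependent interaction."""

    n_effects_min: int = 10          # interaction effects per contrast
    interaction_fdr: float = 0.25
    ligand_fdr: float = 0.05
    ligand_abs_log2fc: float = 0.12
    deg_fdr: float = 0.05            # target-test DEG count used for tie-breaking
    require_sign_agreement: bool = True


@dataclass
class InteractionSummary:
    ligand: str
    donor_type: str
    receptor: str
    target_type: str
    n_effects: dict            # contrast name -> count at interaction FDR cut
    ligand_log2fc: dict        # contrast name -> ligand log2FC in donor type
    ligand_fdr: dict
    n_target_degs: int
    significant: bool

    @property
    def max_effects(self) -> int:
        return max(self.n_effects.values()) if self.n_effects else 0


def contrast_name(contrast) -> str:
    return f"{contrast[0]}-vs-{contrast[1]}"


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(columns=RESULT_COLUMNS)


def _gene_universe(sub: ExpressionDataset, min_detect_frac: float, genes=None) -> list:
    if genes is not None:
        return [g for g in genes if g in sub.genes]
    frac = sub.detection_fraction()
    return list(frac.index[frac >= min_detect_frac])


def _condition_covariates(obs: pd.DataFrame) -> list:
    return [("condition", "categorical")] if obs["condition"].nunique() > 1 else []


def target_test(ds: ExpressionDataset, receptor: str, target_cell_type: str, *,
                min_cells: int = 20, min_detect_frac: float = 0.01,
                genes=None, lfc_mode: str = "combined") -> pd.DataFrame:
    """Per-gene LRT comparing receptor-detected vs receptor-null cells of one type."""
    sub = ds.cells_of_type(target_cell_type)
    if sub.n_cells < min_cells:
        logger.warning("target test skipped: %s has %d < %d cells",
                       target_cell_type, sub.n_cells, min_cells)
        return _empty_results()
    target = sub.gene_counts(receptor) > 0
    if target.all() or not target.any():
        logger.warning("target test skipped: receptor %s is %s in all %s cells",
                       receptor, "detected" if target.all() else "absent", target_cell_type)
        return _empty_results()

    obs = sub.obs.assign(target=target.astype(float)).reset_index(drop=True)
    spec = DesignSpec(
        covariates=[("cdr", "continuous"), *_condition_covariates(obs), ("target", "binary")],
        contrast="target",
    )
    X, contrast_cols = spec.build(obs)
    universe = _gene_universe(sub, min_detect_frac, genes)
    idx = [sub.gene_index(g) for g in universe]
    return hurdle_lrt_table(sub.lognorm[:, idx], X, contrast_cols, universe, lfc_mode=lfc_mode)


def ligand_condition_test(ds: ExpressionDataset, ligands, donor_cell_type: str,
                          contrast, *, lfc_mode: str = "combined") -> pd.DataFrame:
    """Differential expression of ligands across the two contrast conditions
    within the donor cell type (positive log2FC = higher in ``contrast[0]``)."""
    if isinstance(ligands, str):
        ligands = [ligands]
    sub = ds.cells_of_type(donor_cell_type)
    present = set(sub.obs["condition"])
    for level in contrast:
        if level not in present:
            raise ValueError(f"condition level {level!r} absent from {donor_cell_type} cells")
    sub = sub.subset(sub.obs["condition"].isin(contrast).to_numpy())
    obs = sub.obs.assign(cond_hi=(sub.obs["condition"] == contrast[0]).astype(float))
    obs = obs.reset_index(drop=True)
    spec = DesignSpec(covariates=[("cdr", "continuous"), ("cond_hi", "binary")],
                      contrast="cond_hi")
    X, contrast_cols = spec.build(obs)
    genes = [g for g in ligands if g in sub.genes]
    if not genes:
        return _empty_results()
    idx = [sub.gene_index(g) for g in genes]
    return hurdle_lrt_table(sub.lognorm[:, idx], X, contrast_cols, genes, lfc_mode=lfc_mode)


def interaction_test(ds: ExpressionDataset, receptor: str, target_cell_type: str,
                     contrast, *, condition_of_interest: str | None = None,
                     min_cells: int = 20, min_detect_frac: float = 0.01,
                     genes=None, lfc_mode: str = "combined") -> pd.DataFrame:
    """LRT for a condition-specific transcriptional response in target+ cells.

    Cells are restricted to the two contrast conditions; the full model adds
    the binary indicator (target+ AND condition == condition_of_interest) and
    the reduced model drops only that indicator.
    """
    coi = condition_of_interest if condition_of_interest is not None else contrast[0]
    if coi not in contrast:
        raise ValueError(f"condition_of_interest {coi!r} not in contrast {contrast}")
    sub = ds.cells_of_type(target_cell_type)
    sub = sub.subset(sub.obs["condition"].isin(contrast).to_numpy())
    present = set(sub.obs["condition"])
    if present == {coi} or coi not in present:
        raise ValueError(
            f"interaction indicator would be aliased: conditions present are {sorted(present)}"
        )
    if sub.n_cells < min_cells:
        logger.warning("interaction test skipped: %d < %d cells", sub.n_cells, min_cells)
        return _empty_results()
    target = sub.gene_counts(receptor) > 0
    if target.all() or not target.any():
        logger.warning("interaction test skipped: receptor %s constant in %s",
                       receptor, target_cell_type)
        return _empty_results()

    obs = sub.obs.assign(
        target=target.astype(float),
        interaction=(target & (sub.obs["condition"] == coi).to_numpy()).astype(float),
    ).reset_index(drop=True)
    spec = DesignSpec(
        covariates=[("cdr", "continuous"), *_condition_covariates(obs),
                    ("target", "binary"), ("interaction", "binary")],
        contrast="interaction",
    )
    X, contrast_cols = spec.build(obs)
    universe = _gene_universe(sub, min_detect_frac, genes)
    idx = [sub.gene_index(g) for g in universe]
    return hurdle_lrt_table(sub.lognorm[:, idx], X, contrast_cols, universe, lfc_mode=lfc_mode)


@dataclass
class ContactTracingResults:
    """Container for all per-gene test tables of one run."""

    contrasts: list = field(default_factory=list)        # list of (high, low) tuples
    target: dict = field(default_factory=dict)           # (receptor, cell_type) -> df
    interaction: dict = field(default_factory=dict)      # (receptor, cell_type, cname) -> df
    ligand: dict = field(default_factory=dict)           # (donor_type, cname) -> df indexed by gene

    def contrast_names(self) -> list:
        return [contrast_name(c) for c in self.contrasts]


def run_tests(ds: ExpressionDataset, db: InteractionDatabase, contrasts, *,
              donor_types=None, target_types=None, min_cells: int = 20,
              min_detect_frac: float = 0.01, lfc_mode: str = "combined",
              genes=None) -> ContactTracingResults:
    """Run target, ligand-condition and interaction tests for every database
    receptor x target cell type and ligand x donor cell type."""
    cell_types = sorted(ds.obs["cell_type"].unique())
    donor_types = list(donor_types) if donor_types is not None else cell_types
    target_types = list(target_types) if target_types is not None else cell_types
    receptors = sorted({r.receptor for r in db if r.receptor in ds.genes})
    ligands = sorted({r.ligand for r in db if r.ligand in ds.genes})

    res = ContactTracingResults(contrasts=[tuple(c) for c in contrasts])
    for ct in target_types:
        for receptor in receptors:
            tt = target_test(ds, receptor, ct, min_cells=min_cells,
                             min_detect_frac=min_detect_frac, genes=genes, lfc_mode=lfc_mode)
            if not tt.empty:
                res.target[(receptor, ct)] = tt
            for contrast in res.contrasts:
                try:
                    it = interaction_test(ds, receptor, ct, contrast,
                                          min_cells=min_cells,
                                          min_detect_frac=min_detect_frac,
                                          genes=genes, lfc_mode=lfc_mode)
                except ValueError as err:
                    logger.warning("interaction test (%s, %s, %s): %s",
                                   receptor, ct, contrast_name(contrast), err)
                    continue
                if not it.empty:
                    res.interaction[(receptor, ct, contrast_name(contrast))] = it
    for ct in donor_types:
        for contrast in res.contrasts:
            try:
                lt = ligand_condition_test(ds, ligands, ct, contrast, lfc_mode=lfc_mode)
            except ValueError as err:
                logger.warning("ligand test (%s, %s): %s", ct, contrast_name(contrast), err)
                continue
            if not lt.empty:
                res.ligand[(ct, contrast_name(contrast))] = lt.set_index("gene")
    return res


def summarize_interactions(res: ContactTracingResults, db: InteractionDatabase, *,
                           thresholds: Thresholds | None = None,
                           pairs=None) -> list:
    """Combine the component tests into per-interaction summaries.

    ``pairs`` optionally restricts (donor_type, target_type) combinations;
    by default every combination with computed tests is summarized.  The
    significance rule requires, for every contrast: at least ``n_effects_min``
    genes at interaction FDR < ``interaction_fdr``, ligand FDR <
    ``ligand_fdr`` with \\|log2FC\\| > ``ligand_abs_log2fc``, and (across
    contrasts) agreement of the ligand log2FC sign.
    """
    th = thresholds or Thresholds()
    cnames = res.contrast_names()
    donor_types = sorted({d for d, _ in res.ligand})
    target_types = sorted({ct for _, ct in res.target})
    if pairs is None:
        pairs = [(d, t) for d in donor_types for t in target_types]

    out = []
    for rec in sorted(db, key=lambda r: r.key):
        for donor_ct, target_ct in pairs:
            tt = res.target.get((rec.receptor, target_ct))
            if tt is None:
                continue
            excl = {rec.receptor, rec.ligand}
            n_eff, lig_lfc, lig_fdr = {}, {}, {}
            complete = True
            for cname in cnames:
                it = res.interaction.get((rec.receptor, target_ct, cname))
                lt = res.ligand.get((donor_ct, cname))
                if it is None or lt is None or rec.ligand not in lt.index:
                    complete = False
                    break
                hits = it[(it["fdr"] < th.interaction_fdr) & ~it["gene"].isin(excl)]
                n_eff[cname] = int(len(hits))
                lig_lfc[cname] = float(lt.loc[rec.ligand, "log2fc"])
                lig_fdr[cname] = float(lt.loc[rec.ligand, "fdr"])
            if not complete:
                continue
            n_degs = int(((tt["fdr"] < th.deg_fdr) & ~tt["gene"].isin(excl)).sum())
            sig = all(n_eff[c] >= th.n_effects_min for c in cnames)
            sig &= all(lig_fdr[c] < th.ligand_fdr and abs(lig_lfc[c]) > th.ligand_abs_log2fc
                       for c in cnames)
            if th.require_sign_agreement and len(cnames) > 1:
                signs = {np.sign(lig_lfc[c]) for c in cnames}
                sig &= len(signs) == 1 and 0 not in signs
            out.append(InteractionSummary(rec.ligand, donor_ct, rec.receptor, target_ct,
                                          n_eff, lig_lfc, lig_fdr, n_degs, bool(sig)))
    return out


def rank_interactions(summaries) -> list:
    """Stable descending sort by (number of interaction effects, number of
    target-test DEGs); equal keys preserve input order."""
    return sorted(summaries, key=lambda s: (-s.max_effects, -s.n_target_degs))


def summaries_to_frame(summaries, cnames=None) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"ligand": s.ligand, "donor_type": s.donor_type,
               "receptor": s.receptor, "target_type": s.target_type,
               "n_target_degs": s.n_target_degs, "significant": s.significant}
        for c in (cnames or s.n_effects):
            row[f"n_effects[{c}]"] = s.n_effects.get(c)
            row[f"ligand_log2fc[{c}]"] = s.ligand_log2fc.get(c)
            row[f"ligand_fdr[{c}]"] = s.ligand_fdr.get(c)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# response matrix and embedding
# ---------------------------------------------------------------------------

@dataclass
class ResponseScoreMatrix:
    """Signed per-gene response scores, rows keyed by (receptor, cell type).

    Entry = -log10(Bonferroni-adjusted target-test p) x log2FC; zero where the
    gene was untested or the adjusted p is 1.
    """

    scores: pd.DataFrame                     # rows: MultiIndex (receptor, cell_type)
    zero_rows: list = field(default_factory=list)
    pc_embedding: np.ndarray | None = None
    n_pcs: int | None = None
    dc1: pd.Series | None = None


def build_response_matrix(target_tables: dict) -> ResponseScoreMatrix:
    """Assemble response scores from target-test tables keyed (receptor, cell type)."""
    if not target_tables:
        raise ValueError("need at least one target-test table")
    genes = sorted({g for df in target_tables.values() for g in df["gene"]})
    rows = {}
    for key, df in sorted(target_tables.items()):
        p_bonf = adjust_pvalues(
            df["p"].where(df["status"] != "degenerate", np.nan).to_numpy(),
            method="bonferroni",
        )
        score = -np.log10(np.clip(p_bonf, 1e-300, None)) * df["log2fc"].to_numpy()
        score = np.where(np.isnan(p_bonf), 0.0, score)
        rows[key] = pd.Series(score, index=df["gene"].to_numpy())
    mat = pd.DataFrame(index=pd.MultiIndex.from_tuples(rows, names=["receptor", "cell_type"]),
                       columns=genes, dtype=float)
    for key, s in rows.items():
        mat.loc[key, s.index] = s.to_numpy()
    mat = mat.fillna(0.0)
    zero = [key for key in mat.index if not mat.loc[key].to_numpy().any()]
    if zero:
        logger.warning("%d all-zero response rows retained", len(zero))
    return ResponseScoreMatrix(scores=mat, zero_rows=zero)


def kneepoint(cumvar) -> int:
    """Number of components at the knee of a cumulative-variance curve:
    the point of maximum perpendicular distance to the chord joining the first
    and last points (ties resolved to the earliest point)."""
    v = np.asarray(cumvar, dtype=float)
    m = len(v)
    if m == 0:
        raise ValueError("empty curve")
    if m <= 2:
        return 1
    x = np.arange(m, dtype=float)
    dx, dy = x[-1] - x[0], v[-1] - v[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (v - v[0])) / norm
    return int(np.argmax(dist)) + 1


def diffusion_dc1(emb: np.ndarray, n_neighbors: int = 15) -> np.ndarray:
    """First nontrivial diffusion coordinate of a point set.

    Affinities use a kNN-restricted Gaussian kernel with per-point adaptive
    bandwidth (distance to the ceil(k/2)-th neighbour); the kernel is
    symmetrized and row-normalized into a Markov matrix whose second right
    eigenvector is returned (unit norm, sign not fixed here).
    """
    n = emb.shape[0]
    if n < 3:
        raise ValueError("need >=3 rows for a diffusion component")
    k = min(n_neighbors, n - 1)
    D = squareform(pdist(np.asarray(emb, dtype=float)))
    order = np.argsort(D, axis=1, kind="stable")
    h = int(np.ceil(k / 2))
    sigma = D[np.arange(n), order[:, h]]
    pos = D[D > 0]
    fallback = float(pos.min()) if pos.size else 1.0
    sigma = np.where(sigma > 0, sigma, fallback)

    K = np.exp(-(D ** 2) / np.outer(sigma, sigma))
    mask = np.zeros_like(K, dtype=bool)
    rows = np.repeat(np.arange(n), k + 1)
    mask[rows, order[:, : k + 1].ravel()] = True
    mask |= mask.T  # union kNN graph, keeps the kernel symmetric
    K = np.where(mask, K, 0.0)

    d = K.sum(axis=1)
    d[d == 0] = 1.0
    A = K / np.sqrt(np.outer(d, d))  # symmetric conjugate of the Markov matrix
    w, V = np.linalg.eigh(A)
    phi = V[:, -2]  # second-largest eigenvalue = first nontrivial component
    dc1 = phi / np.sqrt(d)
    nrm = np.linalg.norm(dc1)
    return dc1 / nrm if nrm > 0 else dc1


def embed_responses(m: ResponseScoreMatrix, n_neighbors: int = 15) -> ResponseScoreMatrix:
    """PCA-embed response rows (kneepoint-selected dimensionality) and compute
    the first diffusion component; DC1 sign is fixed so the row with the
    largest L2 norm has a non-negative coordinate."""
    from sklearn.decomposition import PCA

    X = m.scores.to_numpy(dtype=float)
    n, g = X.shape
    if n < 3 or (X != 0).any(axis=0).sum() < 2:
        logger.warning("embedding skipped: need >=3 rows and >=2 nonzero columns")
        m.pc_embedding, m.n_pcs, m.dc1 = None, None, None
        return m
    pca = PCA(n_components=min(n - 1, g), svd_solver="full", random_state=0)
    scores = pca.fit_transform(X)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    m.n_pcs = kneepoint(cumvar)
    m.pc_embedding = scores[:, : m.n_pcs]
    dc1 = diffusion_dc1(m.pc_embedding, n_neighbors=n_neighbors)
    anchor = int(np.argmax(np.linalg.norm(X, axis=1)))
    if dc1[anchor] < 0:
        dc1 = -dc1
    m.dc1 = pd.Series(dc1, index=m.scores.index, name="dc1")
    return m
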