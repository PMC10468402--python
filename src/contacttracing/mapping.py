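"""Mapping inferred ligand effects and ligands to cellular subpopulations.

Subcluster markers come from one-vs-rest hurdle tests within a cell type.
A transcriptional response (one row of the response-score matrix) is assigned
to subclusters via the dot product between the response scores and the
FDR-masked marker log2FCs, standardized to the per-response maximum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .hurdle import DesignSpec, hurdle_lrt_table

logger = logging.getLogger(__name__)


def cluster_markers(ds: ExpressionDataset, cell_type: str, *,
                    min_detect_frac: float = 0.01, genes=None,
                    lfc_mode: str = "combined") -> pd.DataFrame:
    """One-vs-rest hurdle LRT per subcluster within a cell type.

    Design: Y ~ CDR + membership, dropping membership; BH FDR within each
    subcluster's gene family.  Returns columns (cell_type, subcluster, gene,
    log2fc, p, fdr).  Singleton subclusters are skipped with a warning.
    """
    sub = ds.cells_of_type(cell_type)
    if "subcluster" not in sub.obs.columns:
        raise ValueError(f"no subcluster annotations for cell type {cell_type!r}")
    clusters = sorted(sub.obs["subcluster"].dropna().unique())
    if len(clusters) < 2:
        raise ValueError(f"cell type {cell_type!r} has fewer than 2 subclusters")
    if genes is None:
        frac = sub.detection_fraction()
        genes = list(frac.index[frac >= min_detect_frac])
    idx = [sub.gene_index(g) for g in genes]
    Y = sub.lognorm[:, idx]

    frames = []
    for cl in clusters:
        member = (sub.obs["subcluster"] == cl).to_numpy()
        if member.sum() < 2:
            logger.warning("subcluster %s/%s skipped: singleton", cell_type, cl)
            continue
        obs = sub.obs.assign(member=member.astype(float)).reset_index(drop=True)
        spec = DesignSpec(covariates=[("cdr", "continuous"), ("member", "binary")],
                          contrast="member")
        X, contrast_cols = spec.build(obs)
        df = hurdle_lrt_table(Y, X, contrast_cols, genes, lfc_mode=lfc_mode)
        df.insert(0, "subcluster", cl)
        df.insert(0, "cell_type", cell_type)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def map_response_to_subclusters(score_row: pd.Series, markers: pd.DataFrame, *,
                                fdr_cut: float = 0.15,
                                assign_cut: float = 0.5) -> pd.DataFrame:
    """Assign a transcriptional response to subclusters by masked dot product.

    Marker log2FCs with FDR > ``fdr_cut`` are zeroed; the raw per-subcluster dot
    product with the response scores is standardized by its maximum, and
    subclusters with standardized score strictly greater than ``assign_cut`` are
    assigned (several subclusters may be).  If no raw dot product is positive,
    nothing is assigned.
    """
    rows = []
    for cl, grp in markers.groupby("subcluster", sort=True):
        lfc = grp.set_index("gene")["log2fc"].where(grp.set_index("gene")["fdr"] <= fdr_cut, 0.0)
        shared = lfc.index.intersection(score_row.index)
        raw = float(score_row.loc[shared] @ lfc.loc[shared])
        rows.append({"subcluster": cl, "raw": raw})
    out = pd.DataFrame(rows)
    mx = out["raw"].max()
    if mx > 0:
        out["standardized"] = out["raw"] / mx
    else:
        logger.warning("no positive dot product: nothing assigned")
        out["standardized"] = 0.0
    out["assigned"] = (out["standardized"] > assign_cut) & (mx > 0)
    return out


def assign_ligand_to_subclusters(ligand: str, markers: pd.DataFrame, *,
                                 fdr_cut: float = 0.15) -> set:
    """Subclusters where the ligand is positively enriched one-vs-rest
    (log2FC > 0 at FDR < ``fdr_cut``)."""
    rows = markers[markers["gene"] == ligand]
    if rows.empty:
        logger.warning("ligand %s untested in marker table", ligand)
        return set()
    hit = rows[(rows["fdr"] < fdr_cut) & (rows["log2fc"] > 0)]
    return set(hit["subcluster"])
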