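"""Copy-number-weighted Shannon diversity (CNV_SDI).

A per-sample karyotype-diversity index over inferred copy-number variant
states: each variant i carries a cell fraction freq_i and an alteration
magnitude delta_i (sum over genomic bins of |state - neutral|); the index is
the Shannon entropy of the normalized weights s_i = freq_i * delta_i / sum_j
freq_j * delta_j.  A sample dominated by one clone scores 0; n equally
frequent, equally altered clones score ln(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_NEUTRAL_STATE = 3  # centre state of a 6-state copy-number HMM
FREQ_TOL = 1e-6


def variant_delta(states, neutral_state: int = DEFAULT_NEUTRAL_STATE) -> float:
    """Alteration magnitude: sum over bins of |state - neutral|."""
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("states must be non-empty")
    return float(np.abs(states - neutral_state).sum())


@dataclass
class CNVVariantProfile:
    """One variant (clone) of a sample: per-bin states, frequency, magnitude."""

    variant_id: str
    freq: float
    states: np.ndarray | None = None
    neutral_state: int = DEFAULT_NEUTRAL_STATE
    delta: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError("freq must be in [0, 1]")
        if self.delta is None:
            if self.states is None:
                raise ValueError("provide either states or a precomputed delta")
            self.delta = variant_delta(self.states, self.neutral_state)
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


def cnv_sdi(variants) -> float:
    """Shannon diversity of variant states weighted by alteration magnitude.

    s_i = freq_i * delta_i / sum(freq * delta); returns sum of -s_i ln s_i.
    Zero-weight variants are dropped (0 ln 0 := 0); an entirely neutral sample
    is defined as 0 with a warning.
    """
    variants = list(variants)
    if not variants:
        raise ValueError("need at least one variant")
    freq = np.array([v.freq for v in variants], dtype=float)
    if abs(freq.sum() - 1.0) > FREQ_TOL:
        raise ValueError(f"variant frequencies sum to {freq.sum():.6f}, expected 1")
    w = freq * np.array([v.delta for v in variants], dtype=float)
    w = w[w > 0]
    if w.size == 0:
        logger.warning("all variants neutral or absent: CNV_SDI defined as 0")
        return 0.0
    s = w / w.sum()
    return float(-(s * np.log(s)).sum()) + 0.0


def profiles_from_assignments(assignments: pd.DataFrame, state_matrix: pd.DataFrame,
                              neutral_state: int = DEFAULT_NEUTRAL_STATE) -> list:
    """Derive variant profiles from cell-level variant assignments.

    ``assignments`` has columns (cell_id, variant_id); ``state_matrix`` is
    variant_id x genomic bins of integer states.  Frequencies are cell
    proportions; deltas come from the state matrix.
    """
    counts = assignments["variant_id"].value_counts()
    total = counts.sum()
    out = []
    for vid, n in counts.sort_index().items():
        if vid not in state_matrix.index:
            raise KeyError(f"variant {vid!r} missing from state matrix")
        out.append(CNVVariantProfile(
            variant_id=str(vid), freq=n / total,
            states=state_matrix.loc[vid].to_numpy(),
            neutral_state=neutral_state,
        ))
    return out


def read_variant_table(path) -> list:
    """Read a per-variant TSV (variant_id, freq, delta) into profiles."""
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_id", "freq", "delta"):
        if col not in df.columns:
            raise ValueError(f"variant table missing column {col!r}")
    return [CNVVariantProfile(variant_id=str(r.variant_id), freq=float(r.freq),
                              delta=float(r.delta))
            for r in df.itertuples(index=False)]


def sdi_by_sample(tables: dict) -> pd.DataFrame:
    """CNV_SDI per sample from a mapping sample_id -> list of profiles."""
    rows = [{"sample_id": k, "cnv_sdi": cnv_sdi(v)} for k, v in sorted(tables.items())]
    return pd.DataFrame(rows)
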