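"""Compositional log2 fold-change activity scores.

Read counts from a pooled screen are compositional: a count is only
meaningful relative to the other guides sequenced in the same sample.
Scores here are therefore computed on centred log-ratio (CLR) transformed
proportions, and the activity score of a guide is the between-condition
difference of its CLR values (a non-parametric log2 fold change, the
expected value of a Dirichlet-multinomial posterior in Monte-Carlo mode).

Two estimators share one contract:

* point-estimate mode (``mc_instances=0``): proportions are the
  prior-smoothed maximum-likelihood estimates; fully deterministic and
  used as the closed-form oracle;
* Monte-Carlo mode: per instance, per sample, proportions are drawn from
  ``Dirichlet(counts + prior)``; the per-guide score is the median over
  instances of the between-condition CLR difference.

With ``orientation="active_positive"`` the sign is flipped for depletion
assays so that "more active" is always a larger score, matching the shared
scale of depletion and enrichment datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CONTROL, DEPLETION, EXPERIMENTAL, CountTable

__all__ = ["ScoringConfig", "clr", "score_diffbtw", "read_score_table", "write_score_table"]


@dataclass
class ScoringConfig:
    """Settings for :func:`score_diffbtw`.

    mc_instances
        Number of Dirichlet Monte-Carlo instances; 0 selects the
        deterministic point-estimate mode.
    prior
        Pseudo-count added to every cell (Dirichlet prior mass); the
        conventional 0.5 per cell by default.
    orientation
        ``"active_positive"`` flips the sign for depletion assays;
        ``"raw"`` reports experimental-minus-control unchanged.
    """

    mc_instances: int = 0
    prior: float = 0.5
    orientation: str = "active_positive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mc_instances < 0:
            raise ValueError("mc_instances must be >= 0")
        if self.prior <= 0:
            raise ValueError("prior must be > 0")
        if self.orientation not in ("active_positive", "raw"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


def clr(p: np.ndarray) -> np.ndarray:
    """Centred log-ratio transform in log base 2.

    clr_i = log2(p_i) - mean_j log2(p_j); the output sums to zero.  ``p``
    must be strictly positive (a simplex vector, or any positive vector:
    the transform is scale-invariant).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("clr requires strictly positive proportions")
    logp = np.log2(p)
    return logp - logp.mean(axis=-1, keepdims=True)


def _delta_from_proportions(p: np.ndarray, ctrl_idx: np.ndarray, exp_idx: np.ndarray) -> np.ndarray:
    """Between-condition CLR difference for a guides x samples proportion matrix."""
    c = clr(p.T).T  # CLR within each sample (column)
    return c[:, exp_idx].mean(axis=1) - c[:, ctrl_idx].mean(axis=1)


def score_diffbtw(table: CountTable, config: ScoringConfig | None = None) -> pd.DataFrame:
    """Per-guide log2FC activity scores plus mean control read counts.

    Returns a DataFrame indexed by guide id with columns ``score`` (log2
    units) and ``mean_control_count`` (mean raw control-condition count).
    Deterministic for a fixed ``config.seed``.
    """
    config = config or ScoringConfig()
    n = table.counts.to_numpy(dtype=float)
    samples = table.sample_ids
    ctrl_idx = np.array([i for i, s in enumerate(samples) if table.conditions[s] == CONTROL])
    exp_idx = np.array([i for i, s in enumerate(samples) if table.conditions[s] == EXPERIMENTAL])

    if config.mc_instances == 0:
        p = n + config.prior
        p = p / p.sum(axis=0, keepdims=True)
        delta = _delta_from_proportions(p, ctrl_idx, exp_idx)
    else:
        rng = np.random.default_rng(config.seed)
        deltas = np.empty((config.mc_instances, n.shape[0]))
        alpha = n + config.prior
        for k in range(config.mc_instances):
            p = np.column_stack([rng.dirichlet(alpha[:, s]) for s in range(n.shape[1])])
            deltas[k] = _delta_from_proportions(p, ctrl_idx, exp_idx)
        delta = np.median(deltas, axis=0)

    if config.orientation == "active_positive" and table.direction == DEPLETION:
        delta = -delta

    return pd.DataFrame(
        {
            "score": delta,
            "mean_control_count": table.mean_control_counts().to_numpy(),
        },
        index=pd.Index(table.guide_ids, name="guide_id"),
    )


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    scores.rename_axis("guide_id").to_csv(path, sep="\t")


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="guide_id")
    df.index = df.index.astype(str)
    if not np.isfinite(df["score"]).all():
        raise ValueError("score table contains non-finite scores")
    return df
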