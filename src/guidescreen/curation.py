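"""Minimum control-read-count curation.

Low control-condition read counts make log2FC activity scores imprecise
and compress their dynamic range (a guide seen once in the control can at
best halve away).  Curation removes guides whose mean control count falls
below a cutoff ``C``; the sweep re-scores, re-encodes and cross-validates
a regressor at every cutoff in a range to find the value that best trades
data volume for score accuracy.

Order of operations matters: scores are *recomputed* on each filtered
table (the CLR denominator changes with the retained guide set), never
subset from the unfiltered scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import WindowSpec, encode_dataset, split_dataset
from .core import CountTable, Genome, TargetSite
from .evaluation import _derive_seed, cross_validate
from .model import build_linear
from .scoring import ScoringConfig, score_diffbtw

__all__ = ["apply_cutoff", "sweep_cutoff", "CutoffSweepResult", "SweepEvalSpec"]


def apply_cutoff(table: CountTable, cutoff: float) -> CountTable:
    """Retain guides whose mean control-condition count is >= cutoff (samples unchanged)."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    keep = table.mean_control_counts() >= cutoff
    return table.subset_guides(table.counts.index[keep])


@dataclass
class SweepEvalSpec:
    """How each cutoff (or length) variant is evaluated.

    A fresh regressor is built per fold via ``make_regressor`` (defaults
    to the ridge surrogate); the 80/20 held-out test fraction is re-drawn
    per variant from a sub-seed derived from ``(seed, variant)`` and is
    excluded from all cross-validation.
    """

    genome: Genome
    sites: list[TargetSite]
    window: WindowSpec = field(default_factory=lambda: WindowSpec(3, True, 11))
    make_regressor: object = None
    folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0

    def regressor_factory(self):
        if self.make_regressor is not None:
            return self.make_regressor
        return lambda _seed=None: build_linear(alpha=1.0)


@dataclass
class CutoffSweepResult:
    entries: pd.DataFrame
    # columns: cutoff, n_retained, spearman_mean, spearman_sd, pearson_mean, valid
    chosen_cutoff: int | None

    def entry(self, cutoff: int) -> pd.Series:
        return self.entries.set_index("cutoff").loc[cutoff]


def sweep_cutoff(
    table: CountTable,
    c_range,
    scoring: ScoringConfig,
    eval_spec: SweepEvalSpec,
) -> CutoffSweepResult:
    """Cross-validated model performance at each control-count cutoff.

    For every ``C`` in ``c_range``: filter the count table, recompute
    scores on the filtered table, encode windows, split off the held-out
    test fraction, and k-fold cross-validate the regressor on the
    training portion.  The chosen cutoff maximizes mean CV Spearman, ties
    resolved toward the smallest ``C`` (less data discarded).  Cutoffs
    that empty the table (or leave fewer guides than folds) are recorded
    as invalid and excluded from the argmax.
    """
    c_values = list(c_range)
    if not c_values:
        raise ValueError("empty cutoff range")
    factory = eval_spec.regressor_factory()
    rows = []
    for c in c_values:
        filtered = apply_cutoff(table, c)
        n_retained = len(filtered.counts)
        min_needed = max(eval_spec.folds, 2)
        if n_retained == 0 or n_retained * (1 - eval_spec.test_fraction) < min_needed:
            rows.append(
                {"cutoff": c, "n_retained": n_retained, "spearman_mean": np.nan,
                 "spearman_sd": np.nan, "pearson_mean": np.nan, "valid": False}
            )
            continue
        scores = score_diffbtw(filtered, scoring)
        ds = encode_dataset(eval_spec.genome, eval_spec.sites, scores, eval_spec.window)
        # sub-seed keyed by the retained guide set: variants that change the data
        # re-split independently, while inert cutoffs reproduce identical metrics
        sub_seed = _derive_seed(eval_spec.seed, "cutoff", ",".join(filtered.guide_ids))
        ds, _ = split_dataset(ds, test_fraction=eval_spec.test_fraction, seed=sub_seed)
        cv = cross_validate(ds.train_subset(), factory, k=eval_spec.folds, seed=sub_seed)
        rows.append(
            {
                "cutoff": c,
                "n_retained": n_retained,
                "spearman_mean": cv.spearman_mean,
                "spearman_sd": cv.spearman_sd,
                "pearson_mean": cv.pearson_mean,
                "valid": True,
            }
        )
    entries = pd.DataFrame(rows)
    valid = entries[entries["valid"]]
    chosen = None
    if not valid.empty and valid["spearman_mean"].notna().any():
        best = valid["spearman_mean"].max()
        # ties toward the smallest cutoff
        chosen = int(valid.loc[valid["spearman_mean"] >= best - 1e-12, "cutoff"].min())
    return CutoffSweepResult(entries=entries, chosen_cutoff=chosen)
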