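"""Cross-validated performance metrics and diagnostic analyses.

Covers the three data diagnostics of the pipeline: flank-length sweeps
(how much upstream/downstream context helps prediction), positional
di-nucleotide score profiles (where in and around the target the activity
information lives), and prediction error stratified by control read count
(how score imprecision at low counts degrades predictions).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .context import EncodedDataset, WindowSpec, encode_dataset, split_dataset
from .core import Genome, TargetSite

__all__ = [
    "CVResult",
    "LengthSweepResult",
    "cross_validate",
    "sweep_lengths",
    "dinuc_profile",
    "DinucProfile",
    "error_by_count",
    "default_count_bins",
]

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rho; NaN (flagged missing) when either vector is constant."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.spearmanr(a, b).statistic)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.pearsonr(a, b).statistic)


@dataclass
class CVResult:
    """Per-fold and aggregate Spearman/Pearson correlations."""

    k: int
    seed: int
    fold_spearman: list[float]
    fold_pearson: list[float]

    @property
    def spearman_mean(self) -> float:
        return float(np.nanmean(self.fold_spearman))

    @property
    def spearman_sd(self) -> float:
        return float(np.nanstd(self.fold_spearman, ddof=1))

    @property
    def pearson_mean(self) -> float:
        return float(np.nanmean(self.fold_pearson))

    @property
    def n_missing_folds(self) -> int:
        return int(np.sum(np.isnan(self.fold_spearman)))


def cross_validate(dataset, make_regressor, k: int = 5, seed: int = 0) -> CVResult:
    """k-fold cross-validated correlation between predictions and labels.

    ``dataset`` is an :class:`EncodedDataset` (or an ``(X, y)`` pair);
    ``make_regressor`` is a zero- or one-argument callable returning a
    fresh fit/predict regressor (the argument, when accepted, is a
    per-fold seed).  Folds are disjoint, seeded, and cover every guide
    exactly once.  Constant predictions give a missing (NaN) fold metric.
    """
    if isinstance(dataset, EncodedDataset):
        X, y = dataset.X, dataset.y
    else:
        X, y = dataset
    n = X.shape[0]
    if k > n:
        raise ValueError(f"cannot form {k} folds from {n} samples")
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32 - 1))
    sp, pe = [], []
    for fold, (tr, va) in enumerate(kf.split(X)):
        try:
            reg = make_regressor(seed * 1000 + fold)
        except TypeError:
            reg = make_regressor()
        reg.fit(X[tr], y[tr])
        pred = reg.predict(X[va])
        sp.append(_safe_spearman(pred, y[va]))
        pe.append(_safe_pearson(pred, y[va]))
    return CVResult(k=k, seed=seed, fold_spearman=sp, fold_pearson=pe)


@dataclass
class LengthSweepResult:
    """Flank-length sweep: CV performance per extension vs the spacer-only baseline."""

    mode: str  # 'upstream' or 'downstream'
    baseline_spearman: float
    baseline_sd: float
    entries: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: extension, n, spearman_mean, spearman_sd, pearson_mean, delta_vs_baseline


def _derive_seed(*parts) -> int:
    """Stable sub-seed from a tuple of labels (independent of hash randomization)."""
    s = "|".join(map(str, parts))
    return zlib.crc32(s.encode("utf-8")) % (2**31)


def sweep_lengths(
    genome: Genome,
    sites: list[TargetSite],
    labels,
    mode: str,
    max_ext: int,
    make_regressor,
    k: int = 5,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> LengthSweepResult:
    """CV performance as a function of appended flank length.

    ``mode="upstream"`` evaluates windows of ``u`` upstream nucleotides
    plus the bare spacer (no PAM) for ``u`` in 0..max_ext; with
    ``mode="downstream"`` the PAM is always included and ``d`` nucleotides
    beyond it are appended for ``d`` in 0..max_ext.  Both curves are
    reported as deltas against the shared spacer-only baseline
    (U=0, no PAM, D=0).  The held-out test fraction is excluded from every
    evaluation.
    """
    if mode not in ("upstream", "downstream"):
        raise ValueError(f"mode must be 'upstream' or 'downstream', got {mode!r}")

    def evaluate(spec: WindowSpec) -> tuple[int, CVResult]:
        # seed keyed by the window geometry itself, so identical specs get
        # identical splits and the upstream ext=0 entry reproduces the baseline
        ds = encode_dataset(genome, sites, labels, spec)
        sub_seed = _derive_seed(seed, spec.upstream, spec.include_pam, spec.downstream)
        ds, _ = split_dataset(ds, test_fraction=test_fraction, seed=sub_seed)
        train = ds.train_subset()
        return len(train), cross_validate(train, make_regressor, k=k, seed=sub_seed)

    _, base = evaluate(WindowSpec(0, False, 0))
    rows = []
    for ext in range(max_ext + 1):
        if mode == "upstream":
            spec = WindowSpec(upstream=ext, include_pam=False, downstream=0)
        else:
            spec = WindowSpec(upstream=0, include_pam=True, downstream=ext)
        n, cv = evaluate(spec)
        rows.append(
            {
                "extension": ext,
                "n": n,
                "spearman_mean": cv.spearman_mean,
                "spearman_sd": cv.spearman_sd,
                "pearson_mean": cv.pearson_mean,
                "delta_vs_baseline": cv.spearman_mean - base.spearman_mean,
            }
        )
    return LengthSweepResult(
        mode=mode,
        baseline_spearman=base.spearman_mean,
        baseline_sd=base.spearman_sd,
        entries=pd.DataFrame(rows),
    )


@dataclass
class DinucProfile:
    """Mean label per (PAM-relative position, di-nucleotide), with per-cell n."""

    means: pd.DataFrame  # index: 16 dinucleotides; columns: positions
    counts: pd.DataFrame


def dinuc_profile(windows: list[str], labels: np.ndarray, positions, spacer_offset: int) -> DinucProfile:
    """Mean activity label per di-nucleotide at each PAM-relative position.

    Position 0 is the first PAM base; the di-nucleotide at position ``p``
    occupies window indices ``spacer_offset + 20 + p`` and the next base.
    Every window must cover all requested positions.
    """
    labels = np.asarray(labels, dtype=float)
    if len(windows) != len(labels):
        raise ValueError("windows and labels differ in length")
    positions = list(positions)
    if not windows:
        raise ValueError("empty window list")
    width = len(windows[0])
    pam0 = spacer_offset + 20
    for p in positions:
        if pam0 + p < 0 or pam0 + p + 2 > width:
            raise ValueError(f"position {p} falls outside the {width}-nt windows")
    arr = np.frombuffer("".join(windows).encode("ascii"), dtype=np.uint8).reshape(len(windows), width)
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    coded = code[arr]
    means = pd.DataFrame(index=DINUCLEOTIDES, columns=positions, dtype=float)
    counts = pd.DataFrame(0, index=DINUCLEOTIDES, columns=positions, dtype=int)
    for p in positions:
        j = pam0 + p
        di = coded[:, j] * 4 + coded[:, j + 1]
        sums = np.bincount(di, weights=labels, minlength=16)
        ns = np.bincount(di, minlength=16)
        with np.errstate(invalid="ignore"):
            means[p] = sums / np.where(ns == 0, np.nan, ns)
        counts[p] = ns
    return DinucProfile(means=means, counts=counts)


def default_count_bins(max_count: float) -> list[float]:
    """Integer-width bins up to 20, then 5-wide bins up to the maximum count."""
    edges = [float(e) for e in range(1, 21)]
    e = 25.0
    while e < max_count + 5:
        edges.append(e)
        e += 5.0
    return edges


def error_by_count(
    predictions: pd.Series,
    scores: pd.DataFrame,
    bins: list[float] | None = None,
) -> pd.DataFrame:
    """Absolute prediction error per mean-control-count bin, split by sign.

    ``predictions`` and the score table are aligned by guide id; unmatched
    ids raise.  Returns one row per occupied bin with the overall mean
    absolute error and the MAE restricted to positive / negative
    predictions (NaN where a stratum is empty).
    """
    missing = predictions.index.difference(scores.index)
    if len(missing):
        raise ValueError(f"predictions contain unmatched guide ids (e.g. {missing[0]!r})")
    sub = scores.loc[predictions.index]
    err = (predictions - sub["score"]).abs()
    counts = sub["mean_control_count"]
    if bins is None:
        bins = default_count_bins(float(counts.max()))
    binned = pd.cut(counts, bins=bins, include_lowest=True, right=False)
    rows = []
    for interval, idx in err.groupby(binned, observed=True).groups.items():
        e = err.loc[idx]
        pos = predictions.loc[idx] > 0
        rows.append(
            {
                "bin_left": interval.left,
                "bin_right": interval.right,
                "n": len(idx),
                "mae": float(e.mean()),
                "n_positive": int(pos.sum()),
                "mae_positive": float(e[pos].mean()) if pos.any() else float("nan"),
                "n_negative": int((~pos).sum()),
                "mae_negative": float(e[~pos].mean()) if (~pos).any() else float("nan"),
            }
        )
    return pd.DataFrame(rows).sort_values("bin_left").reset_index(drop=True)
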