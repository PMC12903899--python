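"""Target-site windows, one-hot encoding, and leakage-checked splits.

A model input window is, in spacer orientation (5'->3' as the sgRNA reads
the target strand): ``U`` upstream nucleotides, the 20-nt spacer, the 3-nt
PAM if included, and ``D`` nucleotides downstream of the PAM, for a total
length of ``U + 20 + 3*include_pam + D``.  Windows are encoded as 4 x N
one-hot matrices with row order A, C, G, T.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PAM_LENGTH, SPACER_LENGTH, Genome, TargetSite

__all__ = [
    "WindowSpec",
    "EncodedDataset",
    "LeakageReport",
    "extract_window",
    "one_hot",
    "decode_one_hot",
    "encode_dataset",
    "split_dataset",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_INDEX_BASE = np.array(list("ACGT"))


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry: U upstream nt, the spacer, optional PAM, D downstream nt."""

    upstream: int = 0
    include_pam: bool = True
    downstream: int = 0

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("flank lengths must be >= 0")
        if self.downstream > 0 and not self.include_pam:
            raise ValueError("downstream nucleotides sit beyond the PAM; include_pam is required")

    @property
    def length(self) -> int:
        return self.upstream + SPACER_LENGTH + (PAM_LENGTH if self.include_pam else 0) + self.downstream

    @property
    def spacer_offset(self) -> int:
        """Index of the first spacer base within the window (== upstream)."""
        return self.upstream


def extract_window(genome: Genome, site: TargetSite, spec: WindowSpec) -> str:
    """Window sequence for one site, in spacer orientation.

    For minus-strand sites this equals the reverse complement of the
    corresponding plus-strand reference slice.  Raises if the window would
    cross the contig boundary.
    """
    oriented = genome.oriented(site.strand)
    start = site.spacer_start - spec.upstream
    end = site.spacer_start + SPACER_LENGTH + (PAM_LENGTH if spec.include_pam else 0) + spec.downstream
    if start < 0 or end > len(oriented):
        raise ValueError(f"window for site {site.guide_id} crosses the contig boundary")
    return oriented[start:end]


def one_hot(seq: str) -> np.ndarray:
    """4 x N one-hot matrix (row order A, C, G, T) for an unambiguous DNA string."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise ValueError(f"cannot one-hot encode non-ACGT character {bad!r}")
    mat = np.zeros((4, len(seq)))
    mat[codes, np.arange(len(seq))] = 1.0
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != 4 or not np.allclose(mat.sum(axis=0), 1.0):
        raise ValueError("expected a 4 x N one-hot matrix with unit column sums")
    return "".join(_INDEX_BASE[mat.argmax(axis=0)])


@dataclass
class EncodedDataset:
    """Per-guide window sequences, 4 x N one-hot encodings and score labels."""

    guide_ids: list[str]
    windows: list[str]
    X: np.ndarray  # (n, 4, N)
    y: np.ndarray  # (n,)
    spec: WindowSpec
    split: np.ndarray | None = None  # 'train' / 'test' per guide, or None

    def __post_init__(self) -> None:
        n = len(self.guide_ids)
        if not (len(self.windows) == self.X.shape[0] == self.y.shape[0] == n):
            raise ValueError("inconsistent dataset lengths")
        if n and self.X.shape[1:] != (4, self.spec.length):
            raise ValueError(
                f"encoding shape {self.X.shape[1:]} does not match window spec length {self.spec.length}"
            )

    def __len__(self) -> int:
        return len(self.guide_ids)

    def subset(self, mask: np.ndarray) -> "EncodedDataset":
        idx = np.nonzero(np.asarray(mask))[0]
        return EncodedDataset(
            guide_ids=[self.guide_ids[i] for i in idx],
            windows=[self.windows[i] for i in idx],
            X=self.X[idx],
            y=self.y[idx],
            spec=self.spec,
            split=self.split[idx] if self.split is not None else None,
        )

    def train_subset(self) -> "EncodedDataset":
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        return self.subset(self.split == "train")

    def test_subset(self) -> "EncodedDataset":
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        return self.subset(self.split == "test")

    def spacers(self) -> list[str]:
        off = self.spec.spacer_offset
        return [w[off : off + SPACER_LENGTH] for w in self.windows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": self.windows,
                "score": self.y,
                "split": self.split if self.split is not None else [""] * len(self),
            },
            index=pd.Index(self.guide_ids, name="guide_id"),
        )


def encode_dataset(
    genome: Genome,
    sites: list[TargetSite],
    labels,
    spec: WindowSpec,
) -> EncodedDataset:
    """Build an encoded dataset for the sites present in ``labels``.

    ``labels`` is a mapping (or a score-table DataFrame with a ``score``
    column) from guide id to its activity score; sites without a label are
    skipped, so a curated score table automatically restricts the dataset.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels["score"].to_dict()
    guide_ids, windows, mats, ys = [], [], [], []
    for site in sites:
        if site.guide_id not in labels:
            continue
        w = extract_window(genome, site, spec)
        guide_ids.append(site.guide_id)
        windows.append(w)
        mats.append(one_hot(w))
        ys.append(float(labels[site.guide_id]))
    X = np.stack(mats) if mats else np.empty((0, 4, spec.length))
    return EncodedDataset(guide_ids=guide_ids, windows=windows, X=X, y=np.array(ys), spec=spec)


@dataclass
class LeakageReport:
    """Train/test sequence-similarity diagnostics for one split."""

    n_duplicates_removed: int
    cross_split_duplicate_windows: int
    min_spacer_hamming: int | None
    hamming_counts: dict[int, int] = field(default_factory=dict)


def _hamming_cross(a: list[str], b: list[str]) -> np.ndarray:
    """Pairwise hamming distance matrix between two equal-length string sets."""
    aa = np.frombuffer("".join(a).encode("ascii"), dtype=np.uint8).reshape(len(a), -1)
    bb = np.frombuffer("".join(b).encode("ascii"), dtype=np.uint8).reshape(len(b), -1)
    out = np.empty((len(a), len(b)), dtype=np.int32)
    chunk = max(1, 2_000_000 // max(1, len(b)))
    for i in range(0, len(a), chunk):
        out[i : i + chunk] = (aa[i : i + chunk, None, :] != bb[None, :, :]).sum(axis=2)
    return out


def split_dataset(
    dataset: EncodedDataset,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[EncodedDataset, LeakageReport]:
    """Deduplicate by window sequence, then split into train and held-out test.

    Exact duplicate windows are removed before splitting (first occurrence
    kept) so no identical input can appear in both splits.  The test set
    holds ``floor(n * test_fraction)`` guides.  The report summarizes the
    pairwise hamming distances between test and train spacers so near-
    duplicates can be audited; no filtering beyond exact-duplicate removal
    is applied.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    seen: dict[str, int] = {}
    keep = []
    for i, w in enumerate(dataset.windows):
        if w not in seen:
            seen[w] = i
            keep.append(i)
    n_dup = len(dataset) - len(keep)
    ds = dataset.subset(np.isin(np.arange(len(dataset)), keep))
    n = len(ds)
    if n < 2:
        raise ValueError("fewer than 2 unique windows after deduplication")
    n_test = int(np.floor(n * test_fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.full(n, "train", dtype=object)
    split[order[:n_test]] = "test"
    ds.split = split

    test_sp = [s for s, tag in zip(ds.spacers(), split) if tag == "test"]
    train_sp = [s for s, tag in zip(ds.spacers(), split) if tag == "train"]
    if test_sp and train_sp:
        dist = _hamming_cross(test_sp, train_sp)
        per_test_min = dist.min(axis=1)
        values, counts = np.unique(per_test_min, return_counts=True)
        report = LeakageReport(
            n_duplicates_removed=n_dup,
            cross_split_duplicate_windows=int(
                sum(1 for w in set(ds.windows) if
                    {tag for ww, tag in zip(ds.windows, split) if ww == w} == {"train", "test"})
            ),
            min_spacer_hamming=int(dist.min()),
            hamming_counts={int(v): int(c) for v, c in zip(values, counts)},
        )
    else:
        report = LeakageReport(n_dup, 0, None)
    return ds, report


def write_windows_fasta(dataset: EncodedDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, w in zip(dataset.guide_ids, dataset.windows):
            fh.write(f">{gid}\n{w}\n")
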