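"""Shared containers for pooled sgRNA/Cas9 screen data.

Coordinate conventions used throughout the package:

* Reference coordinates are 0-based, half-open, on the ``+`` strand.
* A :class:`TargetSite` stores its spacer offset *in the orientation of its
  own strand*: for a ``-`` strand site, ``spacer_start`` indexes into the
  reverse complement of the contig.  This makes window extraction a single
  slice regardless of strand.
* Positions relative to a site are indexed from the first PAM base
  (position 0).  The 20-nt spacer occupies positions -20..-1, the PAM
  occupies 0..2 and downstream flanking bases start at position 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DNA_ALPHABET = "ACGT"
SPACER_LENGTH = 20
PAM_LENGTH = 3

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

CONTROL = "control"
EXPERIMENTAL = "experimental"
DEPLETION = "depletion"
ENRICHMENT = "enrichment"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A single linear contig restricted to the unambiguous A/C/G/T alphabet."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        if set(self.sequence) - set(DNA_ALPHABET):
            bad = sorted(set(self.sequence) - set(DNA_ALPHABET))
            raise ValueError(f"genome contains non-ACGT characters: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    def oriented(self, strand: str) -> str:
        """Contig sequence as read on the given strand (5'->3')."""
        if strand == "+":
            return self.sequence
        if strand == "-":
            return reverse_complement(self.sequence)
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class TargetSite:
    """One NGG-adjacent Cas9 target: 20-nt spacer plus its 3-nt PAM.

    ``spacer_start`` is the 0-based offset of the spacer on the *oriented*
    contig (see module docstring), so the PAM occupies
    ``spacer_start + 20 .. spacer_start + 23`` on that same orientation.
    """

    guide_id: str
    contig_id: str
    strand: str
    spacer_start: int
    spacer: str
    pam: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError(f"spacer must be {SPACER_LENGTH} nt, got {len(self.spacer)}")
        if len(self.pam) != PAM_LENGTH or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")

    @property
    def pam_start(self) -> int:
        return self.spacer_start + SPACER_LENGTH


@dataclass
class CountTable:
    """Integer read counts, guides x samples, with per-sample condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by guide id with one column per sample id.
    conditions
        Mapping from sample id to ``"control"`` or ``"experimental"``; must
        cover exactly the columns of ``counts``.
    direction
        ``"depletion"`` (active guides lose reads under selection) or
        ``"enrichment"`` (active guides gain reads).
    """

    counts: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)
    direction: str = DEPLETION

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate guide ids in count table")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integral")
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if set(self.conditions) != set(c.columns):
            raise ValueError("condition labels must cover exactly the sample ids")
        bad = {v for v in self.conditions.values()} - {CONTROL, EXPERIMENTAL}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if CONTROL not in self.conditions.values() or EXPERIMENTAL not in self.conditions.values():
            raise ValueError("need at least one control and one experimental sample")
        if self.direction not in (DEPLETION, ENRICHMENT):
            raise ValueError(f"direction must be depletion or enrichment, got {self.direction!r}")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def mean_control_counts(self) -> pd.Series:
        """Mean raw read count per guide over the control samples."""
        return self.counts[self.samples_for(CONTROL)].mean(axis=1)

    def subset_guides(self, guide_ids) -> "CountTable":
        return CountTable(
            counts=self.counts.loc[list(guide_ids)].copy(),
            conditions=dict(self.conditions),
            direction=self.direction,
        )
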