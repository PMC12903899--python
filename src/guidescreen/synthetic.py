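"""Synthetic pooled sgRNA/Cas9 screen generator.

Emulates the statistical structure of bacterial killing-efficiency screens:
a pooled library of 20-nt spacers targeting NGG-adjacent sites on both
strands of a genome, a skewed (log-normal) initial library composition,
sequencing of replicate control and selected samples as multinomial draws
at a configured depth, and selection that multiplicatively re-weights
guide abundance by ``2^(-k * activity)`` (depletion: active guides are
lost) or ``2^(+k * activity)`` (enrichment: active guides grow).

Ground-truth activity is planted as positional di-nucleotide preferences
around the PAM plus an optional AT-richness penalty on a flanking window,
so downstream analyses (di-nucleotide profiles, flank-length sweeps,
sequence regression) have a known signal to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CONTROL,
    DEPLETION,
    ENRICHMENT,
    EXPERIMENTAL,
    PAM_LENGTH,
    SPACER_LENGTH,
    CountTable,
    Genome,
    TargetSite,
)

__all__ = [
    "ActivityModel",
    "ScreenConfig",
    "generate_genome",
    "enumerate_targets",
    "assign_true_activity",
    "simulate_screen",
    "default_activity_model",
    "write_genome_fasta",
    "write_sites_tsv",
    "write_activities_tsv",
]


@dataclass
class ActivityModel:
    """Planted sequence-to-activity map.

    ``positional_weights`` maps ``(position, dinucleotide)`` to an additive
    log2-activity contribution, where position is relative to the first PAM
    base (spacer = -20..-1, PAM = 0..2, downstream >= 3) and the
    di-nucleotide occupies ``(position, position + 1)``.  ``at_flank_penalty``
    is added per unit AT-fraction measured over ``at_flank_window``
    (half-open, same coordinates).  Gaussian noise of sd ``noise_sd`` is
    added per site, seeded for reproducibility.
    """

    baseline: float = 0.0
    positional_weights: dict[tuple[int, str], float] = field(default_factory=dict)
    at_flank_penalty: float = 0.0
    at_flank_window: tuple[int, int] = (3, 53)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for (pos, dinuc), w in self.positional_weights.items():
            if len(dinuc) != 2:
                raise ValueError(f"weights are di-nucleotide keyed; got {dinuc!r}")
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight at ({pos}, {dinuc})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def required_span(self) -> tuple[int, int]:
        """Half-open PAM-relative interval the model needs to evaluate a site."""
        lo, hi = 0, PAM_LENGTH
        for pos, _ in self.positional_weights:
            lo, hi = min(lo, pos), max(hi, pos + 2)
        if self.at_flank_penalty != 0.0:
            lo, hi = min(lo, self.at_flank_window[0]), max(hi, self.at_flank_window[1])
        return lo, hi


@dataclass
class ScreenConfig:
    """Replicate structure, depth and selection strength of one screen.

    Defaults mirror a deep depletion screen: a single pre-selection control
    replicate, several selected replicates, and a few-hundred-fold mean
    read coverage per guide.
    """

    n_control: int = 1
    n_experimental: int = 9
    depth: int = 500_000
    abundance_dispersion: float = 1.0
    selection_strength: float = 1.0
    direction: str = DEPLETION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_experimental < 1:
            raise ValueError("need at least one control and one experimental replicate")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.selection_strength < 0:
            raise ValueError("selection strength k must be >= 0")
        if self.abundance_dispersion < 0:
            raise ValueError("abundance dispersion must be >= 0")
        if self.direction not in (DEPLETION, ENRICHMENT):
            raise ValueError(f"direction must be depletion or enrichment, got {self.direction!r}")


def generate_genome(length: int, gc: float = 0.5, seed: int = 0, contig_id: str = "contig_1") -> Genome:
    """Random linear contig with the requested expected G+C fraction."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return Genome(contig_id=contig_id, sequence=bases.tobytes().decode("ascii"))


def _scan_oriented(seq: str, strand: str, contig_id: str, max_flank: int) -> list[TargetSite]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_g = arr == ord("G")
    n = len(arr)
    sites: list[TargetSite] = []
    # PAM at [p, p+3): require GG at p+1, p+2 and a full 20-nt spacer 5' of it.
    gg = is_g[1:-1] & is_g[2:]
    for p in np.nonzero(gg)[0]:
        start = int(p) - SPACER_LENGTH
        if start - max_flank < 0:
            continue
        if p + PAM_LENGTH + max_flank > n:
            continue
        sites.append(
            TargetSite(
                guide_id=f"{contig_id}:{strand}:{start}",
                contig_id=contig_id,
                strand=strand,
                spacer_start=start,
                spacer=seq[start : start + SPACER_LENGTH],
                pam=seq[p : p + PAM_LENGTH],
            )
        )
    return sites


def enumerate_targets(genome: Genome, max_flank: int = 0) -> list[TargetSite]:
    """Every 20-nt protospacer 5' of an NGG, on both strands.

    Sites whose ``spacer +/- max_flank`` window (upstream of the spacer or
    downstream of the PAM) would cross the contig boundary are dropped, so
    every returned site supports window extraction up to ``max_flank``.
    Minus-strand sites are reported in spacer orientation (coordinates on
    the reverse complement of the contig).
    """
    if max_flank < 0:
        raise ValueError("max_flank must be >= 0")
    plus = _scan_oriented(genome.sequence, "+", genome.contig_id, max_flank)
    minus = _scan_oriented(genome.oriented("-"), "-", genome.contig_id, max_flank)
    return plus + minus


def _site_context(genome: Genome, site: TargetSite, lo: int, hi: int) -> str:
    """Sequence covering PAM-relative positions [lo, hi) in spacer orientation."""
    oriented = genome.oriented(site.strand)
    start = site.pam_start + lo
    end = site.pam_start + hi
    if start < 0 or end > len(oriented):
        raise ValueError(
            f"site {site.guide_id}: required context [{lo}, {hi}) relative to the PAM "
            "falls outside the contig"
        )
    return oriented[start:end]


def assign_true_activity(genome: Genome, sites: list[TargetSite], model: ActivityModel) -> dict[str, float]:
    """Planted ground-truth activity for each site (log2 activity units).

    activity = baseline + sum of matched positional di-nucleotide weights
    + at_flank_penalty * AT-fraction(flank window) + Normal(0, noise_sd).
    Deterministic for a fixed ``model.seed`` and site order.
    """
    lo, hi = model.required_span()
    rng = np.random.default_rng(model.seed)
    noise = rng.normal(0.0, model.noise_sd, size=len(sites)) if model.noise_sd > 0 else np.zeros(len(sites))
    out: dict[str, float] = {}
    for i, site in enumerate(sites):
        ctx = _site_context(genome, site, lo, hi)
        a = model.baseline
        for (pos, dinuc), w in model.positional_weights.items():
            j = pos - lo
            if ctx[j : j + 2] == dinuc:
                a += w
        if model.at_flank_penalty != 0.0:
            w0, w1 = model.at_flank_window
            flank = ctx[w0 - lo : w1 - lo]
            at_frac = sum(1 for b in flank if b in "AT") / len(flank)
            a += model.at_flank_penalty * at_frac
        out[site.guide_id] = float(a + noise[i])
    return out


def simulate_screen(
    sites: list[TargetSite],
    activities: dict[str, float],
    config: ScreenConfig,
) -> CountTable:
    """Replicate control/selected read-count table for a guide library.

    Initial library proportions are log-normal(0, dispersion) renormalized;
    each control sample is an independent ``multinomial(depth, p0)`` draw;
    each experimental sample re-weights ``p0`` by ``2^(-k * activity)``
    (depletion) or ``2^(+k * activity)`` (enrichment), renormalizes, and
    draws ``multinomial(depth, p_sel)``.  One child random stream per
    sample, all descended from ``config.seed``.
    """
    if not sites:
        raise ValueError("cannot simulate a screen with an empty site list")
    missing = [s.guide_id for s in sites if s.guide_id not in activities]
    if missing:
        raise ValueError(f"activities missing for {len(missing)} sites (e.g. {missing[0]})")
    guide_ids = [s.guide_id for s in sites]
    act = np.array([activities[g] for g in guide_ids], dtype=float)

    master = np.random.SeedSequence(config.seed)
    init_ss, samples_ss = master.spawn(2)
    rng0 = np.random.default_rng(init_ss)
    raw = rng0.lognormal(mean=0.0, sigma=config.abundance_dispersion, size=len(sites))
    p0 = raw / raw.sum()

    sign = -1.0 if config.direction == DEPLETION else 1.0
    w = p0 * np.power(2.0, sign * config.selection_strength * act)
    p_sel = w / w.sum()

    sample_ids: list[str] = []
    conditions: dict[str, str] = {}
    columns: list[np.ndarray] = []
    streams = samples_ss.spawn(config.n_control + config.n_experimental)
    for i in range(config.n_control):
        sid = f"control_{i + 1}"
        rng = np.random.default_rng(streams[i])
        columns.append(rng.multinomial(config.depth, p0))
        sample_ids.append(sid)
        conditions[sid] = CONTROL
    for j in range(config.n_experimental):
        sid = f"experimental_{j + 1}"
        rng = np.random.default_rng(streams[config.n_control + j])
        columns.append(rng.multinomial(config.depth, p_sel))
        sample_ids.append(sid)
        conditions[sid] = EXPERIMENTAL

    counts = pd.DataFrame(
        np.column_stack(columns).astype(np.int64), index=guide_ids, columns=sample_ids
    )
    return CountTable(counts=counts, conditions=conditions, direction=config.direction)


def default_activity_model(seed: int = 0, noise_sd: float = 0.2) -> ActivityModel:
    """Planted activity model emulating bacterial SpCas9-family preferences.

    Effects are planted on alternating (non-overlapping) di-nucleotide
    positions so each planted weight is identifiable from marginal means:

    * PAM-proximal spacer positions -8, -6, -4, -2: a T-richness bonus
      (T-rich seed regions favoured) plus a small random interaction term;
    * the first bases downstream of the PAM (positions 3, 5, 7): random
      per-base preferences plus a small interaction term;
    * PAM-distal spacer positions -14, -12, -10: weak random effects.

    The resulting signal has an sd of roughly 0.75 log2 units across random
    sequence, with ``noise_sd`` (default 0.2, about a quarter of the signal
    scale) of unexplained per-site variation.
    """
    rng = np.random.default_rng(seed)
    weights: dict[tuple[int, str], float] = {}
    dinucs = [a + b for a in "ACGT" for b in "ACGT"]
    for pos in (-8, -6, -4, -2):
        for d in dinucs:
            n_t = d.count("T")
            weights[(pos, d)] = 0.18 * (n_t - 0.5) + rng.normal(0.0, 0.12)
    for pos in (3, 5, 7):
        pref = {b: rng.normal(0.0, 0.20) for b in "ACGT"}
        for d in dinucs:
            weights[(pos, d)] = pref[d[0]] + pref[d[1]] + rng.normal(0.0, 0.12)
    for pos in (-14, -12, -10):
        for d in dinucs:
            weights[(pos, d)] = rng.normal(0.0, 0.10)
    return ActivityModel(
        baseline=0.0,
        positional_weights=weights,
        at_flank_penalty=0.0,
        noise_sd=noise_sd,
        seed=seed + 1,
    )


# ---------------------------------------------------------------------------
# plain-text writers


def write_genome_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.contig_id}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_sites_tsv(sites: list[TargetSite], path: str | Path) -> None:
    """BED-like 6-column site table: contig, start, end, guide_id, strand, spacer+PAM."""
    rows = [
        (s.contig_id, s.spacer_start, s.spacer_start + SPACER_LENGTH + PAM_LENGTH,
         s.guide_id, s.strand, s.spacer + s.pam)
        for s in sites
    ]
    pd.DataFrame(rows, columns=["contig", "start", "end", "guide_id", "strand", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def write_activities_tsv(activities: dict[str, float], path: str | Path) -> None:
    pd.Series(activities, name="activity").rename_axis("guide_id").to_csv(path, sep="\t")
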