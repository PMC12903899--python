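"""End-to-end pipeline helpers tying the modules together.

These functions define the canonical synthetic study: generate a genome,
enumerate NGG targets, plant ground-truth activities, simulate the screen
and score it.  Tests and the reproduction script drive the same code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountTable, Genome, TargetSite
from .scoring import ScoringConfig, score_diffbtw
from .synthetic import (
    ActivityModel,
    ScreenConfig,
    assign_true_activity,
    default_activity_model,
    enumerate_targets,
    generate_genome,
    simulate_screen,
)

__all__ = ["SimulatedScreen", "simulate_study"]


@dataclass
class SimulatedScreen:
    """A complete simulated screen with its ground truth."""

    genome: Genome
    sites: list[TargetSite]
    activities: dict[str, float]
    table: CountTable
    scores: pd.DataFrame  # unfiltered score table

    @property
    def activity_series(self) -> pd.Series:
        return pd.Series(self.activities)


def simulate_study(
    seed: int = 0,
    n_guides: int = 2000,
    genome_length: int = 120_000,
    gc: float = 0.5,
    max_flank: int = 30,
    coverage: float = 230.0,
    n_control: int = 1,
    n_experimental: int = 9,
    abundance_dispersion: float = 1.0,
    selection_strength: float = 1.0,
    direction: str = "depletion",
    activity_model: ActivityModel | None = None,
    scoring: ScoringConfig | None = None,
) -> SimulatedScreen:
    """Simulate a pooled screen and score it.

    The defaults emulate a deep bacterial depletion screen: ~2,000 guides
    sub-sampled from both strands of a random 120-kb contig, one control
    and nine selected replicates at ~230x mean control coverage, a
    log-normal library composition, and the default planted activity
    model.  ``coverage`` is reads per guide, so each sample's depth is
    ``coverage * n_guides``.
    """
    ss = np.random.SeedSequence(seed)
    genome_seed, sample_seed, screen_seed, model_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    genome = generate_genome(genome_length, gc=gc, seed=genome_seed)
    sites = enumerate_targets(genome, max_flank=max_flank)
    if len(sites) < n_guides:
        raise ValueError(
            f"genome of length {genome_length} yields only {len(sites)} usable sites"
        )
    rng = np.random.default_rng(sample_seed)
    idx = rng.choice(len(sites), size=n_guides, replace=False)
    sites = [sites[i] for i in sorted(idx)]
    model = activity_model if activity_model is not None else default_activity_model(seed=model_seed)
    activities = assign_true_activity(genome, sites, model)
    config = ScreenConfig(
        n_control=n_control,
        n_experimental=n_experimental,
        depth=int(round(coverage * n_guides)),
        abundance_dispersion=abundance_dispersion,
        selection_strength=selection_strength,
        direction=direction,
        seed=screen_seed,
    )
    table = simulate_screen(sites, activities, config)
    scores = score_diffbtw(table, scoring or ScoringConfig())
    return SimulatedScreen(genome=genome, sites=sites, activities=activities, table=table, scores=scores)
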