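"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from thermomorph.config import Normal, PipelineConfig, SimConfig
from thermomorph.inference import AnalysisSubset
from thermomorph.physiology import heatup_speed, truncate_trace
from thermomorph.synthetic import Individual, simulate_heatup_trace


@pytest.fixture
def tiny_counts() -> dict:
    return {
        "ungarica": {"F": {"green": 3, "brown": 3}, "M": {"green": 3, "brown": 3}},
        "sibiricus": {"F": {"green": 3, "brown": 3}, "M": {"green": 3, "brown": 3}},
        "parallelus": {
            "F": {m: 3 for m in ("green", "dorsal-green", "lateral-green", "brown")},
            "M": {m: 3 for m in ("green", "dorsal-green", "lateral-green", "brown")},
        },
    }


@pytest.fixture
def tiny_config(tiny_counts) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.sim.counts = tiny_counts
    cfg.sim.seed = 42
    cfg.analysis.n_bootstrap = 40
    return cfg


@pytest.fixture
def clean_sim() -> SimConfig:
    """Noise-free, dip-free generator for deterministic backbone checks."""
    cfg = SimConfig()
    cfg.noise_sd_c = 0.0
    cfg.dip_prob = 0.0
    cfg.t0 = Normal(5.0, 0.0)
    return cfg


def make_individual(
    species: str = "ungarica",
    sex: str = "M",
    morph: str = "green",
    mass_g: float = 0.2,
    ident: str | None = None,
) -> Individual:
    return Individual(
        id=ident or f"{species}-{sex}-{morph}-x",
        species=species,
        sex=sex,
        morph=morph,
        mass_g=mass_g,
    )


def make_null_subset(
    n_green: int, n_brown: int, seed: int, species: str = "sibiricus", sex: str = "M"
) -> AnalysisSubset:
    """Heat-up speeds for a morph-null subset, via the generator's honest path."""
    sim = SimConfig()
    sim.seed = seed
    rng = np.random.default_rng(seed)
    ids, morphs, speeds = [], [], []
    for morph, n in (("green", n_green), ("brown", n_brown)):
        for i in range(n):
            ind = make_individual(species, sex, morph, mass_g=0.2, ident=f"{morph}{i}")
            trace = simulate_heatup_trace(ind, sim, channel="internal", rng=rng)
            speeds.append(heatup_speed(truncate_trace(trace)))
            ids.append(ind.id)
            morphs.append(morph)
    return AnalysisSubset(
        species=species,
        sex=sex,
        ids=np.array(ids, dtype=object),
        morph=np.array(morphs, dtype=object),
        summaries={"heatup_internal": np.array(speeds)},
    )


# ---------------------------------------------------------------------------
# independent oracles (definition-level, no shared code with the package)
# ---------------------------------------------------------------------------

def brute_midranks(values) -> list[float]:
    """Mid-ranks by pairwise counting."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def brute_spearman(x, y) -> float:
    """Pearson correlation of mid-ranks, from first principles."""
    rx = brute_midranks(x)
    ry = brute_midranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    if dx == 0 or dy == 0:
        return float("nan")
    return num / (dx * dy)


def brute_mannwhitney_u(a, b) -> float:
    """U statistic of the first sample: pairwise wins plus half-ties."""
    return float(
        sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b)
    )
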