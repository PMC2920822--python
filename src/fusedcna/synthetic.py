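"""Synthetic aCGH cohorts with planted copy-number events.

Cohorts are built as additive gain/loss blocks over independent
Gaussian probe noise, emulating the event structure of real tumor
collections: whole-chromosome and arm-level events down to focal ones,
at prevalences from a few percent to most of the cohort.  Every
generated object is a deterministic function of its seed, so all
downstream modules are testable with known ground truth and no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ProbeMap, ProfileMatrix

__all__ = [
    "PlantedEvent",
    "SCENARIOS",
    "generate_dataset",
    "make_probe_map",
    "scenario",
]


@dataclass(frozen=True)
class PlantedEvent:
    """A planted gain (positive amplitude) or loss (negative amplitude)."""

    carrier_samples: tuple
    probe_start: int
    probe_end: int  # inclusive
    amplitude: float

    def __post_init__(self):
        if len(self.carrier_samples) == 0:
            raise ValueError("an event needs at least one carrier sample")
        if self.probe_start > self.probe_end:
            raise ValueError("probe_start must not exceed probe_end")
        object.__setattr__(self, "carrier_samples", tuple(int(i) for i in self.carrier_samples))


def make_probe_map(
    n_probes: int,
    gap_model: str = "uniform",
    seed: int = 0,
    chromosome: str = "1",
    gap: int = 1000,
) -> ProbeMap:
    """Single-chromosome probe map with a p/q arm boundary at the midpoint.

    ``uniform`` places probes at constant spacing ``gap``; ``lognormal``
    draws gaps from a lognormal with median ``gap`` and unit log-sd,
    emulating the wide inter-probe distance disparities of high-density
    arrays.
    """
    if n_probes < 2:
        raise ValueError("need at least 2 probes")
    if gap_model == "uniform":
        positions = 1 + gap * np.arange(n_probes, dtype=np.int64)
    elif gap_model == "lognormal":
        rng = np.random.default_rng(seed)
        gaps = np.maximum(
            1, np.round(rng.lognormal(mean=np.log(gap), sigma=1.0, size=n_probes - 1))
        ).astype(np.int64)
        positions = np.concatenate([[1], 1 + np.cumsum(gaps)])
    else:
        raise ValueError(f"unknown gap model {gap_model!r}")
    arms = np.where(np.arange(n_probes) < n_probes // 2, "p", "q").astype(object)
    probe_ids = np.array([f"P{j:05d}" for j in range(n_probes)], dtype=object)
    chrom = np.full(n_probes, str(chromosome), dtype=object)
    return ProbeMap(probe_ids, chrom, positions, arms)


def generate_dataset(
    n_samples: int,
    probe_map: ProbeMap,
    events: list[PlantedEvent],
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ProfileMatrix, list[PlantedEvent]]:
    """Additive planted events plus independent Gaussian probe noise.

    ``value[i, j]`` is the sum of the amplitudes of every event carrying
    sample ``i`` and covering probe ``j`` (overlapping events add), plus
    ``Normal(0, noise_sd)`` noise, deterministic under ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    p = len(probe_map)
    for ev in events:
        if not (0 <= ev.probe_start <= ev.probe_end < p):
            raise ValueError("event probe range outside the probe map")
        if max(ev.carrier_samples) >= n_samples or min(ev.carrier_samples) < 0:
            raise ValueError("event carrier index outside the cohort")
        chroms = set(probe_map.chromosome[ev.probe_start : ev.probe_end + 1])
        if len(chroms) > 1:
            raise ValueError("an event must lie within one chromosome")
    rng = np.random.default_rng(seed)
    values = np.zeros((n_samples, p))
    for ev in events:
        rows = np.asarray(ev.carrier_samples, dtype=int)
        values[np.ix_(rows, np.arange(ev.probe_start, ev.probe_end + 1))] += ev.amplitude
    if noise_sd > 0:
        values += rng.normal(scale=noise_sd, size=values.shape)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    return ProfileMatrix(sample_ids, values, probe_map), list(events)


def _pick_carriers(rng: np.random.Generator, n_samples: int, prevalence: float, within=None):
    pool = np.arange(n_samples) if within is None else np.asarray(within, dtype=int)
    k = max(1, round(prevalence * n_samples))
    return tuple(int(i) for i in np.sort(rng.choice(pool, size=k, replace=False)))


@dataclass(frozen=True)
class _Scenario:
    description: str
    n_samples: int
    n_probes: int
    noise_sd: float
    build_events: object = field(repr=False)


def _single_gain(rng, n, p):
    carriers = _pick_carriers(rng, n, 0.30)
    return [PlantedEvent(carriers, int(0.4 * p), int(0.6 * p) - 1, 1.0)]


def _focal_gain(rng, n, p):
    carriers = _pick_carriers(rng, n, 0.30)
    start = int(0.10 * p)
    return [PlantedEvent(carriers, start, start + max(4, p // 16) - 1, 1.0)]


def _arm_loss(rng, n, p):
    carriers = _pick_carriers(rng, n, 0.30)
    return [PlantedEvent(carriers, p // 2, p - 1, -1.0)]


def _whole_chromosome_gain(rng, n, p):
    carriers = _pick_carriers(rng, n, 0.20)
    return [PlantedEvent(carriers, 0, p - 1, 0.8)]


def _nested(rng, n, p):
    outer = _pick_carriers(rng, n, 0.30)
    inner = _pick_carriers(rng, n, 0.15, within=outer)
    start = int(0.10 * p)
    return [
        PlantedEvent(outer, p // 2, p - 1, -1.0),
        PlantedEvent(inner, start, start + max(4, p // 12) - 1, 1.0),
    ]


def _noise(rng, n, p):
    return []


SCENARIOS: dict[str, _Scenario] = {
    "single-gain": _Scenario(
        "one 30%-prevalence gain of amplitude 1.0 spanning 20% of the probes",
        60, 200, 0.3, _single_gain,
    ),
    "focal-gain": _Scenario(
        "one 30%-prevalence focal gain (p/16 probes) of amplitude 1.0",
        60, 200, 0.3, _focal_gain,
    ),
    "arm-loss": _Scenario(
        "one 30%-prevalence whole-q-arm loss of amplitude 1.0",
        60, 200, 0.3, _arm_loss,
    ),
    "whole-chromosome-gain": _Scenario(
        "one 20%-prevalence whole-chromosome gain of amplitude 0.8",
        60, 200, 0.3, _whole_chromosome_gain,
    ),
    "nested": _Scenario(
        "a 30%-prevalence q-arm loss with a 15%-prevalence focal gain nested "
        "inside its carriers",
        60, 200, 0.3, _nested,
    ),
    "noise": _Scenario("pure Gaussian noise, no events", 60, 200, 0.3, _noise),
}


def scenario(
    name: str, seed: int = 0, gap_model: str = "uniform"
) -> tuple[ProfileMatrix, list[PlantedEvent]]:
    """Instantiate a named fixture scenario deterministically under ``seed``."""
    try:
        preset = SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    rng = np.random.default_rng(seed)
    probe_map = make_probe_map(preset.n_probes, gap_model=gap_model, seed=seed)
    events = preset.build_events(rng, preset.n_samples, preset.n_probes)
    return generate_dataset(
        preset.n_samples, probe_map, events, noise_sd=preset.noise_sd,
        seed=int(rng.integers(2**31)),
    )
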