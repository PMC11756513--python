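"""Synthetic amplification-curve generator with a closed-form ground truth.

Each simulated reaction is built on the standardized-fluorescence scale
(reporter / ROX) as

    signal(c) = B0 + B1*c + amp(c) + noise,      c = 1..C

where ``amp(c) = A / (1 + exp(-k (c - m)))`` is a logistic amplification
component (zero for non-amplified draws), ``B0`` a baseline intercept, ``B1``
a per-cycle linear drift, and the noise is additive Gaussian.  An optional
hook effect — a linear post-plateau decline — is applied to a random subset
of amplified curves.  The raw reporter trace is the signal multiplied by the
nominal ROX level, and the ROX channel itself carries independent Gaussian
jitter, so the full ROX-division normalization path is exercised.

Ground truth is defined analytically: the reaction's Ct is the (fractional)
cycle at which the *noiseless* logistic component reaches a fixed fraction
``q`` of its plateau amplitude,

    Ct = m + ln(q / (1 - q)) / k,

and the reaction is labelled amplified exactly when that crossing occurs
within the run's C cycles.  This gives every simulated dataset an exact,
testable oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.interpolate import PchipInterpolator

from .curve_io import FluorescenceTrace, ReactionLabel
from .errors import TacallError

__all__ = [
    "SimConfig",
    "SimulatedReaction",
    "closed_form_ct",
    "interpolated_crossing",
    "simulate_reaction",
    "simulate_reactions",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic amplification-curve generator.

    Defaults describe a stool-metagenome-like arrayed qPCR run: 40 cycles,
    about one quarter of reactions amplifying, FAM/VIC dye shares and a
    duplexed-well fraction matching large enteric TAC studies, and midpoints
    drawn late enough that a share of amplifiers crosses only near cycle 40.
    Amplitude, baseline, drift, and noise are on the standardized
    (reporter/ROX) scale; ``rox_mean`` is in instrument units.
    """

    n_reactions: int = 1000
    prevalence: float = 0.25
    cycles: int = 40
    amplitude_range: tuple[float, float] = (1.5, 6.0)
    midpoint_range: tuple[float, float] = (12.0, 42.0)
    slope_range: tuple[float, float] = (0.4, 1.2)
    baseline_range: tuple[float, float] = (0.5, 1.5)
    drift_range: tuple[float, float] = (-0.005, 0.005)
    noise_sd: float = 0.05
    rox_mean: float = 1.5
    rox_sd: float = 0.01
    hook_probability: float = 0.1
    hook_decay: float = 0.01
    crossing_fraction: float = 0.05
    fam_fraction: float = 0.702
    duplex_fraction: float = 0.126
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reactions < 1:
            raise TacallError("n_reactions must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise TacallError("prevalence must lie in [0, 1]")
        if self.cycles < 2:
            raise TacallError("cycles must be >= 2")
        if not 0.0 < self.crossing_fraction < 1.0:
            raise TacallError("crossing_fraction must lie strictly in (0, 1)")
        if self.noise_sd < 0 or self.rox_sd < 0:
            raise TacallError("noise standard deviations must be non-negative")
        if self.rox_mean <= 0:
            raise TacallError("rox_mean must be positive")
        for name in ("amplitude_range", "midpoint_range", "slope_range",
                     "baseline_range", "drift_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise TacallError(f"{name} must be ordered (lo <= hi)")
        if self.slope_range[0] <= 0:
            raise TacallError("slopes must be positive")


@dataclass(eq=False)
class SimulatedReaction:
    """A simulated trace, its gold-standard label, and the latent parameters."""

    trace: FluorescenceTrace
    label: ReactionLabel
    params: dict = field(default_factory=dict)


def closed_form_ct(m: float, k: float, q: float) -> float:
    """Cycle at which the noiseless logistic reaches fraction ``q`` of plateau.

    Solves ``A / (1 + exp(-k (c - m))) = q A`` for ``c``, giving
    ``m + ln(q / (1 - q)) / k`` — independent of the amplitude.
    """
    if k <= 0:
        raise TacallError(f"slope k must be positive, got {k}")
    if not 0.0 < q < 1.0:
        raise TacallError(f"crossing fraction q must lie in (0, 1), got {q}")
    return m + math.log(q / (1.0 - q)) / k


def interpolated_crossing(values: np.ndarray, threshold: float) -> float | None:
    """First fractional cycle at which a sampled curve exceeds ``threshold``.

    Fits a monotone cubic (PCHIP) through the per-cycle samples (cycles
    1..C) and returns the smallest upward root of ``curve - threshold``, or
    ``None`` if the curve never exceeds the threshold.  Monotone cubic
    interpolation recovers fractional crossings of smooth sigmoid curves far
    more accurately than a linear chord between adjacent cycles.
    """
    values = np.asarray(values, dtype=float)
    cycles = np.arange(1, len(values) + 1, dtype=float)
    if np.all(values <= threshold):
        return None
    if values[0] > threshold:
        return float(cycles[0])
    f = PchipInterpolator(cycles, values - threshold)
    roots = [float(r) for r in f.roots() if cycles[0] <= r <= cycles[-1]]
    if not roots:  # pragma: no cover - guarded by the checks above
        return None
    return min(roots)


def _logistic(c: np.ndarray, A: float, m: float, k: float) -> np.ndarray:
    return A / (1.0 + np.exp(-k * (c - m)))


def simulate_reaction(
    config: SimConfig,
    rng: np.random.Generator,
    reaction_id: str = "r1",
    dye: str | None = None,
    well: str | None = None,
) -> SimulatedReaction:
    """Draw one reaction from the generative model.

    The amplification component is present with probability
    ``config.prevalence``; the reaction is labelled amplified only if its
    closed-form crossing cycle falls within the run.
    """
    c = np.arange(1, config.cycles + 1, dtype=float)
    if dye is None:
        dye = "FAM" if rng.random() < config.fam_fraction else "VIC"

    b0 = rng.uniform(*config.baseline_range)
    b1 = rng.uniform(*config.drift_range)
    has_amp = rng.random() < config.prevalence

    A = m = k = ct = None
    hooked = False
    amp = np.zeros_like(c)
    if has_amp:
        A = rng.uniform(*config.amplitude_range)
        m = rng.uniform(*config.midpoint_range)
        k = rng.uniform(*config.slope_range)
        ct = closed_form_ct(m, k, config.crossing_fraction)
        amp = _logistic(c, A, m, k)
        hooked = rng.random() < config.hook_probability
        if hooked:
            # decline starts once the logistic is essentially at plateau
            plateau_start = m + 3.0 / k
            past = np.clip(c - plateau_start, 0.0, None)
            amp = np.clip(amp - config.hook_decay * A * past, 0.0, None)

    signal = b0 + b1 * c + amp
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=config.cycles)
    rox = np.full(config.cycles, config.rox_mean)
    if config.rox_sd > 0:
        rox = rox + rng.normal(0.0, config.rox_sd, size=config.cycles)
    rox = np.clip(rox, 1e-3, None)
    reporter = np.clip(config.rox_mean * signal, 1e-6, None)

    amplified = bool(has_amp and ct is not None and ct <= config.cycles)
    label = ReactionLabel(
        reaction_id=reaction_id,
        amplified=amplified,
        ct=float(ct) if amplified else None,
    )
    trace = FluorescenceTrace(
        reaction_id=reaction_id, dye=dye, reporter=reporter, rox=rox, well=well
    )
    return SimulatedReaction(
        trace=trace,
        label=label,
        params={
            "A": A, "m": m, "k": k, "B0": b0, "B1": b1,
            "hook": hooked, "has_amp": has_amp,
        },
    )


def simulate_reactions(config: SimConfig) -> list[SimulatedReaction]:
    """Draw ``config.n_reactions`` reactions, grouping some into duplex wells.

    A fraction of reactions (``duplex_fraction``) is emitted as FAM+VIC pairs
    sharing a well id; the remainder are singleplex.  Fully deterministic for
    a fixed config (the seed lives in the config).
    """
    rng = np.random.default_rng(config.seed)
    out: list[SimulatedReaction] = []
    # duplex_fraction is the share of *reactions* in duplex wells; a duplex
    # well contributes two reactions, so the per-well probability is smaller
    p_well = config.duplex_fraction / (2.0 - config.duplex_fraction)
    well_no = 0
    while len(out) < config.n_reactions:
        well_no += 1
        well = f"w{well_no:05d}"
        remaining = config.n_reactions - len(out)
        duplex = remaining >= 2 and rng.random() < p_well
        if duplex:
            for dye in ("FAM", "VIC"):
                rid = f"r{len(out) + 1:06d}"
                out.append(simulate_reaction(config, rng, rid, dye=dye, well=well))
        else:
            rid = f"r{len(out) + 1:06d}"
            out.append(simulate_reaction(config, rng, rid, dye=None, well=well))
    return out


def simulate_dataset(
    config: SimConfig,
) -> tuple[list[FluorescenceTrace], list[ReactionLabel]]:
    """Simulate a dataset and return (traces, labels), aligned by reaction_id."""
    reactions = simulate_reactions(config)
    return [r.trace for r in reactions], [r.label for r in reactions]
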