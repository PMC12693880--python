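"""Seeded simulator of multi-phase fed-batch fermentation campaigns.

The simulator emulates a recombinant *Pichia pastoris* style process: a slow
cell-proliferation (lag) phase on the batch substrate, an exponential
fed-batch transition phase on glycerol, and a protein-induction phase in
which biomass plateaus, product (inulinase) accumulates, and methanol is fed
and consumed.  Each run yields a :class:`Batch`: a time grid, a matrix of
nine auxiliary (online-measurable) variables, three target biochemical
variables (biomass, inulinase activity, methanol concentration) and the
ground-truth phase label of every sample.

The kinetic form is deliberately simple — piecewise-logistic biomass with
phase-specific rates, product formation only during induction, methanol as a
feed-minus-consumption balance — because only the phase structure, the
variable schema and controllable batch-to-batch heterogeneity matter to the
downstream soft-sensor pipeline.  No claim of mechanistic fidelity to real
yeast physiology is made.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "ConfigError",
    "KineticsConfig",
    "HeterogeneityConfig",
    "Batch",
    "simulate_batch",
    "simulate_campaign",
    "study_campaign",
    "write_batch_csv",
    "read_batch_csv",
    "AUX_NAMES",
    "TARGET_NAMES",
]

#: names of the nine auxiliary channels, in column order
AUX_NAMES = (
    "temperature",      # degC, phase-specific setpoint
    "ph",               # pH, phase-specific setpoint with slow drift
    "do",               # dissolved oxygen, % saturation, drained by oxygen demand
    "glycerol_feed",    # g/L/h, on only during the fed-batch phase
    "methanol_feed",    # g/L/h, on only during induction (oscillating schedule)
    "agitation",        # rpm, phase setpoint plus oxygen-demand cascade
    "base_addition",    # L cumulative, tracks growth-linked acidification
    "air_flow",         # vvm setpoint per phase
    "broth_volume",     # L, rises with cumulative feed
)

TARGET_NAMES = ("biomass", "inulinase", "methanol")

# typical dynamic range of each auxiliary channel; measurement noise is
# expressed as a fraction of this range
_AUX_RANGES = np.array([8.0, 0.8, 50.0, 12.0, 1.2, 400.0, 4.0, 0.5, 2.0])


class ConfigError(ValueError):
    """Raised when a simulator configuration violates its invariants."""


@dataclass(frozen=True)
class KineticsConfig:
    """Process kinetics and sampling design of one simulated campaign.

    Defaults describe a 240 h run sampled every 4 h (61 samples per batch)
    with three phases: proliferation (0-80 h), fed-batch transition
    (80-160 h) and protein induction (160-240 h).
    """

    duration_h: float = 240.0
    sample_interval_h: float = 4.0
    phase_boundaries_h: tuple[float, ...] = (80.0, 160.0)
    #: specific growth rate (1/h) in each phase
    growth_rate_per_phase: tuple[float, ...] = (0.008, 0.035, 0.005)
    #: inoculum biomass, ug/mL
    biomass_init: float = 20.0
    #: logistic carrying capacity, ug/mL
    biomass_capacity: float = 250.0
    #: U/mL of product formed per (ug/mL biomass x h) during induction
    product_yield: float = 1.8e-4
    #: mean methanol feed rate during induction, g/L/h
    methanol_feed_rate: float = 1.2
    #: fractional amplitude and period (h) of the feed-rate oscillation
    feed_oscillation_frac: float = 0.3
    feed_oscillation_period_h: float = 24.0
    #: methanol uptake, g/L/h per ug/mL biomass
    methanol_uptake_per_biomass: float = 0.006
    #: measurement noise SD as a fraction of each channel's typical range
    noise_sd_aux: float = 0.01
    #: target-assay noise SD as a fraction of each target's trajectory range
    noise_sd_target: float = 0.02
    n_aux_features: int = 9
    seed: int = 42

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_phases(self) -> int:
        return len(self.phase_boundaries_h) + 1

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_h / self.sample_interval_h)) + 1

    def validate(self) -> None:
        if self.duration_h <= 0:
            raise ConfigError("duration_h must be positive")
        if self.sample_interval_h <= 0:
            raise ConfigError("sample_interval_h must be positive")
        ratio = self.duration_h / self.sample_interval_h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                "sample_interval_h must divide duration_h evenly"
            )
        b = np.asarray(self.phase_boundaries_h, dtype=float)
        if b.size and (np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= self.duration_h):
            raise ConfigError(
                "phase_boundaries_h must be strictly increasing inside (0, duration_h)"
            )
        if len(self.growth_rate_per_phase) != self.n_phases:
            raise ConfigError(
                "growth_rate_per_phase must have one rate per phase "
                f"({self.n_phases} phases configured)"
            )
        for name in ("growth_rate_per_phase",):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ConfigError(f"{name} must be finite")
        for name in ("biomass_init", "biomass_capacity", "product_yield",
                     "methanol_feed_rate", "methanol_uptake_per_biomass"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and nonnegative")
        for name in ("noise_sd_aux", "noise_sd_target"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_aux_features < 1:
            raise ConfigError("n_aux_features must be >= 1")


@dataclass(frozen=True)
class HeterogeneityConfig:
    """Batch-to-batch deviation applied on top of :class:`KineticsConfig`.

    ``initial_biomass_scale`` multiplies the inoculum biomass,
    ``feed_rate_scale`` multiplies the methanol feed rate, and
    ``kinetic_jitter_sd`` is the relative SD of a per-batch Gaussian jitter
    on each phase's growth rate.
    """

    initial_biomass_scale: float = 1.0
    feed_rate_scale: float = 1.0
    kinetic_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.initial_biomass_scale <= 0:
            raise ConfigError("initial_biomass_scale must be > 0")
        if self.feed_rate_scale <= 0:
            raise ConfigError("feed_rate_scale must be > 0")
        if self.kinetic_jitter_sd < 0:
            raise ConfigError("kinetic_jitter_sd must be >= 0")


#: heterogeneity of the held-out target batch: 10 % lower inoculum biomass
#: and 5 % higher methanol feed rate than the source batches
TARGET_HETEROGENEITY = HeterogeneityConfig(
    initial_biomass_scale=0.90, feed_rate_scale=1.05, kinetic_jitter_sd=0.02
)


@dataclass
class Batch:
    """One fermentation run: time grid, auxiliaries, targets, phase labels."""

    batch_id: str
    time_h: np.ndarray
    X_aux: np.ndarray
    Y_target: np.ndarray
    phase_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time_h)
        if self.X_aux.shape[0] != n or self.Y_target.shape[0] != n:
            raise ValueError("time_h, X_aux and Y_target must have equal row counts")
        if self.phase_label is not None and len(self.phase_label) != n:
            raise ValueError("phase_label length must match time_h")
        dt = np.diff(self.time_h)
        if n > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time_h must be strictly increasing with constant spacing")

    @property
    def n_samples(self) -> int:
        return len(self.time_h)

    def window(self, start: int, stop: int | None = None) -> "Batch":
        """Contiguous sample window as a new Batch (e.g. one process phase)."""
        sl = slice(start, stop)
        return Batch(
            batch_id=f"{self.batch_id}[{start}:{stop}]",
            time_h=self.time_h[sl].copy(),
            X_aux=self.X_aux[sl].copy(),
            Y_target=self.Y_target[sl].copy(),
            phase_label=None if self.phase_label is None
            else self.phase_label[sl].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        n_aux = self.X_aux.shape[1]
        cols = {"time_h": self.time_h}
        for j in range(n_aux):
            cols[f"aux_{j + 1}"] = self.X_aux[:, j]
        for j, name in enumerate(TARGET_NAMES):
            cols[name] = self.Y_target[:, j]
        if self.phase_label is not None:
            cols["phase"] = self.phase_label
        return pd.DataFrame(cols)


def _phase_of(t: np.ndarray, cfg: KineticsConfig) -> np.ndarray:
    return np.searchsorted(np.asarray(cfg.phase_boundaries_h), t, side="right")


def _logistic_piecewise(t: np.ndarray, cfg: KineticsConfig,
                        x0: float, mu: np.ndarray) -> np.ndarray:
    """Biomass trajectory: logistic growth with a phase-specific rate.

    Within each phase the closed-form logistic solution is used, chained at
    the phase boundaries so the trajectory is continuous.
    """
    cap = cfg.biomass_capacity
    starts = np.concatenate(([0.0], np.asarray(cfg.phase_boundaries_h)))
    x = np.empty_like(t)
    x_start = x0
    phase = _phase_of(t, cfg)
    for p in range(cfg.n_phases):
        mask = phase == p
        tau = t[mask] - starts[p]
        a = (cap - x_start) / max(x_start, 1e-12)
        x[mask] = cap / (1.0 + a * np.exp(-mu[p] * tau))
        # value at the end of this phase seeds the next one
        if p < cfg.n_phases - 1:
            tau_end = (np.asarray(cfg.phase_boundaries_h)[p] - starts[p])
            x_start = cap / (1.0 + a * np.exp(-mu[p] * tau_end))
    return x


def simulate_batch(cfg: KineticsConfig,
                   het: HeterogeneityConfig | None = None,
                   batch_id: str = "batch_1") -> Batch:
    """Simulate a single fed-batch fermentation run.

    Deterministic for a fixed ``cfg.seed``; with all noise SDs zero and unit
    heterogeneity the targets are seed-independent.
    """
    cfg.validate()
    het = het or HeterogeneityConfig(kinetic_jitter_sd=0.0)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF]))

    # jitter draws are consumed first so the noise stream is stable
    jitter = rng.normal(0.0, 1.0, size=cfg.n_phases) * het.kinetic_jitter_sd
    mu = np.asarray(cfg.growth_rate_per_phase) * (1.0 + jitter)

    # fine integration grid that contains every sampling instant
    n_sub = 8
    dt = cfg.sample_interval_h / n_sub
    t_fine = np.arange(0.0, cfg.duration_h + dt / 2, dt)
    phase_fine = _phase_of(t_fine, cfg)
    induction = cfg.n_phases - 1

    x0 = cfg.biomass_init * het.initial_biomass_scale
    biomass_fine = _logistic_piecewise(t_fine, cfg, x0, mu)

    # product accumulates proportionally to biomass during induction only
    rate_p = np.where(phase_fine == induction,
                      cfg.product_yield * biomass_fine, 0.0)
    product_fine = np.concatenate(
        ([0.0], cumulative_trapezoid(rate_p, t_fine)))

    # methanol: oscillating feed minus biomass-proportional uptake
    t_ind = (np.asarray(cfg.phase_boundaries_h)[-1]
             if cfg.n_phases > 1 else 0.0)
    feed = np.where(
        phase_fine == induction,
        cfg.methanol_feed_rate * het.feed_rate_scale
        * (1.0 + cfg.feed_oscillation_frac
           * np.sin(2 * np.pi * (t_fine - t_ind) / cfg.feed_oscillation_period_h)),
        0.0,
    )
    uptake = np.where(phase_fine == induction,
                      cfg.methanol_uptake_per_biomass * biomass_fine, 0.0)
    methanol_fine = np.zeros_like(t_fine)
    m = 0.0
    for i in range(1, len(t_fine)):
        m = max(0.0, m + dt * (feed[i - 1] - uptake[i - 1]))
        methanol_fine[i] = m

    # sample at the 4-h instants
    idx = np.arange(0, len(t_fine), n_sub)
    t = t_fine[idx]
    phase = phase_fine[idx]
    biomass = biomass_fine[idx]
    product = product_fine[idx]
    methanol = methanol_fine[idx]

    # instantaneous growth (normalized) couples DO and base addition to state
    growth = mu[phase] * biomass * (1.0 - biomass / cfg.biomass_capacity)
    g_norm = growth / max(growth.max(), 1e-12)

    setp = {
        "temperature": np.array([30.0, 30.0, 22.0]),
        "ph": np.array([4.9, 5.1, 5.6]),
        "do": np.array([75.0, 45.0, 55.0]),
        "agitation": np.array([350.0, 550.0, 500.0]),
        "air_flow": np.array([1.0, 1.5, 1.2]),
        "glycerol_feed": np.array([0.0, 12.0, 0.0]),
    }

    def per_phase(values: np.ndarray) -> np.ndarray:
        # tile/truncate the 3-phase setpoint table to the configured count
        reps = int(np.ceil(cfg.n_phases / len(values)))
        return np.tile(values, reps)[: cfg.n_phases][phase]

    feed_sampled = feed[idx]
    glycerol = per_phase(setp["glycerol_feed"])
    cum_feed = np.concatenate(
        ([0.0], cumulative_trapezoid(0.01 * (feed[idx] + glycerol), t)))

    channels = [
        per_phase(setp["temperature"]),
        per_phase(setp["ph"]) + 0.1 * np.sin(2 * np.pi * t / 48.0),
        # DO held near its phase setpoint, drained by oxygen demand and
        # methanol feed bursts
        per_phase(setp["do"]) - 0.04 * biomass - 8.0 * g_norm
        - 4.0 * feed_sampled,
        glycerol,
        feed_sampled,
        # agitation cascaded on oxygen demand on top of the phase setpoint
        per_phase(setp["agitation"]) + 0.3 * biomass,
        # cumulative base addition neutralizes growth-linked acidification
        0.02 * (biomass - biomass[0]) + 0.5,
        per_phase(setp["air_flow"]),
        5.0 + cum_feed,
    ]
    # extra generic channels if more than nine are requested
    for extra in range(len(channels), cfg.n_aux_features):
        channels.append(np.cos(2 * np.pi * (extra + 1) * t / cfg.duration_h))
    X_aux = np.column_stack(channels[: cfg.n_aux_features])

    ranges = np.resize(_AUX_RANGES, cfg.n_aux_features)
    X_aux = X_aux + rng.normal(size=X_aux.shape) * (cfg.noise_sd_aux * ranges)

    Y = np.column_stack([biomass, product, methanol])
    y_range = np.maximum(Y.max(axis=0) - Y.min(axis=0), 1e-9)
    Y = Y + rng.normal(size=Y.shape) * (cfg.noise_sd_target * y_range)
    Y = np.maximum(Y, 0.0)  # concentrations cannot be negative

    return Batch(batch_id=batch_id, time_h=t, X_aux=X_aux, Y_target=Y,
                 phase_label=phase.astype(int))


def derive_seed(seed: int, index: int) -> int:
    """Deterministic per-batch child seed (kept below 2**31)."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_campaign(cfg: KineticsConfig, n_batches: int,
                      het_list: list[HeterogeneityConfig] | None = None
                      ) -> list[Batch]:
    """Simulate ``n_batches`` runs with per-batch seeds derived from ``cfg.seed``."""
    if het_list is None:
        het_list = [HeterogeneityConfig() for _ in range(n_batches)]
    if len(het_list) != n_batches:
        raise ValueError(
            f"het_list has {len(het_list)} entries for {n_batches} batches")
    batches = []
    for i, het in enumerate(het_list):
        cfg_i = dataclasses.replace(cfg, seed=derive_seed(cfg.seed, i))
        batches.append(simulate_batch(cfg_i, het, batch_id=f"batch_{i + 1}"))
    return batches


def study_campaign(seed: int = 42, cfg: KineticsConfig | None = None
                   ) -> tuple[list[Batch], Batch]:
    """The default study design: two source batches plus one target batch.

    The target batch carries the reference heterogeneity (10 % lower initial
    biomass, 5 % higher methanol feed rate).  Returns ``(sources, target)``.
    """
    cfg = cfg or KineticsConfig(seed=seed)
    if cfg.seed != seed:
        cfg = dataclasses.replace(cfg, seed=seed)
    het = [HeterogeneityConfig(), HeterogeneityConfig(), TARGET_HETEROGENEITY]
    batches = simulate_campaign(cfg, 3, het)
    return batches[:2], batches[2]


def write_batch_csv(batch: Batch, path) -> None:
    batch.to_frame().to_csv(path, index=False)


def read_batch_csv(path, batch_id: str | None = None) -> Batch:
    """Read a one-batch CSV written by :func:`write_batch_csv`.

    The ``phase`` column is optional; auxiliary columns are ``aux_1..aux_k``.
    """
    df = pd.read_csv(path)
    aux_cols = [c for c in df.columns if c.startswith("aux_")]
    aux_cols.sort(key=lambda c: int(c.split("_")[1]))
    missing = [c for c in TARGET_NAMES if c not in df.columns]
    if missing:
        raise ValueError(f"batch CSV missing target columns: {missing}")
    phase = df["phase"].to_numpy(dtype=int) if "phase" in df.columns else None
    import os
    bid = batch_id or os.path.splitext(os.path.basename(str(path)))[0]
    return Batch(
        batch_id=bid,
        time_h=df["time_h"].to_numpy(dtype=float),
        X_aux=df[aux_cols].to_numpy(dtype=float),
        Y_target=df[list(TARGET_NAMES)].to_numpy(dtype=float),
        phase_label=phase,
    )
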