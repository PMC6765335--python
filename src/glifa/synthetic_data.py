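"""Synthetic IVGTT datasets with the structure the estimation stage assumes.

The generator emulates a group-averaged IVGTT: the subject starts at the
model's basal state, receives a glucose bolus at t = 0 (represented as an
elevated initial glucose, not an input term — trajectories start from the
post-bolus value, as is conventional for IVGTT model fitting), and relaxes
back toward basal over 180 minutes while being sampled on the clinical
protocol grid. Observation noise is multiplicative lognormal by default,
reflecting the roughly constant coefficient of variation of plasma assays.

Eight archetype parameter sets are shipped as fixtures — four metabolic
groups (control, NFG = normal fasting glucose, IFG = impaired fasting
glucose, T2DM = type 2 diabetes), each before and after bariatric surgery —
for both the delay model and the minimal model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np

from .model_core import DelayModelParameters, MinimalModelParameters, SystemState
from .simulate import PRE_BOLUS_TIMES, PROTOCOL_TIMES, simulate_delay
from .steady_state import solve_steady_state

__all__ = [
    "IVGTTDataset",
    "NoiseSpec",
    "generate",
    "archetype",
    "ARCHETYPE_GROUPS",
    "PROTOCOL_TIMES",
]

ARCHETYPE_GROUPS = (
    "control-pre", "control-post", "nfg-pre", "nfg-post",
    "ifg-pre", "ifg-post", "t2dm-pre", "t2dm-post",
)


@dataclass
class IVGTTDataset:
    """Timestamped glucose/insulin/FFA measurements.

    ``pre_bolus`` flags the baseline draws at negative times; fitting uses
    the post-bolus rows only (t >= 0). ``truth`` and ``seed`` record the
    generating parameters and noise whenever the dataset is synthetic.
    """

    times: np.ndarray
    G: np.ndarray
    I: np.ndarray
    F: np.ndarray | None
    pre_bolus: np.ndarray
    group: str | None = None
    truth: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.F is not None:
            self.F = np.asarray(self.F, dtype=float)
        if self.pre_bolus is None:
            self.pre_bolus = self.times < 0
        self.pre_bolus = np.asarray(self.pre_bolus, dtype=bool)
        n = self.times.size
        for name in ("G", "I", "pre_bolus"):
            if getattr(self, name).size != n:
                raise ValueError(f"IVGTTDataset.{name} length mismatch")
        if self.F is not None and self.F.size != n:
            raise ValueError("IVGTTDataset.F length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("IVGTTDataset times must be strictly increasing")

    @property
    def has_ffa(self) -> bool:
        return self.F is not None

    def post_bolus(self) -> "IVGTTDataset":
        """The fitting view: rows with t >= 0 only."""
        m = ~self.pre_bolus
        return IVGTTDataset(
            times=self.times[m], G=self.G[m], I=self.I[m],
            F=self.F[m] if self.F is not None else None,
            pre_bolus=self.pre_bolus[m], group=self.group,
            truth=self.truth, seed=self.seed,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model for the generator.

    ``proportional-lognormal`` multiplies each observation by a unit-median
    lognormal with coefficient of variation ``level``;
    ``additive-gaussian`` adds N(0, (level * series mean)^2).
    """

    model: str = "proportional-lognormal"
    level: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.model not in ("proportional-lognormal", "additive-gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")


class Archetype(NamedTuple):
    delay: DelayModelParameters
    minimal: MinimalModelParameters
    init: SystemState


def _canon_group(group: str) -> str:
    g = group.strip().lower().replace("_", "-").replace(" ", "-")
    if g not in ARCHETYPE_GROUPS:
        raise KeyError(f"unknown group {group!r}; expected one of {ARCHETYPE_GROUPS}")
    return g


def archetype(group: str, bolus_multiplier: float = 3.0) -> Archetype:
    """Fitted parameter sets for one group, plus a default bolus initial state.

    The initial state puts glucose at ``bolus_multiplier`` times basal with
    insulin and FFA still at basal — the insulin response then emerges from
    the model dynamics rather than from the initial condition.
    """
    from .io import read_params  # local import: io imports this module's types

    g = _canon_group(group)
    stem = g.replace("-", "_")
    fx = resources.files("glifa") / "fixtures"
    with resources.as_file(fx / f"table5_{stem}.yaml") as path:
        delay = read_params(path, "delay")
    with resources.as_file(fx / f"table6_{stem}.yaml") as path:
        minimal = read_params(path, "minimal")
    eq = solve_steady_state(delay)
    init = SystemState(bolus_multiplier * eq.G_b, eq.I_b, eq.F_b)
    return Archetype(delay=delay, minimal=minimal, init=init)


def _apply_noise(values: np.ndarray, noise: NoiseSpec, rng: np.random.Generator):
    if noise.level == 0:
        return values.copy()
    if noise.model == "proportional-lognormal":
        sd = np.sqrt(np.log1p(noise.level**2))
        out = values * rng.lognormal(mean=0.0, sigma=sd, size=values.shape)
    else:
        out = values + rng.normal(0.0, noise.level * np.mean(values), size=values.shape)
    return np.maximum(out, 1e-6)


def generate(
    p: DelayModelParameters,
    init: SystemState | None = None,
    noise: NoiseSpec = NoiseSpec(),
    protocol: np.ndarray | None = None,
    group: str | None = None,
    include_pre_bolus: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> IVGTTDataset:
    """Simulate the delay model and sample it on the protocol grid with noise.

    The t = 0 row carries the (noisy) initial condition; pre-bolus rows are
    noisy copies of the basal state, flagged so that fitting ignores them.
    """
    eq = solve_steady_state(p)
    if init is None:
        init = SystemState(3.0 * eq.G_b, eq.I_b, eq.F_b)
    if init.G <= eq.G_b:
        raise ValueError(
            f"generate: post-bolus initial glucose {init.G:g} must exceed basal {eq.G_b:g}"
        )
    if protocol is None:
        protocol = PROTOCOL_TIMES
    protocol = np.asarray(protocol, dtype=float)
    grid = np.union1d([0.0], protocol)
    # pre-bolus history at basal glucose: the subject sat at the fasting
    # steady state until the bolus elevated G at t = 0
    traj = simulate_delay(p, init, t_end=float(grid[-1]), output_times=grid,
                          history=eq.G_b, rtol=rtol, atol=atol)
    rng = np.random.default_rng(noise.seed)
    if include_pre_bolus:
        pre_t = PRE_BOLUS_TIMES
        times = np.concatenate([pre_t, traj.times])
        clean_G = np.concatenate([np.full(pre_t.size, eq.G_b), traj.G])
        clean_I = np.concatenate([np.full(pre_t.size, eq.I_b), traj.I])
        clean_F = np.concatenate([np.full(pre_t.size, eq.F_b), traj.F])
        pre_mask = np.concatenate(
            [np.ones(pre_t.size, dtype=bool), np.zeros(traj.times.size, dtype=bool)]
        )
    else:
        times, clean_G, clean_I, clean_F = traj.times, traj.G, traj.I, traj.F
        pre_mask = np.zeros(times.size, dtype=bool)
    return IVGTTDataset(
        times=times,
        G=_apply_noise(clean_G, noise, rng),
        I=_apply_noise(clean_I, noise, rng),
        F=_apply_noise(clean_F, noise, rng),
        pre_bolus=pre_mask,
        group=group,
        truth={
            "model": "delay",
            "params": p.as_dict(),
            "init": [init.G, init.I_or_X, init.F],
            "history": eq.G_b,
            "noise_model": noise.model,
            "noise_level": noise.level,
        },
        seed=noise.seed,
    )
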