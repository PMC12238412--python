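"""Simulated federated round times.

Federated training is as fast as its slowest collaborator, so a fair
benchmark must simulate wall time reproducibly.  The per-collaborator
simulated time of one round decomposes into download, upload, per-sample
validation and per-sample training components,

    T_k = T_down,k + T_up,k + T_val,k * N_val,k + T_train,k * N_train,k,

with each component drawn from a client-specific normal distribution
N(mu_x,k, sigma_x,k); the round time is the maximum T_k over the
selected clients.  The distribution parameters are fixed per client for
the whole experiment and consumed from a dedicated seeded stream, so
every aggregation algorithm sees the identical timing sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .phantoms import Federation

__all__ = [
    "ACTIONS",
    "ClientTimingParams",
    "RoundTiming",
    "sample_client_time",
    "round_time",
    "make_timing_profile",
    "save_profile",
    "load_profile",
]

#: Time components of one round, in sampling order.
ACTIONS = ("down", "up", "val", "train")

#: Negative normal draws are floored at this fraction of the mean
#: (normals are unbounded below but times are not).
NEGATIVE_FLOOR_FRACTION = 1e-3


@dataclass(frozen=True)
class ClientTimingParams:
    """Normal-distribution parameters of one client's time components.

    ``mu``/``sigma`` map each action in :data:`ACTIONS` to its mean and
    standard deviation in simulated seconds; ``val`` and ``train`` are
    per-sample times, ``down``/``up`` per-round constants (model
    transmission is negligible compared to training in the simulated
    regime, so communication does not scale with model size by
    default).
    """

    mu: Mapping[str, float]
    sigma: Mapping[str, float]

    def __post_init__(self) -> None:
        for action in ACTIONS:
            if action not in self.mu or action not in self.sigma:
                raise ValueError(f"missing timing parameters for action {action!r}")
            if self.mu[action] <= 0:
                raise ValueError(f"mu[{action!r}] must be > 0")
            if self.sigma[action] < 0:
                raise ValueError(f"sigma[{action!r}] must be >= 0")
        object.__setattr__(self, "mu", dict(self.mu))
        object.__setattr__(self, "sigma", dict(self.sigma))


@dataclass(frozen=True)
class ClientRoundTime:
    """Realized time components of one client in one round (seconds)."""

    t_down: float
    t_up: float
    t_val: float
    t_train: float

    @property
    def total(self) -> float:
        return self.t_down + self.t_up + self.t_val + self.t_train


@dataclass(frozen=True)
class RoundTiming:
    """Per-client realized times and the resulting round time."""

    client_times: Mapping[str, ClientRoundTime]
    cumulative_time: float  # seconds, after this round

    @property
    def round_time(self) -> float:
        return round_time({k: v.total for k, v in self.client_times.items()})


def sample_client_time(
    params: ClientTimingParams,
    n_train: int,
    n_val: int,
    rng: np.random.Generator,
) -> ClientRoundTime:
    """Draw one round's time components for one client.

    Each component is drawn once from its normal law; the per-sample
    validation and training draws are scaled by the client's split
    sizes.  Negative draws are truncated to a small positive floor
    (``1e-3`` of the mean).  Deterministic for a fixed generator state.
    """
    if n_train < 0 or n_val < 0:
        raise ValueError("sample counts must be >= 0")
    draws = {}
    for action in ACTIONS:
        value = rng.normal(params.mu[action], params.sigma[action])
        draws[action] = max(value, NEGATIVE_FLOOR_FRACTION * params.mu[action])
    return ClientRoundTime(
        t_down=draws["down"],
        t_up=draws["up"],
        t_val=draws["val"] * n_val,
        t_train=draws["train"] * n_train,
    )


def round_time(client_times: Mapping[str, float]) -> float:
    """Total simulated time of one round: the slowest selected client."""
    if not client_times:
        raise ValueError("round_time requires at least one selected client")
    return float(max(client_times.values()))


def make_timing_profile(
    federation: Federation,
    profile: Literal["size_proportional", "uniform", "custom"] = "size_proportional",
    seed: int = 0,
    base_mu: Mapping[str, float] | None = None,
    sigma_fraction: float = 0.1,
    custom: Mapping[str, ClientTimingParams] | None = None,
) -> dict[str, ClientTimingParams]:
    """Fix per-client timing parameters for a whole experiment.

    ``size_proportional`` (default) makes the per-sample training time
    dominate, so clients with many samples are the slowest — the regime
    in which selective client sampling pays off.  Per-client speed
    factors (uniform in [0.8, 1.2]) are drawn once from ``seed``, so
    regenerating the profile from the same seed yields identical
    parameters.  ``uniform`` gives every client identical parameters;
    ``custom`` passes through a user-supplied mapping.

    Default means (seconds): down 60, up 60, val 3/sample,
    train 30/sample; standard deviations are ``sigma_fraction`` of the
    mean.
    """
    if profile == "custom":
        if custom is None:
            raise ValueError("custom profile requires the `custom` mapping")
        missing = set(c.site_id for c in federation.clients) - set(custom)
        if missing:
            raise ValueError(f"custom profile missing clients: {sorted(missing)}")
        return dict(custom)
    mu = dict(base_mu) if base_mu else {"down": 60.0, "up": 60.0, "val": 3.0, "train": 30.0}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 0x712E]))
    out = {}
    for client in federation.clients:
        factor = 1.0 if profile == "uniform" else float(rng.uniform(0.8, 1.2))
        client_mu = {a: mu[a] * factor for a in ACTIONS}
        client_sigma = {a: sigma_fraction * client_mu[a] for a in ACTIONS}
        out[client.site_id] = ClientTimingParams(mu=client_mu, sigma=client_sigma)
    return out


def save_profile(profile: Mapping[str, ClientTimingParams], path: str | Path) -> None:
    """Serialize a timing profile to JSON next to run outputs."""
    payload = {
        site: {"mu": dict(p.mu), "sigma": dict(p.sigma)} for site, p in profile.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_profile(path: str | Path) -> dict[str, ClientTimingParams]:
    payload = json.loads(Path(path).read_text())
    return {
        site: ClientTimingParams(mu=entry["mu"], sigma=entry["sigma"])
        for site, entry in payload.items()
    }
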