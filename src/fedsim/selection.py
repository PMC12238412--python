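"""Client-selection policies for federated rounds.

Training is as fast as the slowest collaborator, so which clients take
part in a round trades off wall time against data coverage.  The
catalogue mirrors the strategies used by challenge participants:

* ``all`` — full participation every round.
* ``k_largest`` — only the k clients with the most samples (large
  clients are less prone to overfitting).
* ``random_groups`` — a fixed random partition into groups of k,
  cycled through per round and re-randomized every ``regroup_every``
  rounds.
* ``cycle_without_replacement`` — k random clients per round without
  replacement, restarting once every client has participated
  (guarantees all available data are seen).
* ``alternate_drop_slow`` — full participation in even rounds; in odd
  rounds, drop clients whose previous round time exceeded
  ``slow_factor`` times the previous round's mean client time.
* ``poisson_outlier_drop`` — model the client-size distribution as
  Poisson(λ = mean size) and drop size outliers (large clients) beyond
  an upper-tail quantile.

Selections are deterministic given (policy, seed, history); a policy
that would select zero clients falls back to full participation
(flagged in the trace).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .phantoms import Federation

__all__ = ["SelectionPolicy", "ClientSelector", "select", "coverage_report"]

_KINDS = (
    "all",
    "k_largest",
    "random_groups",
    "cycle_without_replacement",
    "alternate_drop_slow",
    "poisson_outlier_drop",
)


@dataclass(frozen=True)
class SelectionPolicy:
    """Declarative configuration of a client-selection strategy."""

    kind: str = "all"
    k: int = 6
    regroup_every: int = 4
    slow_factor: float = 0.75
    outlier_quantile: float = 0.975
    re_randomize: bool = False  # redraw the Poisson outlier set each round
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown selection kind {self.kind!r}; expected one of {_KINDS}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.slow_factor <= 1:
            raise ValueError("slow_factor must lie in (0, 1]")
        if not 0 < self.outlier_quantile < 1:
            raise ValueError("outlier_quantile must lie in (0, 1)")


class ClientSelector:
    """Stateful selector: owns the policy's random stream and cycle state."""

    def __init__(self, policy: SelectionPolicy, federation: Federation):
        self.policy = policy
        self.site_ids = [c.site_id for c in federation.clients]
        self.sizes = federation.sizes
        self._rng = np.random.default_rng(
            np.random.SeedSequence([int(policy.seed) % 2**31, 0x5E7])
        )
        self._groups: list[list[str]] = []
        self._cycle_pool: list[str] = []
        self._poisson_keep: list[str] | None = None
        self.last_reason = ""

    # -- policy implementations ---------------------------------------------

    def _k_largest(self) -> list[str]:
        # ties broken by site_id (stable) for reproducibility
        ranked = sorted(self.site_ids, key=lambda s: (-self.sizes[s], s))
        return ranked[: self.policy.k]

    def _random_groups(self, t: int) -> list[str]:
        k = self.policy.k
        n_groups = max(1, int(np.ceil(len(self.site_ids) / k)))
        if t % self.policy.regroup_every == 0 or not self._groups:
            order = [self.site_ids[i] for i in self._rng.permutation(len(self.site_ids))]
            self._groups = [list(order[i::n_groups]) for i in range(n_groups)]
        return sorted(self._groups[t % len(self._groups)])

    def _cycle_without_replacement(self) -> list[str]:
        chosen: list[str] = []
        while len(chosen) < min(self.policy.k, len(self.site_ids)):
            if not self._cycle_pool:
                self._cycle_pool = [
                    self.site_ids[i] for i in self._rng.permutation(len(self.site_ids))
                ]
                # never pick the same client twice within one round
                self._cycle_pool = [s for s in self._cycle_pool if s not in chosen] or self._cycle_pool
            chosen.append(self._cycle_pool.pop())
        return sorted(chosen)

    def _alternate_drop_slow(self, t: int, prev_times: Mapping[str, float] | None) -> list[str]:
        if t % 2 == 0 or not prev_times:
            return list(self.site_ids)
        mean_time = float(np.mean(list(prev_times.values())))
        threshold = self.policy.slow_factor * mean_time
        kept = [s for s in self.site_ids if prev_times.get(s, 0.0) <= threshold]
        return kept

    def _poisson_outlier_drop(self) -> list[str]:
        if self._poisson_keep is None or self.policy.re_randomize:
            lam = float(np.mean(list(self.sizes.values())))
            threshold = stats.poisson.ppf(self.policy.outlier_quantile, lam)
            self._poisson_keep = [s for s in self.site_ids if self.sizes[s] <= threshold]
        return list(self._poisson_keep)

    # -- entry point ---------------------------------------------------------

    def select(self, t: int, prev_times: Mapping[str, float] | None = None) -> list[str]:
        """Client ids participating in round ``t``.

        ``prev_times`` maps each client of the previous round to its
        realized T_k (needed by time-based policies after round 0).
        """
        kind = self.policy.kind
        if kind == "all":
            chosen = list(self.site_ids)
        elif kind == "k_largest":
            chosen = self._k_largest()
        elif kind == "random_groups":
            chosen = self._random_groups(t)
        elif kind == "cycle_without_replacement":
            chosen = self._cycle_without_replacement()
        elif kind == "alternate_drop_slow":
            chosen = self._alternate_drop_slow(t, prev_times)
        elif kind == "poisson_outlier_drop":
            chosen = self._poisson_outlier_drop()
        else:  # pragma: no cover - guarded by SelectionPolicy
            raise ValueError(kind)
        self.last_reason = kind
        if not chosen:
            self.last_reason = f"{kind}:empty-fallback-all"
            chosen = list(self.site_ids)
        return chosen


def select(
    policy: SelectionPolicy,
    t: int,
    federation: Federation,
    prev_times: Mapping[str, float] | None = None,
) -> list[str]:
    """One-shot selection for stateless policies.

    Convenience wrapper constructing a fresh :class:`ClientSelector`;
    policies with cross-round state (grouping, cycling) should reuse
    one selector across rounds instead.
    """
    return ClientSelector(policy, federation).select(t, prev_times)


def coverage_report(
    selections: Sequence[Sequence[str]],
    clients: Sequence[str] | None = None,
) -> dict[str, int]:
    """Rounds each client participated in, over a history of selections.

    Pass ``clients`` (the full federation roster) to include clients a
    policy never selected with a count of 0 — useful to verify whether
    a policy sees all available data.
    """
    if not selections:
        raise ValueError("coverage_report needs at least one round")
    counts: dict[str, int] = {c: 0 for c in clients} if clients else {}
    for round_clients in selections:
        for client in round_clients:
            counts[client] = counts.get(client, 0) + 1
    return counts
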