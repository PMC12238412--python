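"""Weight-aggregation algorithms for federated rounds.

The dominant pattern among federated tumor-segmentation submissions is a
two-step recipe: compute several independent, normalized per-client
weighting terms p_i^k (dataset size, validation loss, metric
improvement ratios, inverse parameter distance, ...) and combine them
either additively (a beta-weighted arithmetic mean) or multiplicatively;
the combined weights are renormalized and used as a convex combination
of the clients' parameter vectors,

    w_{t+1}^g = sum_k  p̄^k  w_t^k .

Weights may live at three granularities: one scalar per client
(``model``), one per client and tensor (``tensor``), or one per client
and parameter (``scalar``); normalization always holds per granularity
unit.  A server-side optimizer can additionally reinterpret the
aggregated model as a pseudo-gradient step Δ_t = w_t^g − w_agg and
apply SGD- or Adam-style updates with a server learning rate λ_s.

Implemented terms (the catalogue of participant methods):

========================  ==================================================
``fedavg``                p^k ∝ N_k (local dataset size)
``val_loss``              p^k ∝ L(w_t^k), potential for local optimization
``cost_ratio``            p^k ∝ DSC(w_t^k)/DSC(w_t^g), local improvement
``inv_param_distance``    p^k ∝ 1/|w̄_t − w_t^k| at model/tensor/scalar
                          granularity (inverse-distance similarity)
``pid``                   proportional + derivative (loss reduction) +
                          integral (loss summed over a trailing window)
``inv_train_dsc``         p^k ∝ 1/train-DSC, penalizes overfitting clients
========================  ==================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .model import ModelParameters

__all__ = [
    "Granularity",
    "WeightingTermResult",
    "TermSpec",
    "CombinationSpec",
    "AggregationHistory",
    "ClientRoundStats",
    "ServerOptimizerState",
    "term_fedavg",
    "term_val_loss",
    "term_cost_ratio",
    "term_inv_param_distance",
    "term_pid",
    "term_inv_train_dsc",
    "combine_terms",
    "broadcast_term",
    "aggregate",
    "server_update",
    "regularize_by_param_change",
    "compute_term",
]

Granularity = Literal["model", "tensor", "scalar"]

_GRANULARITY_ORDER = {"model": 0, "tensor": 1, "scalar": 2}

#: Clamp for zero denominators and zero distances.
EPSILON = 1e-8


@dataclass(frozen=True)
class WeightingTermResult:
    """Normalized per-client weights of one term.

    ``weights`` is a (K, U) array over ``clients`` (rows) and
    granularity units (columns): U = 1 for model granularity, the
    number of tensors for tensor granularity, or the full parameter
    count for scalar granularity.  Columns sum to 1.  ``flags`` records
    any degenerate-input fallbacks (epsilon clamps, uniform fallbacks)
    for the run log.
    """

    term_id: str
    clients: tuple[str, ...]
    weights: np.ndarray
    granularity: Granularity = "model"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        weights = np.atleast_2d(np.asarray(self.weights, dtype=np.float64))
        if weights.shape[0] != len(self.clients):
            raise ValueError("weights rows must match the client list")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "clients", tuple(self.clients))

    def as_mapping(self) -> dict[str, float]:
        """Model-granularity weights as a client → weight mapping."""
        if self.granularity != "model":
            raise ValueError("as_mapping is only defined for model granularity")
        return {c: float(w) for c, w in zip(self.clients, self.weights[:, 0])}


def _normalized(
    term_id: str,
    clients: Sequence[str],
    raw: np.ndarray,
    granularity: Granularity = "model",
    flags: Sequence[str] = (),
) -> WeightingTermResult:
    """Normalize nonnegative raw weights per granularity unit.

    An all-zero unit falls back to uniform weights (flagged): a term
    that cannot discriminate between clients should not veto them.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=np.float64))
    flags = list(flags)
    totals = raw.sum(axis=0, keepdims=True)
    zero_units = totals[0] == 0
    if np.any(zero_units):
        flags.append(f"{term_id}: uniform fallback on {int(zero_units.sum())} unit(s)")
        raw = raw.copy()
        raw[:, zero_units] = 1.0
        totals = raw.sum(axis=0, keepdims=True)
    return WeightingTermResult(
        term_id=term_id,
        clients=tuple(clients),
        weights=raw / totals,
        granularity=granularity,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# history of per-client statistics across rounds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClientRoundStats:
    """What one selected client reported in one round."""

    val_loss: float
    val_dsc_pre: float  # DSC of the received global model
    val_dsc_post: float  # DSC after local training
    train_dsc: float
    param_delta_norm: float  # ||w_t^k - w_{t-1}^k||_1


class AggregationHistory:
    """Round-indexed log of client statistics feeding adaptive terms.

    ``sizes`` holds the (static) per-client training-sample counts N_k;
    ``rounds[t]`` maps each client selected in round ``t`` to its
    :class:`ClientRoundStats`.  ``window`` is the trailing-window length
    used by integral-style terms.
    """

    def __init__(self, sizes: Mapping[str, int], window: int = 5):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.sizes = dict(sizes)
        self.window = int(window)
        self.rounds: list[dict[str, ClientRoundStats]] = []

    def record(self, stats: Mapping[str, ClientRoundStats]) -> None:
        self.rounds.append(dict(stats))

    def clients_at(self, t: int) -> tuple[str, ...]:
        return tuple(self.rounds[t].keys())

    def recent_losses(self, client: str, t: int, window: int) -> list[float]:
        """Most recent recorded losses of ``client`` in rounds ≤ t (newest
        first), up to ``window`` values."""
        losses = []
        for r in range(t, -1, -1):
            rec = self.rounds[r].get(client)
            if rec is not None:
                losses.append(rec.val_loss)
                if len(losses) == window:
                    break
        return losses


# ---------------------------------------------------------------------------
# weighting terms
# ---------------------------------------------------------------------------


def term_fedavg(sizes: Mapping[str, int], selected: Sequence[str] | None = None) -> WeightingTermResult:
    """FedAvg term: p^k = N_k / Σ N_k over the selected clients."""
    clients = tuple(selected) if selected is not None else tuple(sizes)
    raw = np.array([[float(sizes[c])] for c in clients])
    if raw.sum() == 0:
        raise ValueError("total dataset size of the selected clients is zero")
    return _normalized("fedavg", clients, raw)


def term_val_loss(history: AggregationHistory, t: int) -> WeightingTermResult:
    """Potential-for-local-optimization term: p^k ∝ L(w_t^k).

    Clients with a high post-training validation loss can still improve
    more than low-loss clients.  All-zero losses fall back to uniform
    weights (flagged).
    """
    clients = history.clients_at(t)
    losses = np.array([[history.rounds[t][c].val_loss] for c in clients])
    if np.any(losses < 0):
        raise ValueError("validation losses must be nonnegative")
    return _normalized("val_loss", clients, losses)


def term_cost_ratio(history: AggregationHistory, t: int) -> WeightingTermResult:
    """Local-improvement term: p^k ∝ DSC(w_t^k) / DSC(w_t^g).

    The ratio of the validation metric after local training to the
    metric of the received global model, normalized across clients.
    Zero pre-training DSC is clamped to epsilon (flagged).
    """
    clients = history.clients_at(t)
    flags = []
    ratios = np.empty((len(clients), 1))
    for i, c in enumerate(clients):
        rec = history.rounds[t][c]
        pre = rec.val_dsc_pre
        if pre <= 0:
            flags.append(f"cost_ratio: epsilon clamp for client {c}")
            pre = EPSILON
        ratios[i, 0] = rec.val_dsc_post / pre
    return _normalized("cost_ratio", clients, ratios, flags=flags)


def term_inv_param_distance(
    local_params: Mapping[str, ModelParameters],
    granularity: Granularity = "model",
    eps: float = EPSILON,
) -> WeightingTermResult:
    """Inverse distance to the uniform mean model.

    At ``model`` granularity the weight is the inverse whole-vector L1
    distance to w̄_t = (1/K) Σ_k w_t^k; at ``tensor`` granularity the L1
    distance is taken per tensor; at ``scalar`` granularity the
    element-wise absolute difference is inverted per parameter.  A zero
    distance is clamped to ``eps`` (that unit receives the maximal
    finite weight, flagged).
    """
    clients = tuple(local_params)
    if len(clients) < 2:
        raise ValueError("inverse-distance weighting needs at least 2 clients")
    stack = np.stack([local_params[c].values for c in clients])
    mean = stack.mean(axis=0)
    abs_diff = np.abs(stack - mean)  # (K, P)
    flags: list[str] = []
    if granularity == "model":
        dist = abs_diff.sum(axis=1, keepdims=True)
    elif granularity == "tensor":
        layout = local_params[clients[0]].layout
        cols = []
        offset = 0
        for name, shape in layout:
            size = int(np.prod(shape))
            cols.append(abs_diff[:, offset : offset + size].sum(axis=1))
            offset += size
        dist = np.stack(cols, axis=1)
    elif granularity == "scalar":
        dist = abs_diff
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    n_zero = int((dist == 0).sum())
    if n_zero:
        flags.append(f"inv_param_distance: epsilon clamp on {n_zero} unit(s)")
    raw = 1.0 / np.clip(dist, eps, None)
    return _normalized("inv_param_distance", clients, raw, granularity=granularity, flags=flags)


def term_pid(
    history: AggregationHistory,
    t: int,
    window: int | None = None,
) -> tuple[WeightingTermResult, WeightingTermResult, WeightingTermResult]:
    """Proportional/derivative/integral terms of PID-style aggregation.

    * p_P: the FedAvg (dataset-size) term.
    * p_D: cost reduction L(w_{t−1}^k) − L(w_t^k); a worsening client's
      negative reduction is floored at 0 before normalizing (Eq. 5-style
      aggregation requires a convex combination).  At round 0 there is
      no previous loss and the term falls back to uniform (flagged).
    * p_I: the client's loss summed over its most recent ``window``
      recorded rounds up to and including ``t`` ("room for improvement"
      integral); with ``window=1`` it reduces to the val-loss term of
      round ``t``.

    Clients unselected in earlier rounds contribute their most recent
    recorded loss; a client with no earlier record gets reduction 0.
    """
    if window is None:
        window = history.window
    clients = history.clients_at(t)
    p_p = replace(term_fedavg(history.sizes, clients), term_id="pid_P")

    flags_d: list[str] = []
    reductions = np.zeros((len(clients), 1))
    if t == 0:
        flags_d.append("pid_D: uniform fallback at round 0")
        reductions[:] = 1.0
    else:
        for i, c in enumerate(clients):
            current = history.rounds[t][c].val_loss
            earlier = history.recent_losses(c, t - 1, 1)
            if not earlier:
                flags_d.append(f"pid_D: no previous loss for client {c}")
                continue
            reductions[i, 0] = max(earlier[0] - current, 0.0)
    p_d = _normalized("pid_D", clients, reductions, flags=flags_d)

    integrals = np.array(
        [[float(np.sum(history.recent_losses(c, t, window)))] for c in clients]
    )
    p_i = _normalized("pid_I", clients, integrals)
    return p_p, p_d, p_i


def term_inv_train_dsc(history: AggregationHistory, t: int, eps: float = EPSILON) -> WeightingTermResult:
    """Overfitting-penalty term: p^k ∝ 1 / train-DSC.

    Clients that fit their local data tightly get down-weighted,
    lifting clients with remaining potential for optimization.
    """
    clients = history.clients_at(t)
    flags = []
    raw = np.empty((len(clients), 1))
    for i, c in enumerate(clients):
        d = history.rounds[t][c].train_dsc
        if d <= 0 or not np.isfinite(d):
            flags.append(f"inv_train_dsc: epsilon clamp for client {c}")
            d = eps
        raw[i, 0] = 1.0 / d
    return _normalized("inv_train_dsc", clients, raw, flags=flags)


# ---------------------------------------------------------------------------
# combination, aggregation, server update
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermSpec:
    """Declarative description of one weighting term."""

    kind: str
    options: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "options", dict(self.options))


@dataclass(frozen=True)
class CombinationSpec:
    """How weighting terms are combined into final aggregation weights.

    ``mode="additive"`` computes Σ_i β_i p_i^k with the β normalized to
    sum 1 (uniform if omitted); ``mode="multiplicative"`` computes
    Π_i p_i^k.  Either way the result is renormalized per granularity
    unit.
    """

    mode: Literal["additive", "multiplicative"] = "additive"
    terms: tuple[TermSpec, ...] = (TermSpec("fedavg"),)
    betas: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        terms = tuple(
            t if isinstance(t, TermSpec) else TermSpec(**t) for t in self.terms
        )
        object.__setattr__(self, "terms", terms)
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown combination mode {self.mode!r}")
        if self.betas is not None:
            betas = tuple(float(b) for b in self.betas)
            if any(b < 0 for b in betas) or sum(betas) == 0:
                raise ValueError("betas must be nonnegative with positive sum")
            object.__setattr__(self, "betas", betas)


def broadcast_term(
    term: WeightingTermResult,
    granularity: Granularity,
    layout: Sequence[tuple[str, tuple[int, ...]]] | None = None,
) -> WeightingTermResult:
    """Lift a term to a finer granularity by repeating its weights.

    A model-level weight is constant across tensors/parameters, so
    lifting preserves per-unit normalization.  ``layout`` is required
    when the target granularity is ``scalar`` or when lifting
    tensor→scalar.
    """
    src = _GRANULARITY_ORDER[term.granularity]
    dst = _GRANULARITY_ORDER[granularity]
    if src > dst:
        raise ValueError(f"cannot coarsen {term.granularity} weights to {granularity}")
    if src == dst:
        return term
    if layout is None:
        raise ValueError("layout is required to broadcast weights")
    sizes = [int(np.prod(shape)) for _, shape in layout]
    if term.granularity == "model":
        if granularity == "tensor":
            weights = np.repeat(term.weights, len(sizes), axis=1)
        else:
            weights = np.repeat(term.weights, sum(sizes), axis=1)
    else:  # tensor -> scalar
        weights = np.concatenate(
            [np.repeat(term.weights[:, [i]], n, axis=1) for i, n in enumerate(sizes)],
            axis=1,
        )
    return WeightingTermResult(
        term_id=term.term_id,
        clients=term.clients,
        weights=weights,
        granularity=granularity,
        flags=term.flags,
    )


def combine_terms(
    terms: Sequence[WeightingTermResult],
    spec: CombinationSpec,
) -> WeightingTermResult:
    """Combine normalized terms into final aggregation weights.

    All terms must cover the identical client set at the identical
    granularity (use :func:`broadcast_term` to lift coarser terms
    first).  The combination is renormalized per granularity unit at
    the end; with strictly positive terms the result is independent of
    any intermediate normalization order.
    """
    if not terms:
        raise ValueError("need at least one term")
    clients = terms[0].clients
    granularity = terms[0].granularity
    for term in terms[1:]:
        if term.clients != clients:
            raise ValueError(
                f"term {term.term_id!r} covers clients {term.clients}, "
                f"expected {clients}"
            )
        if term.granularity != granularity:
            raise ValueError(
                f"term {term.term_id!r} has granularity {term.granularity!r}, "
                f"expected {granularity!r} (broadcast_term to lift)"
            )
    stack = np.stack([t.weights for t in terms])  # (n_terms, K, U)
    if spec.mode == "additive":
        if spec.betas is not None and len(spec.betas) != len(terms):
            raise ValueError(
                f"{len(spec.betas)} betas given for {len(terms)} terms"
            )
        betas = (
            np.asarray(spec.betas, dtype=float)
            if spec.betas is not None
            else np.full(len(terms), 1.0 / len(terms))
        )
        betas = betas / betas.sum()
        combined = np.einsum("i,iku->ku", betas, stack)
    else:
        combined = np.prod(stack, axis=0)
        dead_units = combined.sum(axis=0) == 0
        if np.any(dead_units):
            dead_clients = sorted(
                {
                    clients[k]
                    for k in range(len(clients))
                    if np.any(combined[k, dead_units] == 0)
                }
            )
            raise ValueError(
                "multiplicative combination produced an all-zero unit; "
                f"offending clients: {dead_clients}"
            )
    flags = tuple(f for t in terms for f in t.flags)
    term_id = f"{spec.mode}(" + ",".join(t.term_id for t in terms) + ")"
    return _normalized(term_id, clients, combined, granularity=granularity, flags=flags)


def aggregate(
    local_params: Mapping[str, ModelParameters],
    weights: WeightingTermResult,
) -> ModelParameters:
    """Convex combination of client parameter vectors (the global model).

    Supports model, tensor and scalar weight granularity by
    broadcasting each client's weight over the corresponding parameter
    block.  Weights must sum to 1 per granularity unit.  Zero-weight
    clients are skipped, so one-hot weights return the source client's
    parameters bitwise.
    """
    clients = weights.clients
    missing = set(clients) - set(local_params)
    if missing:
        raise ValueError(f"missing parameters for clients: {sorted(missing)}")
    layouts = {local_params[c].layout for c in clients}
    if len(layouts) != 1:
        raise ValueError("client parameter layouts differ; cannot aggregate")
    layout = next(iter(layouts))
    if not np.allclose(weights.weights.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1 per granularity unit")
    scalar = broadcast_term(weights, "scalar", layout)
    out = None
    for i, c in enumerate(clients):
        w = scalar.weights[i]
        if not np.any(w):
            continue
        contribution = w * local_params[c].values
        out = contribution if out is None else out + contribution
    assert out is not None  # weights sum to 1, so someone is nonzero
    return ModelParameters(values=out, layout=layout)


@dataclass
class ServerOptimizerState:
    """Server-side optimizer treating Δ_t = w_t^g − w_agg as a gradient.

    ``kind="none"`` passes the aggregated model through unchanged;
    ``"sgd"`` applies w ← w − λ_s Δ_t (λ_s = 1 recovers plain
    aggregation); ``"adam"`` keeps exponential moment accumulators of
    Δ_t (initialized to zero) and applies the bias-corrected Adam step.
    """

    kind: Literal["none", "sgd", "adam"] = "none"
    server_lr: float = 1.0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: np.ndarray | None = None
    v: np.ndarray | None = None
    step_count: int = 0

    def __post_init__(self) -> None:
        if self.server_lr <= 0:
            raise ValueError("server_lr must be positive")
        if self.kind not in ("none", "sgd", "adam"):
            raise ValueError(f"unknown server optimizer kind {self.kind!r}")


def server_update(
    prev_global: ModelParameters,
    aggregated: ModelParameters,
    state: ServerOptimizerState,
) -> ModelParameters:
    """Apply the server optimizer step; mutates ``state`` accumulators."""
    if prev_global.layout != aggregated.layout:
        raise ValueError("parameter layouts differ between rounds")
    if state.kind == "none":
        return aggregated
    delta = prev_global.values - aggregated.values
    if state.kind == "sgd":
        new = prev_global.values - state.server_lr * delta
        return ModelParameters(values=new, layout=prev_global.layout)
    # adam
    if state.m is None:
        state.m = np.zeros_like(delta)
        state.v = np.zeros_like(delta)
    state.step_count += 1
    state.m = state.beta1 * state.m + (1 - state.beta1) * delta
    state.v = state.beta2 * state.v + (1 - state.beta2) * delta**2
    m_hat = state.m / (1 - state.beta1**state.step_count)
    v_hat = state.v / (1 - state.beta2**state.step_count)
    new = prev_global.values - state.server_lr * m_hat / (np.sqrt(v_hat) + state.eps)
    return ModelParameters(values=new, layout=prev_global.layout)


def regularize_by_param_change(
    weights: WeightingTermResult,
    history: AggregationHistory,
    t: int,
    strength: float = -1.0,
) -> WeightingTermResult:
    """Rescale client weights by their parameter-change norm.

    Each client's weight is multiplied by ``norm**strength`` where
    ``norm = ||w_t^k − w_{t−1}^k||_1``, then renormalized.  Negative
    ``strength`` down-weights large movers (the stability-oriented
    default); positive ``strength`` up-weights them; ``strength=0`` is
    the identity.  At round 0 there is no previous round and the
    weights pass through unchanged (flagged).
    """
    if strength == 0:
        return weights
    if t == 0:
        return replace(weights, flags=weights.flags + ("param_change: identity at round 0",))
    flags = list(weights.flags)
    factors = np.empty((len(weights.clients), 1))
    for i, c in enumerate(weights.clients):
        norm = history.rounds[t][c].param_delta_norm
        if norm <= 0 or not np.isfinite(norm):
            flags.append(f"param_change: epsilon clamp for client {c}")
            norm = EPSILON
        factors[i, 0] = norm**strength
    return _normalized(
        weights.term_id + "*param_change",
        weights.clients,
        weights.weights * factors,
        granularity=weights.granularity,
        flags=flags,
    )


def compute_term(
    spec: TermSpec,
    *,
    history: AggregationHistory,
    t: int,
    local_params: Mapping[str, ModelParameters],
) -> list[WeightingTermResult]:
    """Evaluate one declarative term spec (``pid`` expands to three)."""
    kind = spec.kind
    opts = dict(spec.options)
    if kind == "fedavg":
        return [term_fedavg(history.sizes, history.clients_at(t))]
    if kind == "val_loss":
        return [term_val_loss(history, t)]
    if kind == "cost_ratio":
        return [term_cost_ratio(history, t)]
    if kind == "inv_param_distance":
        return [term_inv_param_distance(local_params, **opts)]
    if kind == "pid":
        return list(term_pid(history, t, **opts))
    if kind == "inv_train_dsc":
        return [term_inv_train_dsc(history, t)]
    raise ValueError(f"unknown weighting term kind {kind!r}")
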