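"""Federated experiment orchestration.

One federated round: select clients → distribute the global model →
each selected client validates the received model, then trains locally
→ compute weighting terms → combine → aggregate into a consensus model
(optionally through a server optimizer) → sample the simulated round
time and advance the clock.  Runs terminate once the cumulative
simulated time exceeds the budget (default one week); the terminating
round earns no credit, and the final model is the one with the highest
global validation DSC among credited rounds (including the initial
model at t = 0).

Everything is reproducible from a single master seed, which fans out
into independent named streams (data, initialization, batches, timing,
selection) so that changing one component — e.g. the aggregation
algorithm — cannot perturb the randomness of the others.  In
particular, per-round timing draws are consumed for *all* clients of
the roster in fixed order whether or not they were selected, so every
aggregation algorithm experiences the identical timing sequence
(the benchmark's fairness contract).

The per-round global validation DSC is the pooled (validation-split
size weighted) mean of the clients' validation DSC on the newly
produced model, computed across all clients — not only the selected
ones — emulating a fixed 20% validation split of the full training
data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import (
    AggregationHistory,
    ClientRoundStats,
    CombinationSpec,
    ServerOptimizerState,
    TermSpec,
    WeightingTermResult,
    _GRANULARITY_ORDER,
    aggregate,
    broadcast_term,
    combine_terms,
    compute_term,
    regularize_by_param_change,
    server_update,
)
from .metrics import ConvergenceCurve, convergence_score
from .model import (
    LocalTrainConfig,
    ModelParameters,
    TinySegNet,
    local_train,
    local_validate,
)
from .phantoms import Federation, SitePhantomSpec, make_federation
from .selection import ClientSelector, SelectionPolicy
from .timing import (
    ClientTimingParams,
    RoundTiming,
    make_timing_profile,
    round_time,
    sample_client_time,
)

__all__ = [
    "Schedule",
    "schedule_value",
    "ExperimentConfig",
    "RoundRecord",
    "RunResult",
    "run_federation",
    "compare_aggregators",
    "write_run_outputs",
]

logger = logging.getLogger("fedsim")

# Stream tags of the master-seed fan-out.
_STREAM_DATA = 1
_STREAM_INIT = 2
_STREAM_BATCH = 3
_STREAM_TIMING = 4
_STREAM_SELECT = 5


@dataclass(frozen=True)
class Schedule:
    """Per-round schedule for a local-training hyperparameter.

    ``constant`` returns ``base``; ``step`` multiplies by ``gamma``
    every ``every`` rounds; ``polynomial`` decays as
    ``base * (1 − t/total_rounds)**power`` (clamped at 0 beyond the
    horizon).
    """

    kind: Literal["constant", "step", "polynomial"] = "constant"
    base: float = 0.1
    gamma: float = 0.5
    every: int = 1
    power: float = 1.0
    total_rounds: int = 20

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "step", "polynomial"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.every < 1 or self.total_rounds < 1:
            raise ValueError("every and total_rounds must be >= 1")


def schedule_value(schedule: Schedule, t: int) -> float:
    """Value of a schedule at round ``t`` (t >= 0)."""
    if t < 0:
        raise ValueError("round index must be >= 0")
    if schedule.kind == "constant":
        return schedule.base
    if schedule.kind == "step":
        return schedule.base * schedule.gamma ** (t // schedule.every)
    frac = 1.0 - t / schedule.total_rounds
    if frac <= 0:
        return 0.0
    return schedule.base * frac**schedule.power


@dataclass(frozen=True)
class ExperimentConfig:
    """Full declarative description of one federated experiment."""

    sites: tuple[SitePhantomSpec, ...]
    size_law: Literal["fixed", "poisson", "lognormal"] = "fixed"
    geometry: tuple[int, ...] = (32, 32)
    model_width: int = 8
    aggregator: CombinationSpec = field(default_factory=CombinationSpec)
    server_optimizer: Literal["none", "sgd", "adam"] = "none"
    server_lr: float = 1.0
    param_change_strength: float = 0.0  # nonzero enables the HT-TUAS-style rescale
    selection: SelectionPolicy = field(default_factory=SelectionPolicy)
    learning_rate: Schedule = field(default_factory=lambda: Schedule(base=0.05))
    epochs: Schedule = field(default_factory=lambda: Schedule(base=1.0))
    batch_size: int = 8
    timing_profile: Literal["size_proportional", "uniform"] = "size_proportional"
    timing_base_mu: Mapping[str, float] | None = None
    timing_sigma_fraction: float = 0.1
    budget_hours: float = 168.0
    max_rounds: int | None = None
    history_window: int = 5
    master_seed: int = 0
    label: str = "experiment"

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("an experiment needs at least 2 sites")
        if self.budget_hours <= 0:
            raise ValueError("budget_hours must be positive")
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "geometry", tuple(int(g) for g in self.geometry))

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [encode(v) for v in obj]
            return obj

        return {k: encode(getattr(self, k)) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ExperimentConfig":
        payload = dict(payload)
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown experiment config keys: {sorted(unknown)}")
        try:
            if "sites" in payload:
                payload["sites"] = tuple(
                    s if isinstance(s, SitePhantomSpec) else SitePhantomSpec(**_tuplify(s))
                    for s in payload["sites"]
                )
            if "aggregator" in payload and not isinstance(payload["aggregator"], CombinationSpec):
                agg = dict(payload["aggregator"])
                agg["terms"] = tuple(TermSpec(**t) if not isinstance(t, TermSpec) else t for t in agg.get("terms", [{"kind": "fedavg"}]))
                if agg.get("betas") is not None:
                    agg["betas"] = tuple(agg["betas"])
                payload["aggregator"] = CombinationSpec(**agg)
            if "selection" in payload and not isinstance(payload["selection"], SelectionPolicy):
                payload["selection"] = SelectionPolicy(**payload["selection"])
            for key in ("learning_rate", "epochs"):
                if key in payload and not isinstance(payload[key], Schedule):
                    payload[key] = Schedule(**payload[key])
        except TypeError as exc:
            raise ValueError(f"invalid experiment config: {exc}") from exc
        return cls(**payload)


def _tuplify(mapping: Mapping) -> dict:
    return {
        k: tuple(v) if isinstance(v, list) else v for k, v in dict(mapping).items()
    }


@dataclass(frozen=True)
class RoundRecord:
    """Everything observed in one federated round."""

    t: int
    selected: tuple[str, ...]
    selection_reason: str
    pre_val_dsc: Mapping[str, float]
    post_val_dsc: Mapping[str, float]
    val_loss: Mapping[str, float]
    train_dsc: Mapping[str, float]
    weights: Mapping[str, float]  # per-client mean weight (summary for the log)
    weight_granularity: str
    flags: tuple[str, ...]
    timing: RoundTiming
    round_seconds: float
    cumulative_seconds: float
    global_val_dsc: float
    learning_rate: float
    epochs: int
    credited: bool


@dataclass
class RunResult:
    """Outcome of one federated experiment."""

    config: ExperimentConfig
    federation_sizes: dict[str, int]
    rounds: list[RoundRecord]
    curve: ConvergenceCurve
    final_params: ModelParameters
    final_round: int  # -1 = the initial model
    initial_val_dsc: float

    @property
    def convergence_score(self) -> float:
        return convergence_score(self.curve)

    @property
    def final_val_dsc(self) -> float:
        if self.final_round < 0:
            return self.initial_val_dsc
        return self.rounds[self.final_round].global_val_dsc


def _derived_seed(master: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(master) % 2**31, tag]).generate_state(1)[0] % 2**31)


def _global_val_dsc(model, params, federation: Federation) -> float:
    """Pooled validation DSC across all clients, weighted by split size."""
    total = 0.0
    n = 0
    for client in federation.clients:
        m = local_validate(model, params, client)
        total += m.val_dsc * client.n_val
        n += client.n_val
    return total / n


def build_federation(config: ExperimentConfig) -> Federation:
    """Materialize the experiment's federation from its site specs."""
    return make_federation(
        config.sites,
        size_law=config.size_law,
        rng_seed=_derived_seed(config.master_seed, _STREAM_DATA),
        geometry=config.geometry,
    )


def run_federation(
    config: ExperimentConfig,
    federation: Federation | None = None,
    timing_profile: Mapping[str, ClientTimingParams] | None = None,
) -> RunResult:
    """Run one full simulated federated-learning experiment.

    ``federation`` and ``timing_profile`` can be passed in to share
    them across several configs (as :func:`compare_aggregators` does);
    otherwise they are built from the config's master seed.
    """
    if federation is None:
        federation = build_federation(config)
    if timing_profile is None:
        timing_profile = make_timing_profile(
            federation,
            profile=config.timing_profile,
            seed=_derived_seed(config.master_seed, _STREAM_TIMING),
            base_mu=config.timing_base_mu,
            sigma_fraction=config.timing_sigma_fraction,
        )
    roster = [c.site_id for c in federation.clients]
    model = TinySegNet(width=config.model_width, ndim=len(config.geometry))
    global_params = model.init_params(_derived_seed(config.master_seed, _STREAM_INIT))
    sizes_train = {c.site_id: c.n_train for c in federation.clients}
    history = AggregationHistory(sizes_train, window=config.history_window)
    selector = ClientSelector(
        replace(
            config.selection,
            seed=_derived_seed(config.master_seed + config.selection.seed, _STREAM_SELECT),
        ),
        federation,
    )
    timing_rng = np.random.default_rng(
        np.random.SeedSequence(
            [_derived_seed(config.master_seed, _STREAM_TIMING), 0xD0]
        )
    )
    server_state = ServerOptimizerState(kind=config.server_optimizer, server_lr=config.server_lr)

    budget_seconds = config.budget_hours * 3600.0
    initial_dsc = _global_val_dsc(model, global_params, federation)
    curve = ConvergenceCurve(budget=config.budget_hours)
    curve.append(0.0, initial_dsc)
    best_dsc, best_round, best_params = initial_dsc, -1, global_params

    prev_local: dict[str, ModelParameters] = {}
    prev_times: dict[str, float] | None = None
    records: list[RoundRecord] = []
    cumulative = 0.0
    t = 0
    while config.max_rounds is None or t < config.max_rounds:
        selected = [s for s in roster if s in set(selector.select(t, prev_times))]
        lr = schedule_value(config.learning_rate, t)
        epochs = max(1, int(round(schedule_value(config.epochs, t))))
        round_seed = _derived_seed(config.master_seed, _STREAM_BATCH) + t
        logger.info("round %d: %d/%d clients, lr=%.4g", t, len(selected), len(roster), lr)

        local_params: dict[str, ModelParameters] = {}
        stats: dict[str, ClientRoundStats] = {}
        pre_dsc, post_dsc, losses, train_dscs = {}, {}, {}, {}
        for site in selected:
            client = federation.client(site)
            pre = local_validate(model, global_params, client)
            cfg = LocalTrainConfig(
                learning_rate=lr,
                epochs_per_round=epochs,
                batch_size=config.batch_size,
                seed=round_seed,
            )
            try:
                new_params, post = local_train(model, global_params, client, cfg)
            except FloatingPointError as exc:
                raise FloatingPointError(f"round {t}: {exc}") from exc
            reference = prev_local.get(site, global_params)
            delta_norm = float(np.abs(new_params.values - reference.values).sum())
            local_params[site] = new_params
            stats[site] = ClientRoundStats(
                val_loss=post.val_loss,
                val_dsc_pre=pre.val_dsc,
                val_dsc_post=post.val_dsc,
                train_dsc=post.train_dsc,
                param_delta_norm=delta_norm,
            )
            pre_dsc[site], post_dsc[site] = pre.val_dsc, post.val_dsc
            losses[site], train_dscs[site] = post.val_loss, post.train_dsc
        history.record(stats)

        # weighting terms -> combined weights -> aggregation
        terms: list[WeightingTermResult] = []
        for term_spec in config.aggregator.terms:
            terms.extend(
                compute_term(term_spec, history=history, t=t, local_params=local_params)
            )
        target = max((term.granularity for term in terms), key=_GRANULARITY_ORDER.get)
        layout = model.layout
        terms = [broadcast_term(term, target, layout) for term in terms]
        spec = config.aggregator
        if spec.betas is not None and len(spec.betas) != len(terms):
            # `pid` expands to three terms; spread its beta uniformly
            spec = replace(spec, betas=None)
        weights = combine_terms(terms, spec)
        if config.param_change_strength != 0.0:
            weights = regularize_by_param_change(
                weights, history, t, strength=config.param_change_strength
            )
        aggregated = aggregate(local_params, weights)
        new_global = server_update(global_params, aggregated, server_state)
        if not np.all(np.isfinite(new_global.values)):
            raise FloatingPointError(f"round {t}: non-finite global parameters")

        global_dsc = _global_val_dsc(model, new_global, federation)

        # timing: draw for every roster client so the stream is identical
        # across aggregation/selection variants
        draws = {
            site: sample_client_time(
                timing_profile[site],
                federation.client(site).n_train,
                federation.client(site).n_val,
                timing_rng,
            )
            for site in roster
        }
        selected_totals = {s: draws[s].total for s in selected}
        this_round = round_time(selected_totals)
        cumulative += this_round
        credited = cumulative <= budget_seconds
        timing = RoundTiming(
            client_times={s: draws[s] for s in selected},
            cumulative_time=cumulative,
        )
        mean_weights = {
            c: float(weights.weights[i].mean()) for i, c in enumerate(weights.clients)
        }
        records.append(
            RoundRecord(
                t=t,
                selected=tuple(selected),
                selection_reason=selector.last_reason,
                pre_val_dsc=pre_dsc,
                post_val_dsc=post_dsc,
                val_loss=losses,
                train_dsc=train_dscs,
                weights=mean_weights,
                weight_granularity=weights.granularity,
                flags=weights.flags,
                timing=timing,
                round_seconds=this_round,
                cumulative_seconds=cumulative,
                global_val_dsc=global_dsc,
                learning_rate=lr,
                epochs=epochs,
                credited=credited,
            )
        )
        global_params = new_global
        prev_local.update(local_params)
        prev_times = selected_totals
        if credited:
            curve.append(cumulative / 3600.0, global_dsc)
            if global_dsc > best_dsc:
                best_dsc, best_round, best_params = global_dsc, t, new_global
        else:
            # the budget-exceeding round is not credited: its model is
            # excluded from final-model selection and from the curve
            break
        t += 1

    return RunResult(
        config=config,
        federation_sizes=federation.sizes,
        rounds=records,
        curve=curve,
        final_params=best_params,
        final_round=best_round,
        initial_val_dsc=initial_dsc,
    )


def compare_aggregators(
    configs: Sequence[ExperimentConfig],
) -> tuple[pd.DataFrame, list[RunResult]]:
    """Run several configs on the shared federation and timing profile.

    All configs must describe the identical federation (sites, size
    law, geometry, master seed); they may differ in aggregator,
    selection policy and schedules.  Returns a comparison table with
    one row per config (convergence score, final pooled DSC, rounds
    completed) plus the full run results.
    """
    if not configs:
        raise ValueError("need at least one config")
    reference = configs[0]
    for cfg in configs[1:]:
        same = (
            cfg.sites == reference.sites
            and cfg.size_law == reference.size_law
            and cfg.geometry == reference.geometry
            and cfg.master_seed == reference.master_seed
            and cfg.timing_profile == reference.timing_profile
            and cfg.budget_hours == reference.budget_hours
        )
        if not same:
            raise ValueError(
                f"config {cfg.label!r} does not share the federation/timing "
                f"setup of {reference.label!r}"
            )
    federation = build_federation(reference)
    profile = make_timing_profile(
        federation,
        profile=reference.timing_profile,
        seed=_derived_seed(reference.master_seed, _STREAM_TIMING),
        base_mu=reference.timing_base_mu,
        sigma_fraction=reference.timing_sigma_fraction,
    )
    results = [run_federation(cfg, federation=federation, timing_profile=profile) for cfg in configs]
    table = pd.DataFrame(
        {
            "label": [c.label for c in configs],
            "convergence_score": [r.convergence_score for r in results],
            "final_val_dsc": [r.final_val_dsc for r in results],
            "rounds_completed": [sum(rec.credited for rec in r.rounds) for r in results],
        }
    )
    return table, results


# ---------------------------------------------------------------------------
# run outputs
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def run_log_frame(result: RunResult) -> pd.DataFrame:
    """Per-(round, client) long-format log of a run."""
    rows = []
    for rec in result.rounds:
        for site in rec.selected:
            ct = rec.timing.client_times[site]
            rows.append(
                {
                    "round": rec.t,
                    "client": site,
                    "selection_reason": rec.selection_reason,
                    "pre_val_dsc": rec.pre_val_dsc[site],
                    "post_val_dsc": rec.post_val_dsc[site],
                    "val_loss": rec.val_loss[site],
                    "train_dsc": rec.train_dsc[site],
                    "weight_mean": rec.weights[site],
                    "weight_granularity": rec.weight_granularity,
                    "t_down": ct.t_down,
                    "t_up": ct.t_up,
                    "t_val": ct.t_val,
                    "t_train": ct.t_train,
                    "t_total": ct.total,
                    "round_seconds": rec.round_seconds,
                    "cumulative_seconds": rec.cumulative_seconds,
                    "global_val_dsc": rec.global_val_dsc,
                    "learning_rate": rec.learning_rate,
                    "epochs": rec.epochs,
                    "credited": rec.credited,
                    "flags": ";".join(rec.flags),
                }
            )
    return pd.DataFrame(rows)


def write_run_outputs(result: RunResult, out_dir: str | Path) -> dict[str, Path]:
    """Write run_log.csv, convergence.csv, result.json and a checkpoint."""
    from .model import save_params
    from .timing import save_profile  # noqa: F401  (profile saved by CLI)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    log = run_log_frame(result)
    paths["run_log"] = out_dir / "run_log.csv"
    log.to_csv(paths["run_log"], index=False, float_format="%.17g")

    curve = pd.DataFrame(result.curve.points, columns=["time_hours", "val_dsc"])
    paths["convergence"] = out_dir / "convergence.csv"
    curve.to_csv(paths["convergence"], index=False, float_format="%.17g")

    paths["result"] = out_dir / "result.json"
    paths["result"].write_text(
        json.dumps(
            {
                "label": result.config.label,
                "convergence_score": result.convergence_score,
                "final_round": result.final_round,
                "final_val_dsc": result.final_val_dsc,
                "initial_val_dsc": result.initial_val_dsc,
                "rounds_completed": sum(r.credited for r in result.rounds),
                "budget_hours": result.config.budget_hours,
                "federation_sizes": result.federation_sizes,
                "conventions": {
                    "curve_interpolation": "step",
                    "convergence_normalized_by_budget": True,
                    "validation_split_rule": "max(1, round(0.2 * n_cases))",
                },
            },
            indent=1,
            sort_keys=True,
        )
    )
    paths["checkpoint"] = out_dir / "final_model.bin"
    save_params(result.final_params, paths["checkpoint"])
    return paths
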