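"""Criterion-driven iterative feature pruning (the selection controller).

The classifier (with its Feature Prune Layer) is trained continuously; once
per epoch three pruning triggers are evaluated in fixed order —

1. validation macro precision reached ``final_prec``;
2. ``max_epochs`` epochs elapsed since the last prune (anti-stall);
3. pseudo-overfitting reached ``max_psovft``;

— and when one fires, ``N = clamp(floor(f*d/n), 1, d - des_feat_num)``
active FPL weights of smallest magnitude are masked out, where ``d`` is the
remaining feature count and ``n`` counts prune events.  Selection terminates
when ``d`` reaches the desired subset size or a total epoch budget runs out
(in which case the top-|W| active features are returned and the truncation
is logged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .evaluation import (SplitSpec, Standardizer, balanced_split,
                         macro_precision, pseudo_overfitting)
from .features import FeatureMatrix
from .network import (BaseNetConfig, FPLNetwork, TrainConfig, TrainTrace,
                      make_optimizer, prune_step, train_one_epoch)

__all__ = [
    "PruneCriteria",
    "StopCriteria",
    "ScheduleParams",
    "PruneEvent",
    "SelectionResult",
    "compute_n_delete",
    "should_prune",
    "target_count",
    "run_selection",
]


@dataclass
class PruneCriteria:
    """Thresholds for the three pruning triggers."""

    final_prec: float = 0.75
    max_epochs: int = 20
    max_psovft: float = 0.05


@dataclass
class StopCriteria:
    """Selection termination: target subset size and total epoch budget."""

    des_feat_num: int = 17
    max_epochs_final: int = 500

    def __post_init__(self) -> None:
        if self.des_feat_num < 1:
            raise ValueError("des_feat_num must be >= 1")


@dataclass
class ScheduleParams:
    """The pruning-coarseness constant f of the deletion schedule."""

    f: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError("f must be in (0, 1)")


@dataclass
class PruneEvent:
    epoch: int
    d_before: int
    d_after: int
    n_delete: int
    trigger: str
    step_counter: int


@dataclass
class SelectionResult:
    selected_names: list[str]
    selected_indices: list[int]
    scores: dict[str, float]
    prune_events: list[PruneEvent]
    termination_reason: str
    trace: TrainTrace
    truncated: bool = False
    final_state: object = None

    def to_dict(self) -> dict:
        return {
            "selected_names": list(self.selected_names),
            "selected_indices": list(map(int, self.selected_indices)),
            "scores": {k: float(v) for k, v in self.scores.items()},
            "prune_events": [asdict(e) for e in self.prune_events],
            "termination_reason": self.termination_reason,
            "truncated": self.truncated,
            "trace": self.trace.to_dict(),
        }


def compute_n_delete(d: int, f: float, n: int, des_feat_num: int) -> int:
    """Deletion count for one prune step: clamp(floor(f*d/n), 1, d-target).

    The floor schedule alone can reach 0 late in training; the lower clamp
    guarantees progress and the upper clamp prevents overshooting below the
    desired feature count.
    """
    if d <= des_feat_num:
        raise ValueError(
            f"no prunable features: d={d} <= des_feat_num={des_feat_num}")
    if n < 1:
        raise ValueError("prune-step counter n must be >= 1")
    raw = math.floor(f * d / n)
    return int(min(max(raw, 1), d - des_feat_num))


def should_prune(prec: float, epochs_since_prune: int, psovft: float,
                 crit: PruneCriteria) -> tuple[bool, str | None]:
    """Evaluate the three pruning triggers in order; return first that fires."""
    if prec >= crit.final_prec:
        return True, "precision"
    if epochs_since_prune >= crit.max_epochs:
        return True, "epochs"
    if psovft >= crit.max_psovft:
        return True, "overfitting"
    return False, None


def target_count(fraction: float, d0: int) -> int:
    """Subset size for a 'top X%' request: round-half-up(fraction*d0), min 1."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    return max(1, int(math.floor(fraction * d0 + 0.5)))


def run_selection(features: FeatureMatrix,
                  sched: ScheduleParams | None = None,
                  crit: PruneCriteria | None = None,
                  stop: StopCriteria | None = None,
                  train_config: TrainConfig | None = None,
                  net_config: BaseNetConfig | None = None,
                  split_spec: SplitSpec | None = None) -> SelectionResult:
    """Run the embedded selection loop and return the surviving subset.

    Inputs are z-scored with training-split statistics before entering the
    FPL.  With identical seed and configuration the run is bit-reproducible.
    """
    sched = sched if sched is not None else ScheduleParams()
    crit = crit if crit is not None else PruneCriteria()
    stop = stop if stop is not None else StopCriteria()
    train_config = train_config if train_config is not None else TrainConfig()
    net_config = net_config if net_config is not None else BaseNetConfig()
    split_spec = split_spec if split_spec is not None else SplitSpec(
        seed=train_config.seed)

    d0 = features.n_features
    if stop.des_feat_num > d0:
        raise ValueError(
            f"des_feat_num={stop.des_feat_num} exceeds feature count {d0}")

    train_fm, val_fm, test_fm = balanced_split(features, split_spec)
    scaler = Standardizer().fit(train_fm.values)
    Xtr = scaler.transform(train_fm.values)
    Xva = scaler.transform(val_fm.values)
    ytr, yva = train_fm.labels, val_fm.labels

    model = FPLNetwork(d0, net_config, with_fpl=True, seed=train_config.seed)
    opt = make_optimizer(model, train_config)
    batch_rng = np.random.default_rng(train_config.seed)

    trace = TrainTrace()
    events: list[PruneEvent] = []
    n = 1                # prune-step counter: counts prune events, from 1
    epochs_since = 0
    epochs_final = 0
    reason = "target reached"
    while True:
        d = model.fpl.active_count
        if d <= stop.des_feat_num:
            reason = "target reached"
            break
        if epochs_final >= stop.max_epochs_final:
            reason = "epoch budget"
            break
        train_one_epoch(model, opt, Xtr, ytr, train_config.batch_size,
                        batch_rng)
        epochs_since += 1
        epochs_final += 1
        tp = macro_precision(ytr, model.predict(Xtr))
        vp = macro_precision(yva, model.predict(Xva))
        ps = pseudo_overfitting(tp, vp)
        trace.append(tp, vp, ps, model.fpl.active_count)
        fire, trigger = should_prune(vp, epochs_since, ps, crit)
        if fire and model.fpl.active_count > stop.des_feat_num:
            n_del = compute_n_delete(model.fpl.active_count, sched.f, n,
                                     stop.des_feat_num)
            d_before = model.fpl.active_count
            model.fpl = prune_step(model.fpl, n_del)
            # rebind the (copied) FPL weight vector and freeze its moments
            opt.params[-1] = model.fpl.weights
            opt.zero_masked_moments(model.fpl)
            events.append(PruneEvent(epoch=epochs_final, d_before=d_before,
                                     d_after=model.fpl.active_count,
                                     n_delete=n_del, trigger=trigger,
                                     step_counter=n))
            epochs_since = 0
            n += 1

    active = model.fpl.active_indices
    truncated = False
    if len(active) > stop.des_feat_num:
        # epoch budget exhausted above target size: keep the top-|W| features
        mags = np.abs(model.fpl.weights[active])
        order = np.argsort(-mags, kind="stable")
        active = np.sort(active[order[:stop.des_feat_num]])
        truncated = True

    names = [features.feature_names[i] for i in active]
    scores = {features.feature_names[i]: float(abs(model.fpl.weights[i]))
              for i in active}
    return SelectionResult(selected_names=names,
                           selected_indices=list(map(int, active)),
                           scores=scores,
                           prune_events=events,
                           termination_reason=reason,
                           trace=trace,
                           truncated=truncated,
                           final_state=model.fpl.copy())
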