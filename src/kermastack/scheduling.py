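"""Staged source-replacement schedules and activity-savings accounting.

Two schemes are modelled, both quantized at one half-life per epoch:

* **push-back** (single-source holders): the used source is not withdrawn
  but recedes one capsule position per epoch; a new source of just enough
  activity tops the focus output back up to the target.
* **combine-pairs** (multisource banks): after each half-life every two
  used sources are combined back-to-back in one holder and new sources
  fill the window positions; a pair delivers ``0.5 + 0.5*T(1)`` of a
  nominal new source, where ``T(1)`` is the one-position total correction.

The maintenance condition at every epoch is conservation: residual output
from kept sources plus newly purchased activity equals the target output.
The activity saving is the residual fraction of the target that did not
have to be bought.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .physics import (
    SourceRecord,
    StackState,
    TransmissionProvider,
    ValidationError,
    analytic_transmission,
    stack_focus_output,
)
from .scenarios import ScenarioBundle, leksell4c_fixture

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EpochAction:
    """What physically happened to the inventory at one epoch."""

    epoch: int
    removed: tuple[str, ...] = ()
    moved: tuple[tuple[str, int, int], ...] = ()  # (id, from_pos, to_pos)
    added: tuple[tuple[str, float, int], ...] = ()  # (id, activity, pos)


@dataclass(frozen=True)
class EpochRecord:
    """Savings bookkeeping for one epoch."""

    epoch: int
    residual_output: float
    new_activity_total: float
    activity_saving: float
    encapsulation_saving: float
    clamped: bool = False


@dataclass
class ScheduleReport:
    """Per-epoch records, physical action log, and holder states."""

    scheme: str
    target: float
    records: list[EpochRecord]
    actions: list[EpochAction]
    stacks: list[list[StackState]]
    notes: list[str] = field(default_factory=list)


def required_new_activity(target: float, residual: float) -> float:
    """Activity to purchase so residual + new = target; clamped at zero.

    A residual above the target would call for negative new activity;
    that is physically a surplus, reported as zero purchase with a log
    notice rather than an error.
    """
    if target <= 0:
        raise ValidationError(f"target must be > 0, got {target}")
    if residual < 0:
        raise ValidationError(f"residual must be >= 0, got {residual}")
    if residual > target:
        log.warning("residual output %.4f exceeds target %.4f; "
                    "new activity clamped to 0", residual, target)
        return 0.0
    return target - residual


def push_back_schedule(capacity: int, epochs: int,
                       transmission: TransmissionProvider | None = None,
                       target: float = 1.0,
                       bundle: ScenarioBundle | None = None,
                       start_installed: bool = True) -> ScheduleReport:
    """Simulate the single-holder push-back scheme for ``epochs`` half-lives.

    At each epoch every kept source ages one half-life and moves back one
    position; the source pushed past the last of ``capacity`` positions is
    withdrawn; a new source enters at the exit window with exactly the
    activity needed to restore the target focus output.

    With ``start_installed`` (default) a full-strength source is already in
    place at epoch 0, so epoch 1 is the first *replacement* event; with
    ``start_installed=False`` the holder starts empty and epoch 1 is the
    first installation (new activity = target, saving 0).
    """
    if capacity < 1:
        raise ValidationError(f"capacity must be >= 1, got {capacity}")
    if epochs < 1:
        raise ValidationError(f"epochs must be >= 1, got {epochs}")
    if bundle is None:
        bundle = leksell4c_fixture()
    if transmission is None:
        transmission = analytic_transmission(bundle.capsule, bundle.geometry)

    sources: list[SourceRecord] = []
    if start_installed:
        sources = [SourceRecord("0-1", initial_activity=target,
                                install_epoch=0)]

    records: list[EpochRecord] = []
    actions: list[EpochAction] = []
    stacks: list[list[StackState]] = []
    for epoch in range(1, epochs + 1):
        aged = [replace(s, age=s.age + 1.0) for s in sources]
        moved = tuple((s.id, i, i + 1) for i, s in enumerate(aged))
        kept, dropped = aged[:capacity - 1], aged[capacity - 1:]
        residual = sum(
            s.activity * transmission(i + 1) for i, s in enumerate(kept))
        new_act = required_new_activity(target, residual)
        clamped = residual > target
        newcomer = SourceRecord(f"{epoch}-1", initial_activity=new_act,
                                install_epoch=epoch)
        sources = [newcomer] + kept
        records.append(EpochRecord(
            epoch=epoch,
            residual_output=residual,
            new_activity_total=new_act,
            activity_saving=min(residual / target, 1.0),
            encapsulation_saving=0.0,
            clamped=clamped,
        ))
        actions.append(EpochAction(
            epoch=epoch,
            removed=tuple(s.id for s in dropped),
            moved=tuple(m for m in moved if m[2] <= capacity - 1),
            added=((newcomer.id, new_act, 0),),
        ))
        stacks.append([StackState(sources=list(sources),
                                  capsule=bundle.capsule,
                                  geometry=bundle.geometry)])
    return ScheduleReport(scheme="push-back", target=target, records=records,
                          actions=actions, stacks=stacks)


def combine_pairs_schedule(epochs: int,
                           transmission: TransmissionProvider | None = None,
                           holders: int = 2,
                           target: float = 1.0,
                           bundle: ScenarioBundle | None = None) -> ScheduleReport:
    """Simulate the pair-combining scheme for a bank of window holders.

    Each of ``holders`` window positions must deliver ``target`` output.
    At every epoch the used (one-half-life-old) window sources are combined
    two per holder — a pair yields ``0.5 + 0.5*T(1)`` of a nominal source —
    and new sources restore the bank total.  Per epoch the bank buys
    ``holders*target - residual`` of activity; half as many fresh capsules
    as window holders are needed, a 50% encapsulation saving.

    The bank bookkeeping follows the pair arithmetic: the required new
    activity per holder pair is ``2*target - pair_output`` (one boosted
    source of 132.8% nominal strength for the reference unit), so half as
    many fresh capsules as window holders are bought.  Epochs beyond the
    first repeat the same nominal arithmetic for each new batch; the
    progressive regrouping of older combined holders into larger groups is
    tracked only structurally, not in the savings records.
    """
    if epochs < 1:
        raise ValidationError(f"epochs must be >= 1, got {epochs}")
    if holders < 2 or holders % 2:
        raise ValidationError(
            f"combine-pairs needs an even holder count >= 2, got {holders}")
    if bundle is None:
        bundle = leksell4c_fixture()
    if transmission is None:
        transmission = analytic_transmission(bundle.capsule, bundle.geometry)

    t1 = transmission(1)
    pair_output = target * (0.5 + 0.5 * t1)
    bank_target = holders * target

    def holder_state(srcs: list[SourceRecord]) -> StackState:
        return StackState(sources=srcs, capsule=bundle.capsule,
                          geometry=bundle.geometry)

    n_pairs = holders // 2
    records: list[EpochRecord] = []
    actions: list[EpochAction] = []
    stacks: list[list[StackState]] = []
    window = [SourceRecord(f"0-{i + 1}", initial_activity=target)
              for i in range(holders)]
    for epoch in range(1, epochs + 1):
        residual = n_pairs * pair_output
        new_total = required_new_activity(bank_target, residual)
        aged = [replace(s, age=s.age + 1.0) for s in window]
        pairs = [aged[i:i + 2] for i in range(0, holders, 2)]
        # one boosted new source per pair of used sources
        newcomers = [SourceRecord(f"{epoch}-{i + 1}",
                                  initial_activity=new_total / n_pairs,
                                  install_epoch=epoch)
                     for i in range(n_pairs)]
        records.append(EpochRecord(
            epoch=epoch,
            residual_output=residual,
            new_activity_total=new_total,
            activity_saving=residual / bank_target,
            encapsulation_saving=0.5,
        ))
        actions.append(EpochAction(
            epoch=epoch,
            moved=tuple((p[1].id, 0, 1) for p in pairs if len(p) == 2),
            added=tuple((s.id, s.initial_activity, 0) for s in newcomers),
        ))
        stacks.append([holder_state([s]) for s in newcomers]
                      + [holder_state(list(p)) for p in pairs])
        # each new batch is booked against nominal-strength window sources
        window = [SourceRecord(f"{epoch}-{i + 1}", initial_activity=target,
                               install_epoch=epoch) for i in range(holders)]
    report = ScheduleReport(scheme="combine-pairs", target=target,
                            records=records, actions=actions, stacks=stacks)
    report.notes.append(
        "per pair of used sources the bank buys one boosted source of "
        "2*target - pair_output activity; savings records repeat the "
        "nominal per-batch arithmetic each epoch")
    return report


def pair_output(transmission: TransmissionProvider, target: float = 1.0) -> float:
    """Focus output of two used sources combined back-to-back after one
    half-life: ``target * (0.5 + 0.5*T(1))``."""
    return target * (0.5 + 0.5 * transmission(1))
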