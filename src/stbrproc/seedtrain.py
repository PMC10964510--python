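"""Fold-expansion arithmetic, seed-train projection and cryo-recovery metrics.

A *seed train* is a stepwise scale-up: each passage's harvest seeds a larger
vessel at a fixed inoculation density. Per-passage *fold expansion* is the
harvest density over the inoculation density; cumulative folds multiply
across passages, and the "average fold" of a multi-passage campaign is the
geometric mean (n-th root of the cumulative fold), which is the per-passage
rate that compounds to the observed total.

Cryopreservation is described by two ratios measured at different times:
*recovery after thawing* (viable count straight out of the vial over the
count frozen, dominated by necrosis) and *recovery on d1* (viable density
24 h after bioreactor inoculation over the target inoculation density,
dominated by anoikis/apoptosis of the dissociated single cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "SeedTrainError",
    "SeedTrainStage",
    "StageResult",
    "SeedTrainResult",
    "CryoEvent",
    "CryoPlan",
    "fold_expansion",
    "per_passage_fold",
    "cumulative_fold",
    "cumulative_yield",
    "plan_seed_train",
    "recovery_post_thaw",
    "recovery_d1",
    "apply_cryo",
]

#: Cryovial fill volume [mL]; CPD is defined per mL of cryomedium.
VIAL_VOLUME_ML = 1.0


class SeedTrainError(ValueError):
    """Raised for domain errors in seed-train arithmetic."""


def fold_expansion(harvest_density: float, inoc_density: float) -> float:
    """Fold expansion of one passage: harvest density / inoculation density.

    Densities share a unit (cells/mL); the result is dimensionless, e.g.
    35×10⁶ harvested from 5×10⁵ inoculated is a 70-fold expansion.
    """
    if inoc_density <= 0:
        raise SeedTrainError(f"inoc_density must be > 0, got {inoc_density}")
    if harvest_density < 0:
        raise SeedTrainError(f"harvest_density must be >= 0, got {harvest_density}")
    return harvest_density / inoc_density


def per_passage_fold(cumulative: float, n_passages: int) -> float:
    """Geometric-mean per-passage fold from a cumulative fold over n passages."""
    if n_passages < 1:
        raise SeedTrainError(f"n_passages must be >= 1, got {n_passages}")
    if cumulative <= 0:
        raise SeedTrainError(f"cumulative fold must be > 0, got {cumulative}")
    return cumulative ** (1.0 / n_passages)


def cumulative_fold(folds: Sequence[float]) -> float:
    """Product of per-passage folds (1 for an empty schedule)."""
    out = 1.0
    for f in folds:
        if f < 0:
            raise SeedTrainError(f"folds must be >= 0, got {f}")
        out *= f
    return out


def cumulative_yield(inoc_cells: float, folds: Sequence[float]) -> float:
    """Cells after compounding ``folds`` from an inoculum of ``inoc_cells``."""
    if inoc_cells < 0:
        raise SeedTrainError(f"inoc_cells must be >= 0, got {inoc_cells}")
    return inoc_cells * cumulative_fold(folds)


@dataclass(frozen=True)
class SeedTrainStage:
    """One stage of a seed train.

    volume [L], inoc_density [cells/mL], fold (dimensionless per-passage
    expansion), duration [d].
    """

    volume: float
    inoc_density: float
    fold: float
    duration: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise SeedTrainError(f"stage volume must be > 0, got {self.volume}")
        if self.inoc_density <= 0:
            raise SeedTrainError(
                f"stage inoc_density must be > 0, got {self.inoc_density}")
        if self.fold < 0:
            raise SeedTrainError(f"stage fold must be >= 0, got {self.fold}")
        if self.duration <= 0:
            raise SeedTrainError(f"stage duration must be > 0, got {self.duration}")

    @property
    def inoculated_cells(self) -> float:
        return self.volume * 1e3 * self.inoc_density  # L → mL

    @property
    def harvested_cells(self) -> float:
        return self.inoculated_cells * self.fold


@dataclass(frozen=True)
class StageResult:
    stage: SeedTrainStage
    inoculated_cells: float
    harvested_cells: float
    #: harvest minus the next stage's inoculum requirement (NaN for the last stage)
    surplus_cells: float


@dataclass(frozen=True)
class SeedTrainResult:
    """Projection of a seed train; infeasibility is flagged, never raised."""

    stages: tuple[SeedTrainStage, ...]
    per_stage: tuple[StageResult, ...]
    total_duration: float
    final_yield: float
    cumulative_fold: float
    feasible: bool


def plan_seed_train(stages: Sequence[SeedTrainStage]) -> SeedTrainResult:
    """Project a seed train stage by stage.

    Each stage inoculates ``volume × inoc_density`` cells and harvests
    ``fold`` times that. The plan is feasible iff every harvest covers the
    next stage's inoculum; the shortfall/surplus is reported per transition.
    """
    if not stages:
        raise SeedTrainError("a seed train needs at least one stage")
    stages = tuple(stages)
    per_stage: list[StageResult] = []
    feasible = True
    for i, st in enumerate(stages):
        surplus = math.nan
        if i + 1 < len(stages):
            surplus = st.harvested_cells - stages[i + 1].inoculated_cells
            if surplus < 0:
                feasible = False
        per_stage.append(StageResult(
            stage=st, inoculated_cells=st.inoculated_cells,
            harvested_cells=st.harvested_cells, surplus_cells=surplus))
    return SeedTrainResult(
        stages=stages,
        per_stage=tuple(per_stage),
        total_duration=sum(st.duration for st in stages),
        final_yield=stages[-1].harvested_cells,
        cumulative_fold=cumulative_fold([st.fold for st in stages]),
        feasible=feasible,
    )


@dataclass(frozen=True)
class CryoEvent:
    """One cryopreservation step between passages.

    cpd: cryopreservation cell density [cells/mL of cryomedium];
    recovery_post_thaw: viable-out/frozen ratio straight after thaw
    (can slightly exceed 1 from counting error); recovery_d1: viable
    density on day 1 over the target inoculation density.
    """

    cpd: float
    recovery_post_thaw: float = 1.0
    recovery_d1: float = 1.0

    def __post_init__(self) -> None:
        if self.cpd <= 0:
            raise SeedTrainError(f"cpd must be > 0, got {self.cpd}")
        if not 0 <= self.recovery_post_thaw <= 1.2:
            raise SeedTrainError(
                f"recovery_post_thaw must be in [0, 1.2], got {self.recovery_post_thaw}")
        if not 0 <= self.recovery_d1 <= 1:
            raise SeedTrainError(
                f"recovery_d1 must be in [0, 1], got {self.recovery_d1}")


def recovery_post_thaw(viable_after_thaw: float, cells_frozen: float) -> float:
    """Post-thaw recovery: viable cells out of the vial / cells frozen.

    Reads the ratio in the direction that yields the reported 80–100%
    range (losses at this point are necrosis from ice crystallization or
    osmotic shock).
    """
    if cells_frozen <= 0:
        raise SeedTrainError(f"cells_frozen must be > 0, got {cells_frozen}")
    if viable_after_thaw < 0:
        raise SeedTrainError(
            f"viable_after_thaw must be >= 0, got {viable_after_thaw}")
    return viable_after_thaw / cells_frozen


def recovery_d1(X_d1: float, X_d0_target: float) -> float:
    """Day-1 recovery: viable density 24 h post-inoculation / target density."""
    if X_d0_target <= 0:
        raise SeedTrainError(f"X_d0_target must be > 0, got {X_d0_target}")
    if X_d1 < 0:
        raise SeedTrainError(f"X_d1 must be >= 0, got {X_d1}")
    return X_d1 / X_d0_target


@dataclass(frozen=True)
class CryoPlan:
    """Seed-train projection adjusted for an intermediate cryo step."""

    plan: SeedTrainResult
    event: CryoEvent
    #: cells that must be frozen to meet the first stage's inoculum after
    #: post-thaw losses
    frozen_cells_required: float
    vials: int
    #: frozen capacity of the vials beyond the requirement
    surplus_frozen_cells: float
    feasible: bool


def apply_cryo(plan: SeedTrainResult, event: CryoEvent) -> CryoPlan:
    """Adjust a seed-train projection for inoculation from cryostock.

    The first stage's effective fold is scaled by ``recovery_d1`` (the d1
    survivors then expand at the unadjusted fold), the frozen-cell
    requirement is the inoculum divided by ``recovery_post_thaw``, and
    vials are counted by ceiling at the event's CPD with the surplus
    reported. Zero recovery fractions yield an infeasible plan, not an
    error.
    """
    if event.recovery_post_thaw == 0 or event.recovery_d1 == 0:
        return CryoPlan(plan=plan, event=event,
                        frozen_cells_required=math.inf, vials=0,
                        surplus_frozen_cells=0.0, feasible=False)
    first = plan.stages[0]
    adjusted_first = SeedTrainStage(
        volume=first.volume, inoc_density=first.inoc_density,
        fold=first.fold * event.recovery_d1, duration=first.duration)
    adjusted = plan_seed_train((adjusted_first,) + plan.stages[1:])
    frozen_required = first.inoculated_cells / event.recovery_post_thaw
    vials = math.ceil(frozen_required / (event.cpd * VIAL_VOLUME_ML))
    surplus = vials * event.cpd * VIAL_VOLUME_ML - frozen_required
    return CryoPlan(plan=adjusted, event=event,
                    frozen_cells_required=frozen_required, vials=vials,
                    surplus_frozen_cells=surplus,
                    feasible=adjusted.feasible)
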