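"""Scenario generation: the packaged Leksell 4C parameter set and
randomized capsule/geometry/inventory bundles for property testing.

Every analysis stage in this package consumes a :class:`ScenarioBundle`,
so tests and CLI runs never need external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .physics import (
    CapsuleSpec,
    MaterialSpec,
    SourceRecord,
    StackState,
    UnitGeometry,
    ValidationError,
)


@dataclass
class ScenarioBundle:
    """A complete, self-consistent input scenario."""

    capsule: CapsuleSpec
    geometry: UnitGeometry
    holders: list[StackState] = field(default_factory=list)
    epochs: int = 1
    seed: int | None = None


def leksell4c_fixture() -> ScenarioBundle:
    """The Leksell 4C Gamma Knife source model used throughout.

    Cobalt pellet column: mu/rho = 0.0527 cm^2/g at 1.25 MeV, effective
    density 5.88 g/cm^3 (pellets packed with interstitial air), height 2 cm.
    Stainless-steel shell: mu/rho = 0.0535 cm^2/g, density 7.85 g/cm^3,
    0.12 cm in front of and 0.49 cm behind the active column.  Capsules
    stack on a 2.72 cm pitch; the focus sits 40.1 cm from the source.
    """
    cobalt = MaterialSpec("cobalt-60 pellets", mass_attenuation=0.0527,
                          density=5.88)
    steel = MaterialSpec("stainless steel", mass_attenuation=0.0535,
                         density=7.85)
    capsule = CapsuleSpec(
        active_material=cobalt,
        shell_material=steel,
        active_height=2.0,
        shell_front_height=0.12,
        shell_back_height=0.49,
        capsule_pitch=2.72,
        active_radius=0.05,
    )
    geometry = UnitGeometry(source_focus_distance=40.1)
    holders = [StackState(sources=[SourceRecord("1-1")], capsule=capsule,
                          geometry=geometry)]
    return ScenarioBundle(capsule=capsule, geometry=geometry, holders=holders)


#: Default sampling ranges for random scenarios.  Distances and heights are
#: chosen so d / h_source >= 5 holds, keeping the point-source inverse-square
#: model inside its validity region.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "mass_attenuation": (0.01, 0.2),   # cm^2/g
    "density": (0.5, 12.0),            # g/cm^3
    "active_height": (0.1, 5.0),       # cm
    "shell_height": (0.1, 1.0),        # cm, split front/back
    "distance": (30.0, 100.0),         # cm
}


def random_scenario(seed: int,
                    ranges: dict[str, tuple[float, float]] | None = None,
                    *,
                    allow_invalid_geometry: bool = False) -> ScenarioBundle:
    """Draw a random but physically valid scenario, reproducible from seed.

    With ``allow_invalid_geometry`` the focus distance is drawn from
    (1, 20) cm so that d / h_source < 5 scenarios occur, exercising the
    point-source-validity warning path.
    """
    eff = dict(DEFAULT_RANGES)
    if ranges:
        unknown = set(ranges) - set(eff)
        if unknown:
            raise ValidationError(f"unknown range keys: {sorted(unknown)}")
        eff.update(ranges)
    for key, (lo, hi) in eff.items():
        if not (0 < lo <= hi):
            raise ValidationError(f"range {key!r} empty or inverted: ({lo}, {hi})")

    rng = np.random.default_rng(seed)

    def draw(key: str) -> float:
        lo, hi = eff[key]
        return float(rng.uniform(lo, hi))

    active = MaterialSpec("random active", draw("mass_attenuation"),
                          draw("density"))
    shell = MaterialSpec("random shell", draw("mass_attenuation"),
                         draw("density"))
    h_active = draw("active_height")
    h_shell = draw("shell_height")
    front = float(rng.uniform(0.05, 0.95)) * h_shell
    layer = front + h_active + (h_shell - front)
    pitch = layer * float(rng.uniform(1.0, 1.2))  # up to 20% air gap
    if allow_invalid_geometry:
        d = float(rng.uniform(1.0, 20.0))
    else:
        d = max(draw("distance"), 5.0 * h_active)
    capsule = CapsuleSpec(active_material=active, shell_material=shell,
                          active_height=h_active, shell_front_height=front,
                          shell_back_height=h_shell - front,
                          capsule_pitch=pitch,
                          active_radius=float(rng.uniform(0.01, 0.3)))
    geometry = UnitGeometry(source_focus_distance=d)
    holders = [StackState(sources=[SourceRecord("1-1")], capsule=capsule,
                          geometry=geometry)]
    return ScenarioBundle(capsule=capsule, geometry=geometry, holders=holders,
                          seed=seed)


def inventory_timeline(bundle: ScenarioBundle, epochs: int,
                       scheme: str = "push-back",
                       capacity: int = 4) -> list[list[StackState]]:
    """Holder states after each half-life epoch under a replacement scheme.

    Source ids follow the batch-hyphen-index convention ("2-1" is the first
    source of the second batch).  ``push-back`` models a single holder with
    ``capacity`` positions: each epoch every source ages one half-life and
    recedes one position, the source past the last position is withdrawn,
    and a new source enters at the exit window.  ``combine-pairs`` models a
    bank of two holders: each epoch the two used sources are combined
    back-to-back in one holder and a new batch of two sources takes the
    window positions.

    Returns one list of holders per epoch, epoch 1 first.
    """
    if epochs < 1:
        raise ValidationError(f"epochs must be >= 1, got {epochs}")
    if scheme == "push-back":
        if capacity < 1:
            raise ValidationError("push-back needs capacity >= 1")
        return _push_back_timeline(bundle, epochs, capacity)
    if scheme == "combine-pairs":
        return _combine_pairs_timeline(bundle, epochs)
    raise ValidationError(f"unknown scheme {scheme!r}")


def _push_back_timeline(bundle: ScenarioBundle, epochs: int,
                        capacity: int) -> list[list[StackState]]:
    sources: list[SourceRecord] = []
    out: list[list[StackState]] = []
    for epoch in range(1, epochs + 1):
        aged = [replace(s, age=s.age + 1.0) for s in sources]
        sources = [SourceRecord(f"{epoch}-1", initial_activity=1.0,
                                install_epoch=epoch)] + aged
        sources = sources[:capacity]
        out.append([StackState(sources=list(sources), capsule=bundle.capsule,
                               geometry=bundle.geometry)])
    return out


def _combine_pairs_timeline(bundle: ScenarioBundle,
                            epochs: int) -> list[list[StackState]]:
    def holder(sources: list[SourceRecord]) -> StackState:
        return StackState(sources=sources, capsule=bundle.capsule,
                          geometry=bundle.geometry)

    out: list[list[StackState]] = []
    prev_new: list[SourceRecord] = []
    for epoch in range(1, epochs + 1):
        combined = [replace(s, age=s.age + 1.0) for s in prev_new]
        prev_new = [SourceRecord(f"{epoch}-{i + 1}", initial_activity=1.0,
                                 install_epoch=epoch) for i in range(2)]
        holders = [holder([s]) for s in prev_new]
        if combined:
            holders.append(holder(combined))
        out.append(holders)
    return out
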