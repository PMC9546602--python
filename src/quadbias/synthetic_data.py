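"""Synthetic study-like IAT datasets with known ground truth.

The generator emulates internet-demonstration-style IAT sessions: a
seven-block design with randomized critical-block order, per-participant
Quad process parameters drawn from component-specific Beta population
distributions, first-response accuracies generated from the Quad tree,
latencies generated so that D-scores track the generating association
asymmetry, and 0-10 feeling thermometers rounded from latent warmth.

Participants come from a three-component mixture: an outgroup-biased
component (associations favoring the outgroup, generated under the
outgroup-bias specification), an ingroup-biased component (mirrored), and
an indifferent component with equal associations and no latency
inflation.  Latencies are a 300 ms floor plus a lognormal body; on trials
where the participant's active association pushes against the correct
key, the trial is slowed by ``inflation_ms`` times the association's
strength.  That coupling — accuracy and latency driven by the same latent
association — is what makes D-scores and Quad parameters agree in
direction, as they must for the analysis pipeline to be exercised
end to end.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .iat_data import (
    DESIGN_STANDARD,
    BlockDesign,
    BlockOrder,
    Pairing,
    SessionRecord,
    StatusRole,
    StimulusCategory,
    TrialRecord,
)
from .quad_core import (
    ActivationMap,
    BiasDirection,
    QuadParameters,
    QuadSpecification,
    cell_probability_array,
)

__all__ = [
    "Component",
    "ComponentConfig",
    "LatencyModel",
    "ThermometerModel",
    "PopulationConfig",
    "GroundTruthRecord",
    "generate_population",
    "fixture_small",
    "FIXTURE_ERROR_TRIALS",
]


class Component(str, enum.Enum):
    OUTGROUP_BIASED = "outgroup_biased"
    INGROUP_BIASED = "ingroup_biased"
    INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class ComponentConfig:
    """Beta population for one mixture component.

    ``means`` are the population means of (ac_a, ac_b, d_detect, ob, g)
    under ``bias_direction``'s specification; ``concentration`` is the
    shared Beta concentration alpha + beta.
    """

    means: tuple[float, float, float, float, float]
    concentration: float
    bias_direction: BiasDirection
    inflation_ms: float  # latency slowdown per unit association strength
    warmth_ingroup: float  # latent warmth means on the 0-10 scale
    warmth_outgroup: float

    def __post_init__(self) -> None:
        if not all(0.0 < m < 1.0 for m in self.means):
            raise ValueError("Beta means must lie in (0, 1)")
        if not self.concentration > 2.0:
            raise ValueError("concentration must exceed 2")


@dataclass(frozen=True)
class LatencyModel:
    base_log_mean: float = math.log(350.0)  # lognormal body, ms
    base_log_sd: float = 0.4
    floor_ms: float = 300.0  # keeps the fast-trial exclusion path exercisable


@dataclass(frozen=True)
class ThermometerModel:
    sd: float = 1.8


def _default_components() -> dict[Component, ComponentConfig]:
    return {
        Component.OUTGROUP_BIASED: ComponentConfig(
            means=(0.25, 0.10, 0.85, 0.50, 0.55),
            concentration=20.0,
            bias_direction=BiasDirection.OUTGROUP_BIAS,
            inflation_ms=150.0,
            warmth_ingroup=6.2,
            warmth_outgroup=8.2,
        ),
        Component.INGROUP_BIASED: ComponentConfig(
            means=(0.25, 0.10, 0.85, 0.50, 0.55),
            concentration=20.0,
            bias_direction=BiasDirection.INGROUP_BIAS,
            inflation_ms=150.0,
            warmth_ingroup=8.5,
            warmth_outgroup=6.0,
        ),
        Component.INDIFFERENT: ComponentConfig(
            means=(0.10, 0.10, 0.85, 0.50, 0.50),
            concentration=20.0,
            bias_direction=BiasDirection.OUTGROUP_BIAS,
            inflation_ms=0.0,
            warmth_ingroup=7.0,
            warmth_outgroup=7.0,
        ),
    }


@dataclass(frozen=True)
class PopulationConfig:
    n_participants: int = 200
    group_membership: str = "lower_status_group"
    status_role: StatusRole = StatusRole.LOWER
    iat_variant: str = "race_bw"
    # mixture proportions roughly matching a large demonstration-site sample
    bias_mixture: tuple[float, float, float] = (0.35, 0.40, 0.25)
    components: dict[Component, ComponentConfig] = field(
        default_factory=_default_components
    )
    trial_design: BlockDesign = DESIGN_STANDARD
    latency_model: LatencyModel = LatencyModel()
    thermometer_model: ThermometerModel = ThermometerModel()
    activation_map: ActivationMap = ActivationMap.FACES_AND_WORDS
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.bias_mixture) - 1.0) > 1e-9:
            raise ValueError("bias_mixture proportions must sum to 1")
        if any(p < 0 for p in self.bias_mixture):
            raise ValueError("bias_mixture proportions must be nonnegative")


@dataclass(frozen=True)
class GroundTruthRecord:
    participant_id: str
    component: Component
    params: QuadParameters
    bias_direction: BiasDirection
    warmth_ingroup: float
    warmth_outgroup: float


_CATEGORY_CYCLE = (
    StimulusCategory.INGROUP_TARGET,
    StimulusCategory.PLEASANT_WORD,
    StimulusCategory.OUTGROUP_TARGET,
    StimulusCategory.UNPLEASANT_WORD,
)

_PRACTICE_CATEGORIES = {
    1: (StimulusCategory.PLEASANT_WORD, StimulusCategory.UNPLEASANT_WORD),
    2: (StimulusCategory.INGROUP_TARGET, StimulusCategory.OUTGROUP_TARGET),
    5: (StimulusCategory.INGROUP_TARGET, StimulusCategory.OUTGROUP_TARGET),
}


def _pairing_of_block(block: int, order: BlockOrder) -> Pairing | None:
    if block in (3, 4):
        first = True
    elif block in (6, 7):
        first = False
    else:
        return None
    if order is BlockOrder.INGROUP_PLEASANT_FIRST:
        return Pairing.INGROUP_PLEASANT if first else Pairing.OUTGROUP_PLEASANT
    return Pairing.OUTGROUP_PLEASANT if first else Pairing.INGROUP_PLEASANT


def generate_population(
    config: PopulationConfig = PopulationConfig(),
) -> tuple[list[SessionRecord], list[GroundTruthRecord]]:
    """Generate a full synthetic sample with its ground truth.

    Fully reproducible from ``config.seed``: per-participant component
    assignment, process parameters, critical-block order, trial accuracies,
    latencies, and thermometer ratings all derive from one seed sequence.
    """
    rng = np.random.default_rng(config.seed)
    lat = config.latency_model
    components = list(Component)  # mixture order: outgroup, ingroup, indifferent
    for comp, weight in zip(components, config.bias_mixture):
        if weight > 0 and comp not in config.components:
            raise ValueError(f"mixture gives weight to unconfigured {comp.value}")
    comp_draws = rng.choice(len(components), size=config.n_participants,
                            p=np.asarray(config.bias_mixture))

    sessions: list[SessionRecord] = []
    truths: list[GroundTruthRecord] = []
    for i in range(config.n_participants):
        comp = components[comp_draws[i]]
        cc = config.components[comp]
        means = np.asarray(cc.means)
        theta = rng.beta(means * cc.concentration, (1.0 - means) * cc.concentration)
        params = QuadParameters.from_array(theta)
        spec = QuadSpecification(cc.bias_direction, config.activation_map)
        wirings = {cell: spec.wiring(cell) for cell in
                   [(c, p) for c in StimulusCategory for p in Pairing]}
        p_correct = dict(
            zip(wirings, cell_probability_array(theta, spec))
        )
        order = (
            BlockOrder.INGROUP_PLEASANT_FIRST
            if rng.uniform() < 0.5
            else BlockOrder.OUTGROUP_PLEASANT_FIRST
        )

        trials: list[TrialRecord] = []
        for block in range(1, 8):
            n_trials = config.trial_design.block_lengths[block - 1]
            pairing = _pairing_of_block(block, order)
            for trial in range(1, n_trials + 1):
                if pairing is None:
                    category = _PRACTICE_CATEGORIES[block][(trial - 1) % 2]
                    # practice: detection plus unbiased guessing
                    p = theta[2] + (1.0 - theta[2]) * 0.5
                    inflate = 0.0
                else:
                    category = _CATEGORY_CYCLE[(trial - 1) % 4]
                    cell = (category, pairing)
                    p = p_correct[cell]
                    w = wirings[cell]
                    inflate = 0.0
                    if w.ac_index >= 0 and not w.push_correct:
                        inflate = cc.inflation_ms * theta[w.ac_index]
                correct = bool(rng.uniform() < p)
                latency = lat.floor_ms + rng.lognormal(lat.base_log_mean,
                                                       lat.base_log_sd) + inflate
                trials.append(
                    TrialRecord(block, trial, category, pairing, correct,
                                float(latency))
                )

        tm = config.thermometer_model
        warm_in = float(np.clip(round(rng.normal(cc.warmth_ingroup, tm.sd)), 0, 10))
        warm_out = float(np.clip(round(rng.normal(cc.warmth_outgroup, tm.sd)), 0, 10))
        pid = f"sim{i:05d}"
        sessions.append(
            SessionRecord(
                participant_id=pid,
                group_membership=config.group_membership,
                status_role=config.status_role,
                iat_variant=config.iat_variant,
                critical_block_order=order,
                trials=trials,
                thermometer_ingroup=int(warm_in),
                thermometer_outgroup=int(warm_out),
            )
        )
        truths.append(
            GroundTruthRecord(pid, comp, params, cc.bias_direction,
                              cc.warmth_ingroup, cc.warmth_outgroup)
        )
    return sessions, truths


def ground_truth_frame(truths: Sequence[GroundTruthRecord]):
    """Ground truth as a pandas DataFrame (one row per participant)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in truths],
            "component": [t.component.value for t in truths],
            "bias_direction": [t.bias_direction.value for t in truths],
            "ac_a": [t.params.ac_a for t in truths],
            "ac_b": [t.params.ac_b for t in truths],
            "d_detect": [t.params.d_detect for t in truths],
            "ob": [t.params.ob for t in truths],
            "g": [t.params.g for t in truths],
            "warmth_ingroup": [t.warmth_ingroup for t in truths],
            "warmth_outgroup": [t.warmth_outgroup for t in truths],
        }
    )


# ---------------------------------------------------------------------------
# hand-checkable fixture

#: (block, trial) positions of the deliberate errors in fixture participant f1.
#: The category cycle puts trial 1 on an ingroup face and trial 2 on a
#: pleasant word, so the hand tally is one error in each of those two cells.
FIXTURE_ERROR_TRIALS = ((3, 1), (3, 2))


def _fixture_session(
    pid: str,
    status: StatusRole,
    order: BlockOrder,
    latency_by_pairing: dict[Pairing, float],
    errors: tuple[tuple[int, int], ...] = (),
    thermo: tuple[int, int] | None = None,
    practice_latency: float = 700.0,
) -> SessionRecord:
    trials: list[TrialRecord] = []
    design = DESIGN_STANDARD
    for block in range(1, 8):
        pairing = _pairing_of_block(block, order)
        for trial in range(1, design.block_lengths[block - 1] + 1):
            if pairing is None:
                category = _PRACTICE_CATEGORIES[block][(trial - 1) % 2]
                base = practice_latency
            else:
                category = _CATEGORY_CYCLE[(trial - 1) % 4]
                base = latency_by_pairing[pairing]
            jitter = 25.0 if trial % 2 else -25.0  # deterministic, nonzero SD
            trials.append(
                TrialRecord(
                    block,
                    trial,
                    category,
                    pairing,
                    (block, trial) not in errors,
                    base + jitter,
                )
            )
    return SessionRecord(
        participant_id=pid,
        group_membership="fixture_group",
        status_role=status,
        iat_variant="race_bw",
        critical_block_order=order,
        trials=trials,
        thermometer_ingroup=None if thermo is None else thermo[0],
        thermometer_outgroup=None if thermo is None else thermo[1],
    )


def fixture_small() -> list[SessionRecord]:
    """Six deterministic, hand-checkable sessions.

    * f1 - lower status, slower under ingroup-pleasant: outgroup-biased by
      D, with two deliberate errors in block 3 (see
      :data:`FIXTURE_ERROR_TRIALS`) for hand-tallied count tables.
    * f2 - lower status, mirrored latencies: ingroup-biased by D.
    * f3 - lower status, identical latencies in both pairings: D = 0,
      unclassified; thermometer tie (6, 6).
    * f4 - higher status, faster under outgroup-pleasant: outgroup-biased.
    * f5 - lower status, asymmetry too small to cross the 0.15 D
      threshold: unclassified.
    * f6 - lower status, latencies mostly under 300 ms: excluded by the
      fast-trial rule.
    """
    ip, op = Pairing.INGROUP_PLEASANT, Pairing.OUTGROUP_PLEASANT
    lower, higher = StatusRole.LOWER, StatusRole.HIGHER
    first = BlockOrder.INGROUP_PLEASANT_FIRST
    second = BlockOrder.OUTGROUP_PLEASANT_FIRST
    return [
        _fixture_session("f1", lower, first, {ip: 850.0, op: 650.0},
                         errors=FIXTURE_ERROR_TRIALS, thermo=(4, 8)),
        _fixture_session("f2", lower, second, {ip: 650.0, op: 850.0},
                         thermo=(9, 3)),
        _fixture_session("f3", lower, first, {ip: 700.0, op: 700.0},
                         thermo=(6, 6)),
        _fixture_session("f4", higher, second, {ip: 850.0, op: 650.0},
                         thermo=(5, 8)),
        _fixture_session("f5", lower, first, {ip: 702.0, op: 700.0},
                         thermo=(7, 5)),
        _fixture_session("f6", lower, first, {ip: 260.0, op: 255.0},
                         practice_latency=260.0, thermo=(5, 5)),
    ]
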