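"""Canonical simulation scenarios for the calibration and validation suite.

Each function returns a :class:`SimulationConfig` describing one study
condition at the default desk scale (20 subjects/group, 60 units, 169 TRs,
TR = 3 s, two 6-node networks). They are used both by the test suite and by
the reproduction script, so the conditions are defined once.

Scenario rationale
------------------
* ``opposite_loading`` — the two groups load the shared stimulus course with
  opposite strength on the two networks (theory-of-mind units stronger in
  controls, affective-empathy units stronger in patients), the qualitative
  pattern the group ISC contrast is meant to recover.
* ``epoch_cohesion`` — a within-network latent switched on during a mid-movie
  epoch for the patient group only (sustained cohesion, amplitude 1.5 —
  edge correlation ~0.7 against unit noise), while controls carry none:
  the sliding-window NCI group test should flag windows inside that epoch.
* ``global_cohesion`` — the same epoch latent applied to every unit of the
  brain pool at moderate amplitude 0.8, a whole-brain effect that spatial
  specificity should *not* attribute to the target network. The amplitude is
  deliberately moderate: at saturating effect sizes the rank-sum statistic
  hits its finite-sample maximum everywhere and its percentile is no longer
  informative.
* ``behavior_power`` / ``behavior_null`` — behavior coupled to the subject
  synchrony gain at Spearman-scale rho = 0.7 (or 0), with a strong loading
  (alpha = 1) so per-subject ISC is an informative readout of the gain.
* ``white_noise_null`` — a global-null dataset (no shared signal, white
  noise) at a reduced scale for family-wise-error calibration.
"""

from __future__ import annotations

import numpy as np

from .simulate import NetworkSpec, SimulationConfig

__all__ = [
    "TOM_UNITS",
    "AFFECTIVE_UNITS",
    "POOL_UNITS",
    "EPOCH",
    "opposite_loading",
    "epoch_cohesion",
    "global_cohesion",
    "behavior_power",
    "behavior_null",
    "white_noise_null",
]

#: unit layout of the default 60-unit pool
TOM_UNITS = np.arange(0, 6)
AFFECTIVE_UNITS = np.arange(6, 12)
POOL_UNITS = np.arange(12, 60)

#: the planted cohesion epoch, TRs [60, 100) — mid-movie, before the
#: rating peak, mirroring a sustained emotional build-up
EPOCH = (60, 100)

_NETWORKS = (
    NetworkSpec("tom", tuple(TOM_UNITS)),
    NetworkSpec("affective", tuple(AFFECTIVE_UNITS)),
)


def opposite_loading(seed: int) -> SimulationConfig:
    """Controls load ToM units at 0.8 vs patients 0.3; reversed on affective."""
    a_patient = np.full(60, 0.5)
    a_control = np.full(60, 0.5)
    a_patient[TOM_UNITS], a_control[TOM_UNITS] = 0.3, 0.8
    a_patient[AFFECTIVE_UNITS], a_control[AFFECTIVE_UNITS] = 0.8, 0.3
    return SimulationConfig(
        alpha_load={"pmdd": a_patient, "control": a_control},
        network_spec=_NETWORKS,
        seed=seed,
    )


def epoch_cohesion(seed: int, beta: float = 1.5) -> SimulationConfig:
    """Patients sustain ToM-network cohesion inside the epoch; controls do not."""
    return SimulationConfig(
        network_spec=(
            NetworkSpec(
                "tom",
                tuple(TOM_UNITS),
                epochs=(EPOCH,),
                beta={"pmdd": beta, "control": 0.0},
            ),
            NetworkSpec("affective", tuple(AFFECTIVE_UNITS)),
        ),
        seed=seed,
    )


def global_cohesion(seed: int, beta: float = 0.8) -> SimulationConfig:
    """A whole-brain epoch effect in patients (for specificity calibration)."""
    return SimulationConfig(
        network_spec=(
            NetworkSpec(
                "global",
                tuple(range(60)),
                epochs=(EPOCH,),
                beta={"pmdd": beta, "control": 0.0},
            ),
        ),
        seed=seed,
    )


def behavior_power(seed: int, rho: float = 0.7) -> SimulationConfig:
    """Behavior coupled to the subject gain; strong loading for ISC readout."""
    return SimulationConfig(
        alpha_load=1.0,
        behav_rho=rho,
        network_spec=_NETWORKS,
        seed=seed,
    )


def behavior_null(seed: int) -> SimulationConfig:
    return behavior_power(seed, rho=0.0)


def white_noise_null(
    seed: int, n_per_group: int = 3, n_units: int = 10, n_tr: int = 100
) -> SimulationConfig:
    """Global null: independent white noise, no gain spread, no AR."""
    return SimulationConfig(
        n_per_group=n_per_group,
        n_units=n_units,
        n_tr=n_tr,
        alpha_load=0.0,
        subject_gain_sd=0.0,
        ar_phi=0.0,
        network_spec=(),
        seed=seed,
    )
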