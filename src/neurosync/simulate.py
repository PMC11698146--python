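"""Synthetic two-group naturalistic-stimulation datasets.

Generates multi-subject node-by-time signals with the statistical structure
the downstream analyses assume, so the whole pipeline can be exercised and
calibrated without any imaging data.

Generative model
----------------
For subject ``i`` in group ``g(i)``, unit ``v`` and TR ``t``::

    x_{i,v}(t) = lam_i * alpha_{g(i),v} * c_v(t)
               + sum_k beta_{g(i),k} * 1[t in epoch_k] * u_{i,k}(t) * w_{k,v}
               + eps_{i,v}(t)

where

* ``c_v`` is a stimulus-locked course shared by **all** subjects (one per
  unit): Gaussian white noise smoothed with a 3-TR moving average and
  z-scored, giving BOLD-like temporal autocorrelation without committing to
  a hemodynamic response model;
* ``lam_i ~ Normal(1, tau^2)`` is a per-subject synchrony gain — the causal
  quantity behavior scores couple to;
* ``u_{i,k}`` is a subject-specific latent of network ``k`` (smoothed,
  z-scored). It is private to the subject, so it drives within-subject
  network cohesion during its epochs without adding cross-subject synchrony;
* ``w_{k,v}`` is 1 for member units of network ``k``, else 0;
* ``eps`` is stationary AR(1) noise: ``eps(t) = phi * eps(t-1) + eta(t)``
  with ``eta ~ Normal(0, sigma^2)``.

All randomness flows through one seeded :class:`numpy.random.Generator`
spawned from ``SimulationConfig.seed``; identical configs produce
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d
from scipy.signal import lfilter

from .datasets import (
    GROUPS,
    IRI_SUBSCALES,
    SYMPTOMS,
    BehavioralTable,
    NetworkDefinition,
    RatingCurve,
    SubjectTimeSeries,
)

__all__ = [
    "ConfigError",
    "NetworkSpec",
    "SimulationConfig",
    "SimulationTruth",
    "SyntheticDataset",
    "default_config",
    "gen_dataset",
    "gen_behavior",
    "gen_rating",
]

_SMOOTH_KERNEL = np.ones(3) / 3.0  # 3-TR moving average for latent courses


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""

    def __init__(self, fieldname: str, message: str) -> None:
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class NetworkSpec:
    """A simulated network: member units, active epochs, cohesion amplitude.

    ``epochs`` are half-open TR windows ``[start, stop)`` during which the
    network latent is switched on. ``beta`` is the cohesion amplitude,
    either one float for both groups or a mapping ``group -> float``.
    """

    name: str
    members: tuple[int, ...]
    epochs: tuple[tuple[int, int], ...] = ()
    beta: float | Mapping[str, float] = 0.0

    def beta_for(self, group: str) -> float:
        if isinstance(self.beta, Mapping):
            return float(self.beta.get(group, 0.0))
        return float(self.beta)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset generator.

    Defaults mirror the study scale: 20 subjects per group, 169 TRs at
    TR = 3 s (an 8 min 27 s movie), 60 units containing two 6-node
    networks.
    """

    n_per_group: int = 20
    n_units: int = 60
    n_tr: int = 169
    tr_seconds: float = 3.0
    #: shared-signal loading, unitless: scalar, or mapping group -> scalar
    #: or group -> array of length n_units.
    alpha_load: float | Mapping[str, float | np.ndarray] = 0.5
    #: SD tau of the per-subject synchrony gain lam ~ Normal(1, tau^2).
    subject_gain_sd: float = 0.3
    network_spec: tuple[NetworkSpec, ...] = ()
    ar_phi: float = 0.3
    noise_sd: float = 1.0
    #: target coupling of behavior scores to the subject gain, in [-1, 1].
    behav_rho: float = 0.5
    seed: int = 0

    def alpha_for(self, group: str) -> np.ndarray:
        """Per-unit loading vector for a group."""
        a = self.alpha_load
        if isinstance(a, Mapping):
            a = a.get(group, 0.0)
        arr = np.broadcast_to(np.asarray(a, dtype=float), (self.n_units,))
        return arr.copy()

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ConfigError("n_per_group", "need at least 3 subjects per group")
        if self.n_units < 1:
            raise ConfigError("n_units", "need at least 1 unit")
        if self.n_tr < 2:
            raise ConfigError("n_tr", "need at least 2 time points")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds", "must be positive")
        if not 0 <= self.ar_phi < 1:
            raise ConfigError("ar_phi", f"must lie in [0, 1), got {self.ar_phi}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd", "must be nonnegative")
        if self.subject_gain_sd < 0:
            raise ConfigError("subject_gain_sd", "must be nonnegative")
        rhos = (
            list(self.behav_rho.values())
            if isinstance(self.behav_rho, Mapping)
            else [self.behav_rho]
        )
        if any(abs(r) > 1 for r in rhos):
            raise ConfigError("behav_rho", f"|rho| must be <= 1, got {self.behav_rho}")
        for net in self.network_spec:
            members = np.asarray(net.members, dtype=int)
            if members.size and (members.min() < 0 or members.max() >= self.n_units):
                raise ConfigError(
                    "network_spec",
                    f"network {net.name!r} has unit indices outside "
                    f"[0, {self.n_units})",
                )
            if len(set(net.members)) != len(net.members):
                raise ConfigError(
                    "network_spec", f"network {net.name!r} has duplicate members"
                )
            for start, stop in net.epochs:
                if not (0 <= start < stop <= self.n_tr):
                    raise ConfigError(
                        "network_spec",
                        f"network {net.name!r} epoch ({start}, {stop}) outside "
                        f"[0, {self.n_tr})",
                    )


@dataclass
class SimulationTruth:
    """Record of the generating parameters, for recovery tests.

    Holds everything needed to reproduce the dataset bit-identically
    (the config, including its seed) plus the realized latent quantities.
    """

    config: SimulationConfig
    subject_ids: list[str]
    groups: list[str]
    #: realized per-subject synchrony gains lam_i, in subject order.
    gains: np.ndarray
    #: per-group per-unit loadings actually applied.
    alpha: dict[str, np.ndarray]
    networks: tuple[NetworkSpec, ...]
    #: the shared stimulus course c, shape (n_units, n_tr).
    shared_course: np.ndarray = field(repr=False, default=None)

    def gains_for(self, group: str) -> np.ndarray:
        mask = np.asarray([g == group for g in self.groups])
        return self.gains[mask]


@dataclass
class SyntheticDataset:
    subjects: list[SubjectTimeSeries]
    behavior: BehavioralTable
    rating: RatingCurve
    truth: SimulationTruth

    def group_subjects(self, group: str) -> list[SubjectTimeSeries]:
        return [s for s in self.subjects if s.group == group]


def default_config(**overrides) -> SimulationConfig:
    """Study-scale default configuration.

    Two 6-node networks — a theory-of-mind network (units 0–5) and an
    affective-empathy network (units 6–11) — inside a 60-unit pool, 20
    subjects per group, 169 TRs at TR = 3 s.
    """
    networks = (
        NetworkSpec("tom", members=tuple(range(0, 6))),
        NetworkSpec("affective", members=tuple(range(6, 12))),
    )
    cfg = SimulationConfig(network_spec=networks)
    return replace(cfg, **overrides) if overrides else cfg


def _smooth_standard(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """White noise smoothed with a 3-TR moving average, z-scored along time."""
    x = rng.standard_normal(shape)
    x = convolve1d(x, _SMOOTH_KERNEL, axis=-1, mode="nearest")
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], phi: float, sd: float
) -> np.ndarray:
    """Stationary AR(1) noise along the last axis."""
    eta = rng.standard_normal(shape) * sd
    if phi == 0:
        return eta
    # scale the first innovation so the process starts in its stationary law
    eta[..., 0] /= np.sqrt(1.0 - phi**2)
    return lfilter([1.0], [1.0, -phi], eta, axis=-1)


def gen_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a seeded synthetic two-group dataset.

    Returns subjects, a behavior table coupled to the subject gains at
    ``cfg.behav_rho``, a sadness-rating curve, and the truth record.
    Identical configs (including seed) yield bit-identical output.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    seq_signal, seq_behav, seq_rating = root.spawn(3)
    rng = np.random.default_rng(seq_signal)

    # shared stimulus course, one per unit, common to all subjects
    c = _smooth_standard(rng, (cfg.n_units, cfg.n_tr))

    alpha = {g: cfg.alpha_for(g) for g in GROUPS}
    epoch_masks = []
    for net in cfg.network_spec:
        m = np.zeros(cfg.n_tr)
        for start, stop in net.epochs:
            m[start:stop] = 1.0
        epoch_masks.append(m)

    subjects: list[SubjectTimeSeries] = []
    ids: list[str] = []
    groups: list[str] = []
    gains: list[float] = []
    prefix = {"pmdd": "pmdd", "control": "ctrl"}
    for group in GROUPS:
        for j in range(cfg.n_per_group):
            sid = f"{prefix[group]}{j + 1:02d}"
            lam = 1.0 + cfg.subject_gain_sd * rng.standard_normal()
            x = lam * alpha[group][:, None] * c
            for net, mask in zip(cfg.network_spec, epoch_masks):
                beta = net.beta_for(group)
                u = _smooth_standard(rng, (cfg.n_tr,))  # drawn even if beta=0,
                # so switching beta on/off does not reshuffle the RNG stream
                if beta != 0.0 and len(net.members):
                    x[list(net.members), :] += beta * mask * u
            x += _ar1_noise(rng, (cfg.n_units, cfg.n_tr), cfg.ar_phi, cfg.noise_sd)
            subjects.append(
                SubjectTimeSeries(sid, group, x, tr_seconds=cfg.tr_seconds)
            )
            ids.append(sid)
            groups.append(group)
            gains.append(lam)

    truth = SimulationTruth(
        config=cfg,
        subject_ids=ids,
        groups=groups,
        gains=np.asarray(gains),
        alpha=alpha,
        networks=cfg.network_spec,
        shared_course=c,
    )
    behavior = gen_behavior(truth, rho=cfg.behav_rho, seed=seq_behav)
    # peak window scales with the series: the study-scale default (TRs
    # 85-115 of 169) sits at fractions 0.50-0.68 of the timeline
    peak = (int(0.50 * cfg.n_tr), max(int(0.50 * cfg.n_tr) + 1, int(0.68 * cfg.n_tr)))
    rating = gen_rating(cfg.n_tr, peak_window=peak, seed=seq_rating)
    return SyntheticDataset(subjects, behavior, rating, truth)


# affine maps from standardized scores to questionnaire-like ranges:
# IRI subscales score 0-28 (centre 14, spread 5); symptoms ordinal-like 0-20.
_IRI_LOC, _IRI_SCALE = 14.0, 5.0
_SYM_LOC, _SYM_SCALE = 10.0, 3.0


def gen_behavior(
    truth: SimulationTruth,
    rho: float | Mapping[str, float] | None = None,
    seed=None,
    measures: Sequence[str] | None = None,
) -> BehavioralTable:
    """Generate behavior scores coupled to the per-subject synchrony gains.

    Each measure column ``b`` is built as
    ``b = rho * z(lam) + sqrt(1 - rho^2) * Normal(0, 1)`` from the
    standardized gains ``z(lam)``, then affinely mapped to a
    questionnaire-like range (no clipping, so monotonicity in ``lam`` is
    exact at ``|rho| = 1``). The sample correlation of ``b`` with ``lam``
    converges to ``rho`` as n grows.

    Parameters
    ----------
    rho : float or mapping, optional
        Coupling per measure (scalar applies to every measure). Defaults to
        the config's ``behav_rho``.
    """
    if rho is None:
        rho = truth.config.behav_rho
    if measures is None:
        measures = list(IRI_SUBSCALES) + list(SYMPTOMS)

    def rho_for(col: str) -> float:
        r = rho.get(col, 0.0) if isinstance(rho, Mapping) else float(rho)
        if abs(r) > 1:
            raise ValueError(f"|rho| must be <= 1, got {r} for {col!r}")
        return r

    rng = np.random.default_rng(seed)
    lam = np.asarray(truth.gains, dtype=float)
    sd = lam.std()
    z = (lam - lam.mean()) / (sd if sd > 0 else 1.0)

    cols: dict[str, np.ndarray] = {
        "subject_id": np.asarray(truth.subject_ids),
        "group": np.asarray(truth.groups),
    }
    for col in measures:
        r = rho_for(col)
        b = r * z + np.sqrt(1.0 - r**2) * rng.standard_normal(lam.size)
        if col in IRI_SUBSCALES:
            cols[col] = _IRI_LOC + _IRI_SCALE * b
        else:
            cols[col] = _SYM_LOC + _SYM_SCALE * b
    return BehavioralTable(pd.DataFrame(cols))


def gen_rating(
    n_tr: int,
    peak_window: tuple[int, int] = (85, 115),
    scale_max: float = 6.0,
    seed=None,
) -> RatingCurve:
    """Generate a unimodal sadness-rating curve (median and MAD per TR).

    The median curve is a low baseline plus a Gaussian bump centred in
    ``peak_window`` reaching ~0.9 * ``scale_max``, with light smoothed
    jitter; the MAD curve is a small positive dispersion band. All values
    lie in ``[0, scale_max]``.
    """
    start, stop = peak_window
    if not (0 <= start < stop <= n_tr):
        raise ValueError(
            f"peak_window ({start}, {stop}) must lie inside [0, {n_tr})"
        )
    if scale_max <= 0:
        raise ValueError("scale_max must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_tr, dtype=float)
    centre = 0.5 * (start + stop - 1)
    width = max((stop - start) / 2.0, 1.0)
    bump = np.exp(-0.5 * ((t - centre) / width) ** 2)
    median = scale_max * (0.15 + 0.75 * bump)
    median += 0.02 * scale_max * _smooth_standard(rng, (n_tr,))
    median = np.clip(median, 0.0, scale_max)
    # keep the argmax inside the requested peak window despite the jitter
    inside = np.zeros(n_tr, bool)
    inside[start:stop] = True
    if not inside[np.argmax(median)]:
        k = start + int(np.argmax(median[start:stop]))
        median[k] = min(scale_max, median.max() + 1e-6)
    mad = np.clip(
        0.08 * scale_max * (1.0 + 0.3 * _smooth_standard(rng, (n_tr,))),
        0.0,
        scale_max,
    )
    return RatingCurve(median=median, mad=mad, scale_max=scale_max)
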