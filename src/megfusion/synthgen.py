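"""Synthetic study generator with planted representational geometry.

Emulates the data layout of a threshold-level object recognition study:
300 real-image trials per participant (5 exemplars x 4 categories, each
presented 15 times), ~50% of trials reported as recognized, 272 MEG sensors
epoched from -500 to 2000 ms, and per-ROI fMRI voxel patterns.  Three
representational effects can be planted with known amplitudes and time
windows, so every downstream analysis has a recoverable ground truth:

* ``category_effect`` — a category-specific sensor template added to
  recognized trials only (category information is absent when recognition
  fails);
* ``two_state_offset`` — an outcome-specific template shared by all trials
  with the same recognition outcome (pattern bifurcation into a
  "recognized" and an "unrecognized" brain state);
* ``recognition_shrink`` — shrinkage (< 1) of the across-exemplar pattern
  variability in recognized trials.  Patterns cluster around a shared
  "recognized" center: the exemplar component becomes
  sqrt(1 - shrink) * center + sqrt(shrink) * exemplar, which shrinks the
  idiosyncratic variance by the factor ``shrink`` while preserving total
  pattern energy.  (A pure variance rescaling would be invisible to
  correlation-distance RDMs, which normalize amplitude; clustering in
  correlation space requires a shared direction.)

All templates are drawn once per dataset from a seeded standard normal;
noise is i.i.d. Gaussian across sensors/voxels and time.  These are
modeling stand-ins — no empirical generative model is implied — and they
are recorded as such in the :class:`GroundTruth` table.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .conditions import (
    CATEGORIES,
    N_CONDITIONS,
    N_EXEMPLARS_PER_CATEGORY,
    N_REAL_EXEMPLARS,
    condition_index,
    condition_position,
)

__all__ = [
    "ConfigError",
    "EffectWindow",
    "RoiProfile",
    "SimulationConfig",
    "EpochedDataset",
    "RunDesign",
    "default_roi_profiles",
    "generate_behavior",
    "generate_meg_epochs",
    "generate_fmri_patterns",
]


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class EffectWindow:
    """An additive effect amplitude gated by a rectangular time window."""

    amplitude: float
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.end_ms < self.start_ms:
            raise ConfigError(
                f"effect window end ({self.end_ms}) before start ({self.start_ms})"
            )

    def mask(self, time_ms: np.ndarray) -> np.ndarray:
        return (time_ms >= self.start_ms) & (time_ms <= self.end_ms)


@dataclass(frozen=True)
class RoiProfile:
    """Planted geometry mixture for one fMRI region of interest."""

    two_state_weight: float
    recognition_weight: float
    network: str


def default_roi_profiles() -> dict[str, RoiProfile]:
    """Study-like ROI set: visual regions two-state dominant, frontoparietal
    regions recognition-model dominant."""
    profiles: dict[str, RoiProfile] = {}
    for roi in ("V1", "V2", "V3"):
        profiles[roi] = RoiProfile(1.0, 0.3, "Visual")
    for cat in CATEGORIES:
        profiles[f"VTC_{cat}"] = RoiProfile(1.0, 0.4, "Visual")
    for roi in ("L_MFG", "R_MFG"):
        profiles[roi] = RoiProfile(0.1, 1.0, "FPCN")
    for roi in ("L_IPS", "R_IPS", "R_IFJ"):
        profiles[roi] = RoiProfile(0.05, 1.0, "DAN")
    for roi in ("L_aInsula", "R_aInsula"):
        profiles[roi] = RoiProfile(0.15, 1.0, "SAL")
    for roi in ("PCC", "mPFC", "L_AG", "R_AG"):
        profiles[roi] = RoiProfile(0.15, 1.0, "DMN")
    return profiles


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; ``seed`` fixes outputs bit-for-bit."""

    n_subjects_meg: int = 24
    n_subjects_fmri: int = 25
    n_trials: int = 300
    n_sensors: int = 272
    n_voxels_per_roi: int = 200
    sfreq_hz: float = 400.0
    epoch_window_ms: tuple[float, float] = (-500.0, 2000.0)
    p_recognized: float = 0.5
    acc_recognized: float = 0.861
    acc_unrecognized: float = 0.401
    category_effect: EffectWindow = EffectWindow(1.0, 400.0, 1000.0)
    exemplar_effect: EffectWindow = EffectWindow(1.0, 100.0, 2000.0)
    two_state_offset: EffectWindow = EffectWindow(1.0, 200.0, 1900.0)
    recognition_shrink: float = 0.3
    shrink_window_ms: tuple[float, float] = (130.0, 1900.0)
    noise_sd: float = 1.0
    n_runs_fmri: int = 15
    tr_s: float = 2.0
    roi_profiles: dict[str, RoiProfile] = field(default_factory=default_roi_profiles)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_recognized", "acc_recognized", "acc_unrecognized"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if not 0.0 < self.recognition_shrink <= 1.0:
            raise ConfigError(
                f"recognition_shrink must lie in (0, 1], got {self.recognition_shrink}"
            )
        if self.n_trials % N_REAL_EXEMPLARS != 0:
            raise ConfigError(
                f"n_trials must be a multiple of {N_REAL_EXEMPLARS} so each "
                f"exemplar repeats equally often, got {self.n_trials}"
            )
        t0, t1 = self.epoch_window_ms
        if t1 <= t0:
            raise ConfigError("epoch window must have positive length")
        for label, win in (
            ("category_effect", self.category_effect),
            ("exemplar_effect", self.exemplar_effect),
            ("two_state_offset", self.two_state_offset),
            ("recognition_shrink", EffectWindow(0.0, *self.shrink_window_ms)),
        ):
            if win.start_ms < t0 or win.end_ms > t1:
                raise ConfigError(
                    f"{label} window [{win.start_ms}, {win.end_ms}] ms lies "
                    f"outside the epoch [{t0}, {t1}] ms"
                )

    def rng(self, stream: str) -> np.random.Generator:
        """A named, reproducible random stream derived from ``seed``.

        Distinct stream names give statistically independent generators;
        the same (seed, name) pair always yields the same stream.
        """
        key = zlib.crc32(stream.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    def time_axis_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sfreq_hz
        t0, t1 = self.epoch_window_ms
        n = int(round((t1 - t0) / dt)) + 1
        return t0 + dt * np.arange(n)


@dataclass
class EpochedDataset:
    """Trials x sensors x time array with per-trial condition labels."""

    data: np.ndarray
    time_ms: np.ndarray
    labels: pd.DataFrame  # columns: exemplar, category, outcome
    sfreq_hz: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x time")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis length does not match data")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length does not match trial count")
        if self.labels["category"].nunique() > 4:
            raise ValueError("more than 4 categories in labels")
        if self.labels["outcome"].nunique() > 2:
            raise ValueError("more than 2 recognition outcomes in labels")
        if self.labels.groupby("category")["exemplar"].nunique().max() > 5:
            raise ValueError("more than 5 exemplars in a category")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    def condition_codes(self) -> np.ndarray:
        """Canonical 0-39 condition position per trial."""
        return np.array(
            [
                condition_position(o, c, e)
                for o, c, e in zip(
                    self.labels["outcome"], self.labels["category"], self.labels["exemplar"]
                )
            ]
        )


def generate_behavior(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the behavioral table of one participant.

    Each of the 20 real images appears ``n_trials / 20`` times.  The
    recognition outcome is Bernoulli(``p_recognized``); the 4-alternative
    categorization response is correct with probability ``acc_recognized``
    (recognized trials) or ``acc_unrecognized`` (unrecognized trials), with
    errors uniform over the other three categories.
    """
    rng = config.rng("behavior")
    reps = config.n_trials // N_REAL_EXEMPLARS
    categories = np.repeat(
        np.tile(np.arange(len(CATEGORIES)), N_EXEMPLARS_PER_CATEGORY), reps
    )
    exemplars = np.repeat(
        np.tile(np.arange(1, N_EXEMPLARS_PER_CATEGORY + 1), len(CATEGORIES)), reps
    )
    order = rng.permutation(config.n_trials)
    categories, exemplars = categories[order], exemplars[order]

    recognized = rng.random(config.n_trials) < config.p_recognized
    acc = np.where(recognized, config.acc_recognized, config.acc_unrecognized)
    correct = rng.random(config.n_trials) < acc
    # errors: uniform over the three other categories
    shift = rng.integers(1, len(CATEGORIES), size=config.n_trials)
    responses = np.where(
        correct, categories, (categories + shift) % len(CATEGORIES)
    )
    return pd.DataFrame(
        {
            "trial": np.arange(config.n_trials),
            "exemplar": exemplars,
            "category": [CATEGORIES[c] for c in categories],
            "outcome": np.where(recognized, "recognized", "unrecognized"),
            "response": [CATEGORIES[c] for c in responses],
            "correct": correct,
        }
    )


def _ground_truth_rows(config: SimulationConfig) -> list[dict]:
    note = "synthetic stand-in; additive Gaussian templates, no empirical generative model"
    rows = [
        {
            "scope": "meg",
            "effect": "category_effect",
            "amplitude": config.category_effect.amplitude,
            "start_ms": config.category_effect.start_ms,
            "end_ms": config.category_effect.end_ms,
            "note": note,
        },
        {
            "scope": "meg",
            "effect": "two_state_offset",
            "amplitude": config.two_state_offset.amplitude,
            "start_ms": config.two_state_offset.start_ms,
            "end_ms": config.two_state_offset.end_ms,
            "note": note,
        },
        {
            "scope": "meg",
            "effect": "recognition_shrink",
            "amplitude": config.recognition_shrink,
            "start_ms": config.shrink_window_ms[0],
            "end_ms": config.shrink_window_ms[1],
            "note": note,
        },
    ]
    for roi, prof in config.roi_profiles.items():
        rows.append(
            {
                "scope": f"roi:{roi}",
                "effect": "two_state_weight",
                "amplitude": prof.two_state_weight,
                "start_ms": np.nan,
                "end_ms": np.nan,
                "note": f"network={prof.network}; {note}",
            }
        )
        rows.append(
            {
                "scope": f"roi:{roi}",
                "effect": "recognition_weight",
                "amplitude": prof.recognition_weight,
                "start_ms": np.nan,
                "end_ms": np.nan,
                "note": f"network={prof.network}; {note}",
            }
        )
    return rows


def generate_meg_epochs(
    config: SimulationConfig, behavior: pd.DataFrame
) -> tuple[EpochedDataset, pd.DataFrame]:
    """Simulate sensor-level epochs for the trials in ``behavior``.

    Per-trial signal = Gaussian baseline noise
    + category template x ``category_effect`` (recognized trials, in window)
    + outcome template x ``two_state_offset`` (in window)
    + exemplar-specific component whose standard deviation is scaled by
      ``sqrt(recognition_shrink)`` for recognized trials inside the
      shrink window.

    The pre-stimulus baseline is pure noise by construction (all default
    effect windows are post-stimulus).  Returns the dataset and the
    ground-truth table of planted parameters.
    """
    if len(behavior) == 0:
        raise ConfigError("behavior table is empty")
    rng = config.rng("meg_templates")
    time_ms = config.time_axis_ms()
    n_trials, n_sensors, n_times = len(behavior), config.n_sensors, time_ms.size

    cat_templates = rng.standard_normal((len(CATEGORIES), n_sensors))
    out_templates = rng.standard_normal((2, n_sensors))  # recognized, unrecognized
    ex_templates = rng.standard_normal((N_REAL_EXEMPLARS, n_sensors))
    cluster_center = rng.standard_normal(n_sensors)  # recognized-trial attractor

    noise_rng = config.rng("meg_noise")
    data = noise_rng.standard_normal((n_trials, n_sensors, n_times)) * config.noise_sd

    cat_idx = np.array([CATEGORIES.index(c) for c in behavior["category"]])
    ex_idx = np.array(
        [
            CATEGORIES.index(c) * N_EXEMPLARS_PER_CATEGORY + (e - 1)
            for c, e in zip(behavior["category"], behavior["exemplar"])
        ]
    )
    recognized = (behavior["outcome"] == "recognized").to_numpy()

    cat_mask = config.category_effect.mask(time_ms)
    ts_mask = config.two_state_offset.mask(time_ms)
    ex_mask = config.exemplar_effect.mask(time_ms)
    shrink_mask = (time_ms >= config.shrink_window_ms[0]) & (
        time_ms <= config.shrink_window_ms[1]
    )

    # category information present in recognized trials only
    add = config.category_effect.amplitude * cat_templates[cat_idx[recognized]]
    data[np.ix_(recognized, np.arange(n_sensors), np.flatnonzero(cat_mask))] += add[
        :, :, None
    ]
    # two-state offset: outcome-specific shared template, all trials
    out_idx = np.where(recognized, 0, 1)
    add = config.two_state_offset.amplitude * out_templates[out_idx]
    data[:, :, ts_mask] += add[:, :, None]
    # exemplar component; in recognized trials inside the shrink window the
    # idiosyncratic variance is multiplied by recognition_shrink while the
    # complementary energy moves into the shared cluster center
    ex_amp = config.exemplar_effect.amplitude * ex_templates[ex_idx]  # trials x sensors
    scale = np.ones((n_trials, n_times))
    scale[:, ~ex_mask] = 0.0
    shrink_cols = np.flatnonzero(ex_mask & shrink_mask)
    scale[np.ix_(recognized, shrink_cols)] = np.sqrt(config.recognition_shrink)
    data += ex_amp[:, :, None] * scale[:, None, :]
    center_gain = config.exemplar_effect.amplitude * np.sqrt(
        1.0 - config.recognition_shrink
    )
    data[np.ix_(recognized, np.arange(n_sensors), shrink_cols)] += (
        center_gain * cluster_center[None, :, None]
    )

    labels = behavior[["exemplar", "category", "outcome"]].reset_index(drop=True)
    dataset = EpochedDataset(data=data, time_ms=time_ms, labels=labels, sfreq_hz=config.sfreq_hz)
    ground_truth = pd.DataFrame(_ground_truth_rows(config))
    return dataset, ground_truth


@dataclass(frozen=True)
class RunDesign:
    """Event timing of one simulated fMRI run.

    ``condition_ids`` index the 48 exemplar x outcome regressors in the
    order produced by :func:`megfusion.fmri_glm.regressor_labels`.
    """

    onsets_s: np.ndarray
    condition_ids: np.ndarray
    question_onsets_s: np.ndarray
    tr_s: float
    n_volumes: int


def _roi_condition_patterns(
    config: SimulationConfig, roi: str, rng: np.random.Generator
) -> np.ndarray:
    """Noise-free 40 x voxels condition patterns for one ROI.

    Two-state geometry: an outcome-specific shared template.  Recognition
    geometry: recognized conditions share a cluster-center template plus a
    shrunken exemplar spread, while unrecognized conditions carry a
    full-variance exemplar spread with no shared component.
    """
    prof = config.roi_profiles[roi]
    nv = config.n_voxels_per_roi
    o_templates = rng.standard_normal((2, nv))
    cluster_center = rng.standard_normal(nv)
    spread = rng.standard_normal((N_CONDITIONS, nv))

    patterns = np.empty((N_CONDITIONS, nv))
    shared_gain = np.sqrt(1.0 - config.recognition_shrink)
    for pos, cond in enumerate(condition_index()):
        rec = cond.outcome == "recognized"
        two_state = o_templates[0 if rec else 1]
        if rec:
            recognition = (
                shared_gain * cluster_center
                + np.sqrt(config.recognition_shrink) * spread[pos]
            )
        else:
            recognition = spread[pos]
        patterns[pos] = (
            prof.two_state_weight * two_state + prof.recognition_weight * recognition
        )
    return patterns


def generate_fmri_patterns(
    config: SimulationConfig, mode: str = "betas"
) -> tuple[dict[str, object], pd.DataFrame]:
    """Simulate per-ROI fMRI data with the planted geometry mixture.

    mode="betas": returns {roi: 40 x voxels condition-pattern array}.
    mode="bold_runs": returns {roi: list of (bold, RunDesign)} where
    ``bold`` is volumes x voxels, generated by convolving the run design
    with the gamma HRF of :mod:`megfusion.fmri_glm` so GLM recovery is
    testable.  Also returns the ground-truth table.
    """
    if mode not in ("betas", "bold_runs"):
        raise ValueError(f"unknown mode {mode!r}")
    if not config.roi_profiles:
        raise ConfigError("no ROI profiles defined")
    ground_truth = pd.DataFrame(_ground_truth_rows(config))

    out: dict[str, object] = {}
    if mode == "betas":
        for roi in config.roi_profiles:
            rng = config.rng(f"fmri:{roi}")
            patterns = _roi_condition_patterns(config, roi, rng)
            patterns = patterns + config.noise_sd * rng.standard_normal(patterns.shape)
            out[roi] = patterns
        return out, ground_truth

    from . import fmri_glm  # deferred: avoid import cycle at module load

    design_rng = config.rng("fmri_designs")
    designs = []
    for _ in range(config.n_runs_fmri):
        designs.append(_simulate_run_design(config, design_rng))
    for roi in config.roi_profiles:
        rng = config.rng(f"fmri:{roi}")
        patterns40 = _roi_condition_patterns(config, roi, rng)
        # scrambled-image conditions: unstructured patterns (dropped downstream)
        betas48 = np.zeros((48, config.n_voxels_per_roi))
        real_ids = fmri_glm.real_condition_regressors()
        betas48[real_ids] = patterns40
        scram = np.setdiff1d(np.arange(48), real_ids)
        betas48[scram] = rng.standard_normal((scram.size, config.n_voxels_per_roi))
        runs = []
        for design in designs:
            X = fmri_glm.build_design_matrix(design)
            bold = X[:, :48] @ betas48 + config.noise_sd * rng.standard_normal(
                (design.n_volumes, config.n_voxels_per_roi)
            )
            runs.append((bold, design))
        out[roi] = runs
    return out, ground_truth


def _simulate_run_design(
    config: SimulationConfig, rng: np.random.Generator
) -> RunDesign:
    """One run: each of the 24 images once, in random order, with a single
    realized recognition outcome per presentation; the categorization
    question follows each stimulus after a delay."""
    n_events = 24
    iti = 12.0  # generous spacing so designs are comfortably full rank
    onsets = 6.0 + iti * np.arange(n_events)
    order = rng.permutation(n_events)
    recognized = rng.random(n_events) < config.p_recognized
    condition_ids = np.array(
        [img if rec else img + 24 for img, rec in zip(order, recognized)]
    )
    question_onsets = onsets + 5.0
    n_volumes = int(np.ceil((onsets[-1] + 30.0) / config.tr_s))
    return RunDesign(
        onsets_s=onsets,
        condition_ids=condition_ids,
        question_onsets_s=question_onsets,
        tr_s=config.tr_s,
        n_volumes=n_volumes,
    )
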