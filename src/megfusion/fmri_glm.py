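"""First-level GLM for per-ROI fMRI pattern estimation.

Each run's design matrix has 49 columns: one stick regressor per image x
recognition-outcome combination ((20 real + 4 scrambled images) x 2
outcomes = 48) plus one nuisance regressor aligned to the onsets of the
first behavioral question, every regressor convolved with a single-gamma
hemodynamic response function.  Because each image appears once per run
with a single realized outcome, only 25 columns are non-zero in any run.
Least-squares betas are estimated on the non-zero columns, averaged
across runs per condition, and the scrambled-image conditions dropped,
leaving the 40 real-image condition patterns that feed the RDMs.

HRF defaults (gamma shape 6, scale 1 s, unit peak, no undershoot) are
configuration, not empirically fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .conditions import (
    CATEGORIES,
    N_EXEMPLARS_PER_CATEGORY,
    N_REAL_EXEMPLARS,
)
from .synthgen import RunDesign

__all__ = [
    "HrfParams",
    "gamma_hrf",
    "regressor_labels",
    "real_condition_regressors",
    "build_design_matrix",
    "estimate_betas",
    "average_conditions",
]

N_IMAGES = 24  # 20 real exemplars + 4 scrambled
N_REGRESSORS = 2 * N_IMAGES + 1  # 49: 48 image x outcome + 1 nuisance
_CONV_DT = 0.1  # s, internal convolution grid (finer than any TR)


@dataclass(frozen=True)
class HrfParams:
    shape: float = 6.0
    scale_s: float = 1.0
    duration_s: float = 32.0


def gamma_hrf(params: HrfParams = HrfParams(), dt: float = _CONV_DT) -> np.ndarray:
    """Single-gamma HRF sampled at ``dt``, normalized to unit peak."""
    t = np.arange(0.0, params.duration_s, dt)
    h = sps.gamma.pdf(t, a=params.shape, scale=params.scale_s)
    return h / h.max()


def regressor_labels() -> list[str]:
    """Column labels of the 49-regressor design, in fixed order.

    Recognized block first: 20 real exemplars (categories in canonical
    order, exemplars 1-5) then 4 scrambled images; the unrecognized block
    repeats the same image order; the nuisance regressor is last.
    """
    labels = []
    for outcome in ("recognized", "unrecognized"):
        for cat in CATEGORIES:
            for ex in range(1, N_EXEMPLARS_PER_CATEGORY + 1):
                labels.append(f"{outcome}/{cat}{ex}")
        for s in range(1, 5):
            labels.append(f"{outcome}/scrambled{s}")
    labels.append("nuisance/question")
    return labels


def real_condition_regressors() -> np.ndarray:
    """Regressor columns of the 40 real-image conditions, in the canonical
    RDM order (recognized block then unrecognized block)."""
    real = np.arange(N_REAL_EXEMPLARS)
    return np.concatenate([real, real + N_IMAGES])


def build_design_matrix(
    run: RunDesign, hrf_params: HrfParams = HrfParams()
) -> np.ndarray:
    """n_volumes x 49 design matrix for one run.

    Stick functions on a 0.1 s grid are convolved with the gamma HRF and
    sampled at the TR.  Columns of image x outcome combinations that never
    occur in the run stay all-zero.
    """
    run_len_s = run.n_volumes * run.tr_s
    if np.any(run.onsets_s < 0) or np.any(run.onsets_s >= run_len_s):
        raise ValueError("event onset outside the run")
    if np.any(run.question_onsets_s >= run_len_s):
        raise ValueError("nuisance onset outside the run")
    if np.any((run.condition_ids < 0) | (run.condition_ids >= 2 * N_IMAGES)):
        raise ValueError("condition id outside 0..47")

    hrf = gamma_hrf(hrf_params)
    n_fine = int(np.ceil(run_len_s / _CONV_DT))
    X = np.zeros((run.n_volumes, N_REGRESSORS))
    vol_idx = np.rint(np.arange(run.n_volumes) * run.tr_s / _CONV_DT).astype(int)

    def column(onsets: np.ndarray) -> np.ndarray:
        sticks = np.zeros(n_fine)
        sticks[np.rint(np.asarray(onsets) / _CONV_DT).astype(int)] = 1.0
        return np.convolve(sticks, hrf)[:n_fine][vol_idx]

    for onset, cond in zip(run.onsets_s, run.condition_ids):
        X[:, cond] += column([onset])
    X[:, -1] = column(run.question_onsets_s)
    return X


def estimate_betas(bold: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares betas per voxel; all-zero columns return NaN rows.

    ``bold`` is n_volumes x voxels.  Raises if the non-zero columns are
    rank deficient (the least-squares solution would not be unique).
    """
    bold = np.asarray(bold, dtype=float)
    design = np.asarray(design, dtype=float)
    if bold.shape[0] != design.shape[0]:
        raise ValueError("bold and design have different numbers of volumes")
    active = np.flatnonzero(np.any(design != 0.0, axis=0))
    Xa = design[:, active]
    if np.linalg.matrix_rank(Xa) < active.size:
        raise ValueError("design matrix is rank deficient on its non-zero columns")
    coef, *_ = np.linalg.lstsq(Xa, bold, rcond=None)
    betas = np.full((design.shape[1], bold.shape[1]), np.nan)
    betas[active] = coef
    return betas


def average_conditions(run_betas: list[np.ndarray]) -> np.ndarray:
    """Run-averaged patterns for the 40 real-image conditions.

    Each element of ``run_betas`` is a 49 x voxels array from one run
    (NaN rows mark conditions not observed in that run).  The mean is
    taken over runs where the condition was observed; scrambled-image
    conditions and the nuisance regressor are dropped.  A condition never
    observed in any run stays NaN.
    """
    stacked = np.stack(run_betas)  # runs x 49 x voxels
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
    return mean[real_condition_regressors()]
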