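"""RSA-based MEG-fMRI fusion and model-driven commonality analysis.

Fusion correlates the time-resolved MEG RDMs with a spatially localized
fMRI RDM: at each MEG time point the squared Spearman rank correlation
between the two lower-triangle dissimilarity vectors gives the variance
shared by the two modalities (R2_fusion).  Commonality analysis then asks
how much of that shared variance a hypothesis (model) RDM accounts for:

    C = R2(MEG, fMRI) + R2(MEG, model) - R2(MEG, {fMRI, model})

where the joint term is the squared multiple correlation of the
rank-transformed MEG vector regressed on the fMRI and model rank vectors
together.  All three vectors are rank-transformed once (average ranks for
ties) before any correlation is computed.  C can be negative (suppression)
and never exceeds min(R2_MEG.fMRI, R2_MEG.model) beyond numerical noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "FusionTimecourse",
    "CommonalityTimecourse",
    "rdm_to_vector",
    "vector_to_rdm",
    "fuse",
    "commonality",
    "commonality_timecourse",
]

COLLINEAR_TOL = 1e-10


@dataclass
class FusionTimecourse:
    time_ms: np.ndarray
    r2_fusion: np.ndarray  # squared Spearman rho per time point


@dataclass
class CommonalityTimecourse:
    time_ms: np.ndarray
    c: dict[str, np.ndarray]  # model name -> C per time point
    r2_fusion: np.ndarray
    roi: str | None = field(default=None)


def rdm_to_vector(rdm: np.ndarray) -> np.ndarray:
    """Strictly-lower-triangle entries in row-major order.

    Length n(n-1)/2 (780 for 40 conditions).  The diagonal is excluded;
    asymmetric input (off-diagonal, NaN-diagonal ignored) is an error.
    """
    rdm = np.asarray(rdm, dtype=float)
    if rdm.ndim != 2 or rdm.shape[0] != rdm.shape[1]:
        raise ValueError("RDM must be square")
    off = ~np.eye(rdm.shape[0], dtype=bool)
    if not np.allclose(rdm[off], rdm.T[off], equal_nan=True):
        raise ValueError("RDM is not symmetric")
    i, j = np.tril_indices(rdm.shape[0], -1)
    return rdm[i, j]


def vector_to_rdm(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rdm_to_vector` (diagonal restored as NaN)."""
    vec = np.asarray(vec, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * vec.size)) / 2))
    if n * (n - 1) // 2 != vec.size:
        raise ValueError(f"vector length {vec.size} is not triangular")
    rdm = np.full((n, n), np.nan)
    i, j = np.tril_indices(n, -1)
    rdm[i, j] = vec
    rdm[j, i] = vec
    return rdm


def _center_norm(v: np.ndarray) -> np.ndarray:
    v = v - v.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return v / norm


def _prepare_rank_vectors(
    meg_rdms: np.ndarray, fmri_rdm: np.ndarray, model_rdm: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rank-transform (average ranks) and center/normalize all vectors.

    Returns (meg_ranks [T x P], fmri_ranks [P], model_ranks [P],
    pair_index [P x 2]).  Centered, unit-norm rank vectors turn every
    correlation downstream into a dot product; a permutation of the pair
    entries preserves centering and norm, which the label-permutation test
    exploits.
    """
    fmri_rdm = getattr(fmri_rdm, "values", fmri_rdm)
    model_rdm = getattr(model_rdm, "values", model_rdm)
    meg_rdms = np.asarray(meg_rdms, dtype=float)
    if meg_rdms.ndim == 2:
        meg_rdms = meg_rdms[None]
    n = meg_rdms.shape[1]
    pair_index = np.column_stack(np.tril_indices(n, -1))
    meg_vecs = np.stack([rdm_to_vector(r) for r in meg_rdms])
    f_vec = rdm_to_vector(np.asarray(fmri_rdm, dtype=float))
    m_vec = rdm_to_vector(np.asarray(model_rdm, dtype=float))
    if not (meg_vecs.shape[1] == f_vec.size == m_vec.size):
        raise ValueError("RDM sizes do not match")
    meg_ranks = _center_norm(np.apply_along_axis(sps.rankdata, 1, meg_vecs))
    f_ranks = _center_norm(sps.rankdata(f_vec))
    m_ranks = _center_norm(sps.rankdata(m_vec))
    return meg_ranks, f_ranks, m_ranks, pair_index


def _commonality_from_ranks(
    meg_ranks: np.ndarray, f_ranks: np.ndarray, m_ranks: np.ndarray
) -> np.ndarray:
    """C per MEG row from centered, unit-norm rank vectors.

    The two-predictor multiple R2 has the closed form
    (r1^2 + r2^2 - 2 r1 r2 r12) / (1 - r12^2), identical to OLS of the
    MEG ranks on the fMRI and model ranks jointly.  When the two
    predictors' ranks coincide exactly (|r12| = 1) the joint regression
    degenerates to a single predictor and C reduces to R2(MEG, fMRI) — the
    formula identity C = R2 + R2 - R2; near-collinearity short of identity
    is an error (the joint R2 is numerically ill-defined).
    """
    r12 = float(f_ranks @ m_ranks)
    r1 = meg_ranks @ f_ranks
    r2 = meg_ranks @ m_ranks
    if 1.0 - r12**2 < COLLINEAR_TOL:
        if np.allclose(np.abs(r1), np.abs(r2), atol=1e-9):
            return r1**2
        raise ValueError(
            "fMRI and model rank vectors are collinear; joint R2 undefined"
        )
    r2_joint = (r1**2 + r2**2 - 2.0 * r1 * r2 * r12) / (1.0 - r12**2)
    return r1**2 + r2**2 - r2_joint


def fuse(
    meg_rdms: np.ndarray,
    fmri_rdm: np.ndarray,
    time_ms: np.ndarray | None = None,
) -> FusionTimecourse:
    """Squared Spearman correlation between MEG and fMRI RDMs per time point.

    Group-average RDMs are the intended inputs (the best estimate of the
    true RDM when the two modalities come from different participants).
    A constant dissimilarity vector yields NaN with a warning.
    """
    meg_rdms = np.asarray(meg_rdms, dtype=float)
    if meg_rdms.ndim == 2:
        meg_rdms = meg_rdms[None]
    if time_ms is None:
        time_ms = np.arange(meg_rdms.shape[0], dtype=float)
    meg_vecs = np.stack([rdm_to_vector(r) for r in meg_rdms])
    f_vec = rdm_to_vector(np.asarray(fmri_rdm, dtype=float))
    meg_ranks = _center_norm(np.apply_along_axis(sps.rankdata, 1, meg_vecs))
    f_ranks = _center_norm(sps.rankdata(f_vec))
    if np.any(~np.isfinite(f_ranks)):
        warnings.warn("constant fMRI dissimilarity vector; fusion undefined")
        return FusionTimecourse(np.asarray(time_ms), np.full(meg_rdms.shape[0], np.nan))
    bad = ~np.isfinite(meg_ranks).all(axis=1)
    if bad.any():
        warnings.warn(f"{bad.sum()} constant MEG dissimilarity vectors; set to NaN")
    rho = meg_ranks @ f_ranks
    r2 = rho**2
    r2[bad] = np.nan
    return FusionTimecourse(np.asarray(time_ms), r2)


def commonality(
    meg_rdm: np.ndarray, fmri_rdm: np.ndarray, model_rdm: np.ndarray
) -> float:
    """Commonality coefficient C for a single MEG time point."""
    meg_ranks, f_ranks, m_ranks, _ = _prepare_rank_vectors(
        np.asarray(meg_rdm)[None] if np.asarray(meg_rdm).ndim == 2 else meg_rdm,
        fmri_rdm,
        model_rdm,
    )
    return float(_commonality_from_ranks(meg_ranks, f_ranks, m_ranks)[0])


def commonality_timecourse(
    meg_rdms: np.ndarray,
    fmri_rdm: np.ndarray,
    model_rdms: dict[str, np.ndarray],
    time_ms: np.ndarray | None = None,
    roi: str | None = None,
) -> CommonalityTimecourse:
    """C(t) for each model RDM, plus the companion fusion R2 timecourse."""
    meg_rdms = np.asarray(meg_rdms, dtype=float)
    if meg_rdms.ndim == 2:
        meg_rdms = meg_rdms[None]
    if time_ms is None:
        time_ms = np.arange(meg_rdms.shape[0], dtype=float)
    c: dict[str, np.ndarray] = {}
    for name, model in model_rdms.items():
        meg_ranks, f_ranks, m_ranks, _ = _prepare_rank_vectors(
            meg_rdms, fmri_rdm, model
        )
        c[name] = _commonality_from_ranks(meg_ranks, f_ranks, m_ranks)
    r2 = fuse(meg_rdms, fmri_rdm, time_ms).r2_fusion
    return CommonalityTimecourse(
        time_ms=np.asarray(time_ms), c=c, r2_fusion=r2, roi=roi
    )
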