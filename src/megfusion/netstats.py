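"""Explanatory-power decomposition by model, time window, and network.

A model RDM's explanatory power at a time point is its commonality
coefficient divided by the total MEG-fMRI shared variance (clipped at
zero when the coefficient is negative, capped at 100%).  Timecourses are
split into an early (0-1000 ms) and a late (1000-2000 ms) post-stimulus
window (or sliding windows), averaged across the ROIs of each functional
network, and compared with a 2 x 2 mixed-design ANOVA: model
(recognition vs two-state) as the repeated-measures factor and window
(early vs late) as the between-group factor, time points serving as the
observational units.  Effect sizes are generalized eta squared.

Treating time points as independent observations replicates the stated
group-level design despite their autocorrelation; see the methods note.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bonferroni, mann_whitney, wilcoxon_signed_rank

__all__ = [
    "NetworkAssignment",
    "AnovaResult",
    "NETWORK_COLUMNS",
    "load_network_voxel_table",
    "assign_networks",
    "explained_fraction",
    "split_windows",
    "window_summary",
    "network_average",
    "dominant_model",
    "mixed_anova_2x2",
    "block_bootstrap_model_effect",
]

NETWORK_COLUMNS = ("Visual", "Somato", "SAL", "DAN", "Limbic", "FPCN", "DMN")
EXCLUDED_NETWORK = "Somato"  # somatosensory/motor: not part of the analysis


@dataclass
class NetworkAssignment:
    network: dict[str, str]  # retained ROI -> network label
    excluded: dict[str, str]  # ROI -> reason


@dataclass
class AnovaResult:
    table: pd.DataFrame  # effect, F, df1, df2, p, eta2_g
    posthoc: pd.DataFrame


def load_network_voxel_table() -> pd.DataFrame:
    """Packaged ROI x network voxel-percentage table (study-layout TSV)."""
    ref = importlib.resources.files("megfusion") / "data" / "network_voxel_table.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="roi")


def assign_networks(voxel_table: pd.DataFrame) -> NetworkAssignment:
    """Assign each ROI to the network holding its highest voxel share.

    ROIs whose winning network is the somatosensory/motor network are
    excluded.  A tie at the argmax is an error demanding manual
    resolution.  Percentages outside [0, 100] are rejected; row sums may
    fall short of 100 (voxels outside the listed networks).
    """
    cols = [c for c in NETWORK_COLUMNS if c in voxel_table.columns]
    if not cols:
        raise ValueError("voxel table has no recognized network columns")
    vals = voxel_table[cols].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("voxel percentages must lie in [0, 100]")
    network: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for roi, row in zip(voxel_table.index, vals):
        top = row.max()
        winners = [c for c, v in zip(cols, row) if v == top]
        if len(winners) > 1:
            raise ValueError(
                f"ROI {roi!r}: tie between networks {winners}; resolve manually"
            )
        if winners[0] == EXCLUDED_NETWORK:
            excluded[roi] = f"highest voxel count in {EXCLUDED_NETWORK} ({top:.2f}%)"
        else:
            network[roi] = winners[0]
    return NetworkAssignment(network=network, excluded=excluded)


def explained_fraction(c, r2_fusion):
    """Percentage of MEG-fMRI shared variance a model accounts for.

    max(C, 0) / R2_fusion * 100, capped at 100; undefined (NaN) where
    R2_fusion <= 0.  Vectorized over time points.
    """
    c = np.asarray(c, dtype=float)
    r2 = np.asarray(r2_fusion, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.clip(np.maximum(c, 0.0) / r2, 0.0, 1.0) * 100.0
    frac = np.where(r2 > 0, frac, np.nan)
    if frac.ndim == 0:
        return float(frac)
    return frac


def split_windows(time_ms: np.ndarray, scheme: str = "early_late") -> dict[str, np.ndarray]:
    """Window name -> time-point index array.

    "early_late": early = [0, 1000] ms, late = (1000, 2000] ms.
    "sliding100" / "sliding200": non-overlapping windows of that width
    covering 0-2000 ms (robustness variants).
    """
    time_ms = np.asarray(time_ms, dtype=float)
    if scheme == "early_late":
        windows = {
            "early": np.flatnonzero((time_ms >= 0) & (time_ms <= 1000)),
            "late": np.flatnonzero((time_ms > 1000) & (time_ms <= 2000)),
        }
    elif scheme in ("sliding100", "sliding200"):
        width = 100.0 if scheme == "sliding100" else 200.0
        windows = {}
        start = 0.0
        while start < 2000.0:
            end = start + width
            idx = np.flatnonzero((time_ms >= start) & (time_ms < end))
            if idx.size:
                windows[f"{start:.0f}-{end:.0f}ms"] = idx
            start = end
    else:
        raise ValueError(f"unknown window scheme {scheme!r}")
    for name, idx in windows.items():
        if idx.size == 0:
            raise ValueError(f"window {name!r} contains no time points")
    return windows


def window_summary(
    series: np.ndarray, time_ms: np.ndarray, scheme: str = "early_late"
) -> pd.DataFrame:
    """Median explained percentage per window for one timecourse."""
    series = np.asarray(series, dtype=float)
    windows = split_windows(time_ms, scheme)
    rows = []
    for name, idx in windows.items():
        rows.append(
            {
                "window": name,
                "start_ms": float(time_ms[idx[0]]),
                "end_ms": float(time_ms[idx[-1]]),
                "n_points": int(idx.size),
                "median": float(np.nanmedian(series[idx])),
            }
        )
    return pd.DataFrame(rows)


def network_average(
    roi_series: dict[str, np.ndarray], assignment: NetworkAssignment
) -> dict[str, np.ndarray]:
    """Average timecourses across the member ROIs of each network."""
    out: dict[str, list[np.ndarray]] = {}
    for roi, series in roi_series.items():
        net = assignment.network.get(roi)
        if net is None:
            continue
        out.setdefault(net, []).append(np.asarray(series, dtype=float))
    return {net: np.nanmean(np.stack(v), axis=0) for net, v in sorted(out.items())}


def dominant_model(explained: dict[str, np.ndarray]) -> str:
    """Model with the larger median explained variance over the series."""
    medians = {name: float(np.nanmedian(s)) for name, s in explained.items()}
    return max(medians, key=medians.get)


def _anova_cells(early: np.ndarray, late: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    early = np.asarray(early, dtype=float)
    late = np.asarray(late, dtype=float)
    for name, arr in (("early", early), ("late", late)):
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"{name} data must be observations x 2 models")
        if arr.shape[0] < 2:
            raise ValueError(f"fewer than 2 observations in the {name} window")
        if np.isnan(arr).any():
            raise ValueError(f"NaN values in the {name} window")
    return early, late


def mixed_anova_2x2(
    early: np.ndarray,
    late: np.ndarray,
    model_names: tuple[str, str] = ("recognition", "two_state"),
) -> AnovaResult:
    """2 x 2 mixed-design ANOVA with generalized eta squared.

    ``early`` and ``late`` are observations x 2 arrays (columns = the two
    models, rows = time points of that window).  Model is the
    repeated-measures factor, window the between-group factor.  Post hoc:
    paired two-sided Wilcoxon between models within each window,
    two-sided Mann-Whitney between windows within each model, Bonferroni
    over the four tests.
    """
    early, late = _anova_cells(early, late)
    groups = [early, late]
    n = [g.shape[0] for g in groups]
    N = sum(n)
    q = 2  # repeated levels
    gm = np.concatenate([g.ravel() for g in groups]).mean()

    group_means = [g.mean() for g in groups]
    subj_means = [g.mean(axis=1) for g in groups]
    model_means = np.concatenate(groups).mean(axis=0)
    cell_means = [g.mean(axis=0) for g in groups]

    ss_window = q * sum(ni * (gmean - gm) ** 2 for ni, gmean in zip(n, group_means))
    ss_subj = q * sum(((sm - gmean) ** 2).sum() for sm, gmean in zip(subj_means, group_means))
    ss_model = N * ((model_means - gm) ** 2).sum()
    ss_inter = sum(
        ni * ((cm - gmean - model_means + gm) ** 2).sum()
        for ni, gmean, cm in zip(n, group_means, cell_means)
    )
    ss_resid = sum(
        ((g - sm[:, None] - cm[None, :] + gmean) ** 2).sum()
        for g, sm, cm, gmean in zip(groups, subj_means, cell_means, group_means)
    )

    df_window, df_subj = 1, N - 2
    df_model, df_inter, df_resid = 1, 1, N - 2

    def effect_row(name, ss, df, ss_err, df_err):
        ms, ms_err = ss / df, ss_err / df_err
        f = ms / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(f, df, df_err)) if ms_err > 0 else 1.0
        eta2_g = ss / (ss + ss_subj + ss_resid) if (ss + ss_subj + ss_resid) > 0 else 0.0
        return {
            "effect": name,
            "F": float(f),
            "df1": df,
            "df2": df_err,
            "p": p,
            "eta2_g": float(eta2_g),
        }

    table = pd.DataFrame(
        [
            effect_row("window", ss_window, df_window, ss_subj, df_subj),
            effect_row("model", ss_model, df_model, ss_resid, df_resid),
            effect_row("model x window", ss_inter, df_inter, ss_resid, df_resid),
        ]
    )

    rows = []
    for win, g in zip(("early", "late"), groups):
        diffs = g[:, 0] - g[:, 1]
        if np.all(diffs == 0.0):
            w, p = np.nan, 1.0  # identical model timecourses: no evidence
        else:
            w, p = wilcoxon_signed_rank(diffs, 0.0, alternative="two-sided")
        rows.append(
            {
                "test": f"{model_names[0]} vs {model_names[1]} ({win})",
                "kind": "wilcoxon",
                "statistic": w,
                "p": p,
            }
        )
    for m, name in enumerate(model_names):
        u, p = mann_whitney(early[:, m], late[:, m], alternative="two-sided")
        rows.append(
            {
                "test": f"early vs late ({name})",
                "kind": "mann_whitney",
                "statistic": u,
                "p": p,
            }
        )
    posthoc = pd.DataFrame(rows)
    posthoc["p_bonferroni"] = bonferroni(posthoc["p"].to_numpy())
    return AnovaResult(table=table, posthoc=posthoc)


def block_bootstrap_model_effect(
    early: np.ndarray,
    late: np.ndarray,
    block_len: int = 40,
    n_boot: int = 2000,
    seed: int | None = None,
) -> dict[str, float]:
    """Autocorrelation-robust alternative to the mixed ANOVA's model effect.

    The ANOVA treats time points as independent units, which explained-
    variance timecourses are not.  This circular-block bootstrap resamples
    contiguous blocks of time points (within each window) of the paired
    model difference and reports a two-sided p for the mean difference
    being zero, plus a bootstrap SE.  Non-default; the ANOVA remains the
    primary report.
    """
    early, late = _anova_cells(early, late)
    diff = np.concatenate([early[:, 0] - early[:, 1], late[:, 0] - late[:, 1]])
    n = diff.size
    block_len = max(1, min(block_len, n))
    n_blocks = int(np.ceil(n / block_len))
    rng = np.random.default_rng(seed)
    obs = diff.mean()
    boots = np.empty(n_boot)
    for b in range(n_boot):
        starts = rng.integers(0, n, n_blocks)
        idx = (starts[:, None] + np.arange(block_len)[None, :]).ravel() % n
        boots[b] = diff[idx[:n]].mean()
    se = boots.std(ddof=1)
    centered = boots - boots.mean()
    p = (1.0 + np.sum(np.abs(centered) >= abs(obs))) / (1.0 + n_boot)
    return {"mean_diff": float(obs), "se": float(se), "p": float(p)}
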