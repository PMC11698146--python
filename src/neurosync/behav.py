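"""Associations between neural measures (per-ROI ISC, per-epoch NCI) and
behavioral scales, with phase-shuffled nulls and dependent-tests FDR.

Correlations are Spearman by default (rank-based, as appropriate for
ordinal questionnaire scores); Pearson is available where noted. Families
of dependent tests are corrected with Benjamini–Yekutieli FDR. Null-based
p-values use the add-one permutation estimator and so are never exactly 0.
"""

from __future__ import annotations

import logging
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import BehavioralTable, SubjectTimeSeries
from .isc import ISCResult, _group_stack, _loo_corr_matrix, phase_randomize_many
from .nci import NCISeries, Epoch, fdr_by

logger = logging.getLogger(__name__)

__all__ = [
    "spearman",
    "isc_behavior_assoc",
    "symptom_isc_assoc",
    "nci_behavior_assoc",
    "epoch_mean_nci",
    "compare_scales",
]


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-tailed p.

    Midrank-based rho; p from the t approximation, or by exact permutation
    enumeration for n <= 8. Constant input yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 4:
        raise ValueError(f"need n >= 4, got n = {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("spearman: constant input, correlation undefined")
        return np.nan, np.nan
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 8:
        # exact two-sided permutation p over all n! orderings of y
        ryc = ry - ry.mean()
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        perms = np.array(list(permutations(range(n))))
        rho_all = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, min(p, 1.0)


def _assoc_rho(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    """Correlation coefficient only (no p) — used inside null loops."""
    if kind == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _assoc(x: np.ndarray, y: np.ndarray, kind: str) -> tuple[float, float]:
    if kind == "spearman":
        return spearman(x, y)
    if kind == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    raise ValueError("assoc must be 'spearman' or 'pearson'")


def _roi_means(result: ISCResult, roi_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean ISC over each ROI's member units."""
    cols = {"subject_id": result.subject_ids}
    for _, roi in roi_table.iterrows():
        units = np.asarray(roi["units"], dtype=int)
        with np.errstate(invalid="ignore"):
            cols[roi["label"]] = np.nanmean(result.r[:, units], axis=1)
    return pd.DataFrame(cols)


def _check_ids(neural_ids: Sequence[str], behavior: BehavioralTable) -> None:
    missing = sorted(set(neural_ids) - set(behavior.subject_ids))
    if missing:
        raise ValueError(
            f"behavioral table is missing subject ids: {', '.join(missing)}"
        )


def isc_behavior_assoc(
    isc_result: ISCResult,
    roi_table: pd.DataFrame,
    behavior: BehavioralTable,
    measures: Sequence[str],
    assoc: str = "spearman",
) -> pd.DataFrame:
    """Correlate per-subject ROI ISC with behavioral measures.

    For every ROI x measure pair, the Spearman correlation between the
    subjects' mean ISC over the ROI's units and the measure; q is BY-FDR
    over the whole ROI x measure family.

    Returns a DataFrame (measure, region, rho, p, q, n).
    """
    _check_ids(isc_result.subject_ids, behavior)
    roi_means = _roi_means(isc_result, roi_table)
    merged = roi_means.merge(behavior.table, on="subject_id", how="left")
    rows = []
    for _, roi in roi_table.iterrows():
        for m in measures:
            if m not in merged.columns:
                raise KeyError(f"measure {m!r} not in behavioral table")
            x = merged[roi["label"]].to_numpy(float)
            y = merged[m].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            rho, p = _assoc(x[ok], y[ok], assoc)
            rows.append((m, roi["label"], rho, p, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["measure", "region", "rho", "p", "n"])
    out["q"] = _by_with_nan(out["p"].to_numpy())
    return out[["measure", "region", "rho", "p", "q", "n"]]


def _by_with_nan(p: np.ndarray) -> np.ndarray:
    q = np.full(p.size, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = fdr_by(p[ok])
    return q


def symptom_isc_assoc(
    subjects: Sequence[SubjectTimeSeries],
    roi_units: Sequence[int],
    behavior: BehavioralTable,
    symptoms: Sequence[str],
    group: str = "pmdd",
    n_iter: int = 1000,
    seed=None,
    assoc: str = "spearman",
) -> pd.DataFrame:
    """Symptom–synchrony association with a phase-shuffled null.

    The synchrony measure per subject is the mean leave-one-out ISC over the
    ROI's units within ``group``. The observed correlation of that measure
    with each symptom is referred to a null built by phase-randomizing every
    subject x unit series and recomputing the whole procedure per iteration;
    p = (1 + #{|null| >= |observed|}) / (1 + n_iter), never exactly 0.

    Returns a DataFrame (measure, region, rho, p, q, n).
    """
    if n_iter < 100:
        raise ValueError(f"n_iter must be >= 100, got {n_iter}")
    members, X = _group_stack(subjects, group)
    ids = [s.subject_id for s in members]
    _check_ids(ids, behavior)
    units = np.asarray(roi_units, dtype=int)
    Xroi = X[:, units, :]  # (S, n_roi, T)
    behav = behavior.table.set_index("subject_id").loc[ids]
    y = {m: behav[m].to_numpy(float) for m in symptoms}

    def synchrony(stack: np.ndarray) -> np.ndarray:
        r = _loo_corr_matrix(stack)
        with np.errstate(invalid="ignore"):
            return np.nanmean(r, axis=-1)  # (..., S)

    obs = synchrony(Xroi)
    rho_obs = {m: _assoc_rho(obs, y[m], assoc) for m in symptoms}

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S, nroi, T = Xroi.shape
    batch = max(1, int(2e6 // (S * nroi * T)) or 1)
    null = {m: np.empty(n_iter) for m in symptoms}
    done = 0
    while done < n_iter:
        b = min(batch, n_iter - done)
        surr = phase_randomize_many(
            np.broadcast_to(Xroi, (b, S, nroi, T)).copy(), rng
        )
        sync_null = synchrony(surr)  # (b, S)
        for m in symptoms:
            for i in range(b):
                null[m][done + i] = _assoc_rho(sync_null[i], y[m], assoc)
        done += b

    rows = []
    for m in symptoms:
        p = (1 + np.sum(np.abs(null[m]) >= abs(rho_obs[m]) - 1e-12)) / (1 + n_iter)
        rows.append((m, "roi", rho_obs[m], float(p), len(ids)))
    out = pd.DataFrame(rows, columns=["measure", "region", "rho", "p", "n"])
    out["q"] = _by_with_nan(out["p"].to_numpy())
    return out[["measure", "region", "rho", "p", "q", "n"]]


def epoch_mean_nci(
    series: Sequence[NCISeries], epochs: Sequence[Epoch]
) -> pd.DataFrame:
    """Per-subject mean NCI over each epoch's windows (tidy table).

    Raises if any epoch contains no analysis windows.
    """
    for k, ep in enumerate(epochs):
        if len(ep.windows) == 0:
            raise ValueError(
                f"epoch {k} (TRs [{ep.tr_start}, {ep.tr_stop})) contains no "
                "analysis windows"
            )
    rows = []
    for s in series:
        curve = s.networks if isinstance(s.networks, str) else "-".join(s.networks)
        for k, ep in enumerate(epochs):
            vals = s.values[ep.windows]
            with np.errstate(invalid="ignore"):
                rows.append((s.subject_id, curve, k, float(np.nanmean(vals))))
    return pd.DataFrame(rows, columns=["subject_id", "curve", "epoch", "value"])


def nci_behavior_assoc(
    epoch_nci: pd.DataFrame,
    behavior: BehavioralTable,
    measures: Sequence[str],
    assoc: str = "spearman",
) -> pd.DataFrame:
    """Correlate per-subject epoch-mean NCI with behavioral measures.

    ``epoch_nci`` is the tidy table from :func:`epoch_mean_nci` (possibly
    concatenated over curves: intra-NCI of each network and the
    inter-NCI). One Spearman test per (curve, epoch) x measure; q is BY-FDR
    across the whole family.
    """
    _check_ids(epoch_nci["subject_id"].unique().tolist(), behavior)
    merged = epoch_nci.merge(behavior.table, on="subject_id", how="left")
    rows = []
    for (curve, epoch), sub in merged.groupby(["curve", "epoch"], sort=True):
        for m in measures:
            x = sub["value"].to_numpy(float)
            y = sub[m].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            rho, p = _assoc(x[ok], y[ok], assoc)
            rows.append((m, f"{curve}:epoch{epoch}", rho, p, int(ok.sum())))
    out = pd.DataFrame(rows, columns=["measure", "region", "rho", "p", "n"])
    out["q"] = _by_with_nan(out["p"].to_numpy())
    return out[["measure", "region", "rho", "p", "q", "n"]]


def compare_scales(
    behavior: BehavioralTable,
    measures: Sequence[str],
    group_a: str = "pmdd",
    group_b: str = "control",
) -> pd.DataFrame:
    """Plain two-sample comparison of behavioral scales between groups.

    Mann-Whitney U (two-tailed) per measure — a simple helper for group
    descriptions, not a substitute for multivariate modeling.
    """
    t = behavior.table
    rows = []
    for m in measures:
        a = t.loc[t["group"] == group_a, m].to_numpy(float)
        b = t.loc[t["group"] == group_b, m].to_numpy(float)
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((m, float(np.median(a)), float(np.median(b)), float(u), float(p)))
    return pd.DataFrame(
        rows, columns=["measure", "median_a", "median_b", "u", "p"]
    )
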