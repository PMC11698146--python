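"""Network Cohesion Index (NCI) in sliding windows, with group tests,
dependent-tests FDR and spatial-specificity nulls.

The NCI of a node set in a time window is a one-sample t-statistic over the
Fisher-Z-transformed Pearson correlations of its edges: all node pairs
within one network (intra-NCI) or all pairs connecting two disjoint
networks (inter-NCI). Computed in sliding windows (10 TRs by default — 30 s
at TR = 3 s), it tracks the moment-to-moment functional cohesion of a
network in each subject. Groups are compared per window with a rank-sum Z;
the window family is corrected with Benjamini–Yekutieli FDR (windows
overlap, hence dependent tests); and network effects are benchmarked for
spatial specificity against random equally-sized node sets drawn from the
whole-brain pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import NetworkDefinition, RatingCurve, SubjectTimeSeries
from .isc import fisher_z

logger = logging.getLogger(__name__)

__all__ = [
    "NCISeries",
    "Epoch",
    "intra_nci",
    "inter_nci",
    "sliding_nci",
    "window_group_test",
    "fdr_by",
    "spatial_specificity",
    "rating_epochs",
    "n_windows",
    "significant_runs",
]


def n_windows(n_tr: int, window_length: int, step: int = 1) -> int:
    """Number of sliding windows: floor((n_tr - w) / step) + 1."""
    if window_length > n_tr:
        raise ValueError(
            f"window_length {window_length} exceeds series length {n_tr}"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    return (n_tr - window_length) // step + 1


@dataclass
class NCISeries:
    """Per-window NCI values for one subject and one network (or pair).

    ``networks`` is one name for intra-NCI or an ordered pair for
    inter-NCI. Windows are half-open ``[s, s + window_length)``, 0-based.
    NaN values mark degenerate windows (constant node series or zero edge
    variance), never silently large numbers.
    """

    subject_id: str
    networks: str | tuple[str, str]
    window_length: int
    step: int
    values: np.ndarray
    window_starts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        if self.values.shape != self.window_starts.shape:
            raise ValueError("values and window_starts must align")


def _edge_t(z: np.ndarray) -> float:
    """One-sample t over edge Fisher-Z values: mean / (sd / sqrt(E))."""
    if np.isnan(z).any():
        return np.nan
    e = z.size
    sd = z.std(ddof=1)
    if sd == 0:
        return np.nan  # zero edge variance: degenerate, flagged not inflated
    return float(z.mean() / (sd / np.sqrt(e)))


def _corr_all(window: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of node rows; NaN rows for constant nodes."""
    w = np.asarray(window, dtype=float)
    wc = w - w.mean(axis=1, keepdims=True)
    sd = np.sqrt((wc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (wc @ wc.T) / np.outer(sd, sd)
    # exact-range test: centring a constant row leaves float residue
    bad = (sd == 0) | (np.ptp(w, axis=1) == 0)
    c[bad, :] = np.nan
    c[:, bad] = np.nan
    return np.clip(c, -1.0, 1.0)


def intra_nci(window: np.ndarray, network: NetworkDefinition | None = None) -> float:
    """Intra-network cohesion of one window.

    Pearson r for all n(n-1)/2 node pairs, Fisher-Z each (r clipped to
    +/-(1 - 1e-7) before atanh), then the one-sample t-statistic
    ``mean(z) / (sd(z) / sqrt(E))`` over the E edge values.

    ``window`` is a nodes x w matrix; with a ``network`` given, its member
    rows are selected first.
    """
    w = np.asarray(window, dtype=float)
    if network is not None:
        w = w[network.indices]
    n = w.shape[0]
    if n < 3:
        raise ValueError(
            f"insufficient edges: intra-NCI needs >= 3 nodes, got {n}"
        )
    if w.shape[1] < 3:
        raise ValueError("window must span at least 3 TRs")
    c = _corr_all(w)
    iu, ju = np.triu_indices(n, k=1)
    return _edge_t(fisher_z(c[iu, ju]))


def inter_nci(
    window: np.ndarray,
    net_a: NetworkDefinition | Sequence[int],
    net_b: NetworkDefinition | Sequence[int],
) -> float:
    """Inter-network cohesion: t over Fisher-Z values of all cross edges.

    Symmetric in its two (disjoint) node sets; needs at least 2 cross edges.
    """
    ia = net_a.indices if isinstance(net_a, NetworkDefinition) else np.asarray(net_a, int)
    ib = net_b.indices if isinstance(net_b, NetworkDefinition) else np.asarray(net_b, int)
    if np.intersect1d(ia, ib).size:
        raise ValueError("inter-NCI requires disjoint networks")
    if ia.size * ib.size < 2:
        raise ValueError("need at least 2 cross-network edges")
    if ia.min() > ib.min():  # canonical order: inter(A,B) == inter(B,A) exactly
        ia, ib = ib, ia
    w = np.asarray(window, dtype=float)
    if w.shape[1] < 3:
        raise ValueError("window must span at least 3 TRs")
    c = _corr_all(w)
    return _edge_t(fisher_z(c[np.ix_(ia, ib)].ravel()))


def _windowed_corr(X: np.ndarray, w: int, step: int) -> np.ndarray:
    """Correlation matrices of node rows in every sliding window.

    X: (n_nodes, n_tr) -> (n_windows, n_nodes, n_nodes), vectorized.
    """
    sw = sliding_window_view(X, w, axis=1)[:, ::step]  # (n, W, w)
    swc = sw - sw.mean(axis=-1, keepdims=True)
    cov = np.einsum("iwt,jwt->wij", swc, swc)
    sd = np.sqrt(np.einsum("iwt,iwt->wi", swc, swc))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = cov / (sd[:, :, None] * sd[:, None, :])
    bad = (sd == 0) | (np.ptp(sw, axis=-1) == 0).T  # (W, n)
    if bad.any():
        c[bad[:, :, None] | bad[:, None, :]] = np.nan
    return np.clip(c, -1.0, 1.0)


def _edge_t_stack(z: np.ndarray) -> np.ndarray:
    """Vectorized one-sample t over the last (edge) axis; NaN-degenerate."""
    e = z.shape[-1]
    mean = z.mean(axis=-1)
    sd = z.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(e))
    t[~np.isfinite(t)] = np.nan
    return t


def sliding_nci(
    subject: SubjectTimeSeries,
    networks: NetworkDefinition | tuple[NetworkDefinition, NetworkDefinition],
    window_length: int = 10,
    step: int = 1,
) -> NCISeries:
    """NCI of every sliding window for one subject.

    ``networks``: a single :class:`NetworkDefinition` (intra-NCI) or a pair
    (inter-NCI). Window s covers TRs ``[s, s + window_length)``; the number
    of windows is ``floor((n_tr - w) / step) + 1``.
    """
    W = n_windows(subject.n_tr, window_length, step)
    starts = np.arange(W) * step
    if isinstance(networks, NetworkDefinition):
        idx = networks.indices
        if idx.size < 3:
            raise ValueError("insufficient edges: intra-NCI needs >= 3 nodes")
        c = _windowed_corr(subject.data[idx], window_length, step)
        iu, ju = np.triu_indices(idx.size, k=1)
        z = fisher_z(c[:, iu, ju])
        name: str | tuple[str, str] = networks.name
    else:
        net_a, net_b = networks
        if np.intersect1d(net_a.indices, net_b.indices).size:
            raise ValueError("inter-NCI requires disjoint networks")
        if net_a.size * net_b.size < 2:
            raise ValueError("need at least 2 cross-network edges")
        joint = np.concatenate([net_a.indices, net_b.indices])
        c = _windowed_corr(subject.data[joint], window_length, step)
        block = c[:, : net_a.size, net_a.size :]
        z = fisher_z(block.reshape(W, -1))
        name = (net_a.name, net_b.name)
    values = _edge_t_stack(z)
    n_degen = int(np.isnan(values).sum())
    if n_degen:
        logger.warning(
            "sliding_nci(%s, %s): %d degenerate window(s) flagged NaN",
            subject.subject_id, name, n_degen,
        )
    return NCISeries(
        subject_id=subject.subject_id,
        networks=name,
        window_length=window_length,
        step=step,
        values=values,
        window_starts=starts,
    )


def ranksum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Wilcoxon rank-sum Z with midranks and tie-corrected variance.

    Positive Z means sample ``a`` tends to exceed sample ``b``. All-tied
    input returns 0 (midrank convention). No continuity correction, so the
    statistic equals the exact permutation standardization of the rank sum
    (same mean and variance as the full enumeration over group assignments).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    n = na + nb
    ranks = stats.rankdata(np.concatenate([a, b]))
    wa = ranks[:na].sum()
    mean = na * (n + 1) / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0
    return float((wa - mean) / np.sqrt(var))


def _perm_p(a: np.ndarray, b: np.ndarray, z_obs: float, rng, max_exact=200_000,
            n_mc=10_000) -> float:
    """Two-sided permutation p for the rank-sum Z: exact enumeration of all
    group assignments when feasible, else Monte Carlo with the add-one rule."""
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    z_abs = abs(z_obs)
    if comb(n, na) <= max_exact:
        count = total = 0
        for idx in combinations(range(n), na):
            sel = np.zeros(n, bool)
            sel[list(idx)] = True
            z = ranksum_z(pooled[sel], pooled[~sel])
            count += abs(z) >= z_abs - 1e-12
            total += 1
        return count / total
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(n)
        z = ranksum_z(pooled[perm[:na]], pooled[perm[na:]])
        hits += abs(z) >= z_abs - 1e-12
    return (1 + hits) / (1 + n_mc)


def _stack_series(series: Sequence[NCISeries]) -> np.ndarray:
    ref = series[0]
    for s in series[1:]:
        if not np.array_equal(s.window_starts, ref.window_starts):
            raise ValueError("NCI series have misaligned windows")
    return np.stack([s.values for s in series])


def window_group_test(
    series_a: Sequence[NCISeries],
    series_b: Sequence[NCISeries],
    method: str = "ranksum",
    seed=None,
    epochs: Sequence["Epoch"] | None = None,
) -> pd.DataFrame:
    """Per-window two-sample comparison of subject NCI values.

    Each window is tested with a Wilcoxon rank-sum comparison converted to a
    standard-normal Z (sign = group A minus group B); p is two-tailed —
    normal approximation with midranks (``method="ranksum"``) or a
    permutation p for the same Z (``method="perm"``, exact enumeration at
    small n). q is Benjamini–Yekutieli FDR across the whole window family.
    Subjects with a degenerate (NaN) value are dropped window-wise; windows
    left with < 3 subjects in either group come back NaN.

    Returns a DataFrame with columns window_start, n_a, n_b, mean_a, mean_b,
    median_a, median_b, z, p, q, specificity (NaN placeholder) and
    epoch (bool, when ``epochs`` given).
    """
    if method not in ("ranksum", "perm"):
        raise ValueError("method must be 'ranksum' or 'perm'")
    if len(series_a) < 3 or len(series_b) < 3:
        raise ValueError("need at least 3 subjects per group")
    A, B = _stack_series(series_a), _stack_series(series_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups have different window counts")
    starts = series_a[0].window_starts
    rng = np.random.default_rng(seed)
    rows = []
    n_dropped = 0
    for w in range(A.shape[1]):
        a, b = A[:, w], B[:, w]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        n_dropped += (A.shape[0] - a.size) + (B.shape[0] - b.size)
        if a.size < 3 or b.size < 3:
            rows.append((starts[w], a.size, b.size) + (np.nan,) * 6)
            continue
        z = ranksum_z(a, b)
        if method == "ranksum":
            p = 2.0 * stats.norm.sf(abs(z)) if z != 0 else 1.0
        else:
            p = _perm_p(a, b, z, rng)
        rows.append(
            (
                starts[w], a.size, b.size,
                float(a.mean()), float(b.mean()),
                float(np.median(a)), float(np.median(b)),
                z, min(p, 1.0),
            )
        )
    if n_dropped:
        logger.warning(
            "window_group_test: dropped %d degenerate subject-window value(s)",
            n_dropped,
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "window_start", "n_a", "n_b", "mean_a", "mean_b",
            "median_a", "median_b", "z", "p",
        ],
    )
    q = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        q[ok] = fdr_by(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    out["specificity"] = np.nan
    if epochs is not None:
        in_epoch = np.zeros(len(out), dtype=bool)
        for ep in epochs:
            in_epoch |= np.isin(np.arange(len(out)), ep.windows)
        out["epoch"] = in_epoch
    return out


def fdr_by(p: np.ndarray) -> np.ndarray:
    """Benjamini–Yekutieli step-up FDR for dependent tests.

    q_(i) = min over j >= i of min(1, p_(j) * m * c(m) / j) with
    c(m) = sum_{k=1..m} 1/k; output order matches input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def significant_runs(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Runs of consecutive windows with q < alpha (run-length summary)."""
    sig = (table["q"] < alpha).to_numpy()
    rows = []
    i = 0
    while i < sig.size:
        if sig[i]:
            j = i
            while j + 1 < sig.size and sig[j + 1]:
                j += 1
            rows.append(
                {
                    "first_window": int(i),
                    "last_window": int(j),
                    "length": j - i + 1,
                    "z_min": float(table["z"].iloc[i : j + 1].abs().min()),
                    "z_max": float(table["z"].iloc[i : j + 1].abs().max()),
                }
            )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(
        rows, columns=["first_window", "last_window", "length", "z_min", "z_max"]
    )


def _window_z(
    X: np.ndarray,
    groups: np.ndarray,
    start: int,
    w: int,
    edge_sets: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Correlation matrices of one window for every subject, then the rank-sum
    Z between groups of the edge-t statistic for each requested edge set.
    X: (S, U, T); edge sets are (i_idx, j_idx) pairs into the unit axis.
    Returns one Z per edge set.
    """
    win = X[:, :, start : start + w]
    wc = win - win.mean(axis=-1, keepdims=True)
    cov = np.einsum("sit,sjt->sij", wc, wc)
    sd = np.sqrt(np.einsum("sit,sit->si", wc, wc))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = cov / (sd[:, :, None] * sd[:, None, :])
    z = fisher_z(np.clip(c, -1.0, 1.0))
    out = np.empty(len(edge_sets))
    for k, (iu, ju) in enumerate(edge_sets):
        t = _edge_t_stack(z[:, iu, ju])  # (S,)
        a, b = t[groups], t[~groups]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        out[k] = ranksum_z(a, b) if (a.size >= 3 and b.size >= 3) else np.nan
    return out


def _edges_for(sets: tuple[np.ndarray, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Edge index arrays: intra edges of one set, or cross edges of two."""
    if len(sets) == 1:
        iu, ju = np.triu_indices(sets[0].size, k=1)
        return sets[0][iu], sets[0][ju]
    ia, ib = np.meshgrid(sets[0], sets[1], indexing="ij")
    return ia.ravel(), ib.ravel()


def spatial_specificity(
    subjects: Sequence[SubjectTimeSeries],
    group_a: str,
    group_b: str,
    window_start: int,
    window_length: int,
    target: NetworkDefinition | tuple[NetworkDefinition, NetworkDefinition],
    pool: np.ndarray,
    n_random: int = 200,
    seed=None,
) -> float:
    """Spatial specificity (percent) of a window's group difference.

    Recomputes the window's between-group |Z| for ``n_random`` random node
    sets of the same size(s) as the target network(s), drawn without
    replacement from ``pool`` with the target nodes excluded, and returns
    ``100 * fraction of random sets with |Z| strictly below the observed
    |Z|``. Values near 100 mean the network effect is not a whole-brain
    phenomenon.
    """
    if n_random < 100:
        raise ValueError(f"n_random must be >= 100, got {n_random}")
    if isinstance(target, NetworkDefinition):
        sizes = (target.size,)
        target_units = target.indices
    else:
        sizes = (target[0].size, target[1].size)
        target_units = np.concatenate([target[0].indices, target[1].indices])
    pool = np.setdiff1d(np.asarray(pool, dtype=int), target_units)
    if pool.size < sum(sizes):
        raise ValueError(
            f"pool of {pool.size} nodes (targets excluded) cannot supply "
            f"{sum(sizes)} nodes"
        )
    X = np.stack([s.data for s in subjects])
    groups = np.asarray([s.group == group_a for s in subjects])
    if groups.sum() < 3 or (~groups).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    rng = np.random.default_rng(seed)

    if isinstance(target, NetworkDefinition):
        obs_sets = (target.indices,)
    else:
        obs_sets = (target[0].indices, target[1].indices)
    edge_sets = [_edges_for(obs_sets)]
    for _ in range(n_random):
        draw = rng.choice(pool, size=sum(sizes), replace=False)
        if len(sizes) == 1:
            edge_sets.append(_edges_for((draw,)))
        else:
            edge_sets.append(_edges_for((draw[: sizes[0]], draw[sizes[0] :])))
    zs = _window_z(X, groups, window_start, window_length, edge_sets)
    z_obs, z_rand = abs(zs[0]), np.abs(zs[1:])
    if np.isnan(z_obs):
        return np.nan
    return float(100.0 * np.mean(z_rand[~np.isnan(z_rand)] < z_obs))


@dataclass
class Epoch:
    """A rating-defined stimulus epoch: a TR run and the windows inside it."""

    tr_start: int
    tr_stop: int  # half-open
    windows: np.ndarray  # indices of analysis windows fully inside the run


def rating_epochs(
    rating: RatingCurve,
    threshold: float,
    window_length: int = 10,
    step: int = 1,
) -> list[Epoch]:
    """Epochs where the median rating reaches ``threshold``.

    Maximal runs of consecutive TRs with ``median >= threshold``, each
    mapped to the set of analysis windows lying fully inside the run.
    A threshold outside the observed rating range yields an empty set with
    a warning.
    """
    med = rating.median
    if threshold < med.min() or threshold > med.max():
        logger.warning(
            "rating_epochs: threshold %.3g outside observed rating range "
            "[%.3g, %.3g]; no epochs",
            threshold, med.min(), med.max(),
        )
        return []
    above = med >= threshold
    W = n_windows(med.size, window_length, step)
    starts = np.arange(W) * step
    epochs: list[Epoch] = []
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j + 1 < above.size and above[j + 1]:
                j += 1
            inside = np.where((starts >= i) & (starts + window_length <= j + 1))[0]
            epochs.append(Epoch(tr_start=i, tr_stop=j + 1, windows=inside))
            i = j + 1
        else:
            i += 1
    return epochs
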