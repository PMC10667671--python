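"""Beta diversity: Bray-Curtis, NMDS, ANOSIM, SIMPER, temporal decay.

All operations work on a :class:`DistanceMatrix` of Bray-Curtis
dissimilarities computed from rarefied relative abundances (with equal
sample depths, counts and proportions give the same dissimilarity).
Temporal analytics assess recovery after a mixing disturbance: time-lag
regression (dissimilarity vs. months between samples) and the
distribution of pairwise dissimilarities within/between the before,
mixing and after periods.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .community import CommunityTable, compare_groups_kw

DAYS_PER_MONTH = 30.44  # mean Gregorian month

PERIOD_PAIR_BINS = ("B-B", "B-M", "B-A", "M-M", "M-A", "A-A")
_PERIOD_CODE = {"before": "B", "mixing": "M", "after": "A"}


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    data: np.ndarray
    ids: tuple

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "ids", tuple(self.ids))
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(d, d.T):
            raise ValueError("matrix must be symmetric")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("Bray-Curtis dissimilarities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS sample coordinates and final Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float


def bray_curtis(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    ``d(j, k) = sum_t |y_tj - y_tk| / sum_t (y_tj + y_tk)`` on relative
    abundances.  Raises on all-zero samples (dissimilarity undefined).
    """
    rel = table.relative_abundance().to_numpy()
    d = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(d, tuple(table.samples))


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 8,
    seed: int | None = None,
    max_iter: int = 300,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling (Kruskal stress-1).

    Runs one classical-scaling start plus ``n_starts`` random starts and
    keeps the configuration with the lowest stress.  Coordinates are
    centred and rotated to their principal axes so the layout is
    reproducible up to axis sign, which is fixed by making the largest-
    magnitude coordinate on each axis positive.
    """
    if dm.n < k + 1:
        raise ValueError("need at least k + 1 samples")
    if np.allclose(dm.condensed(), dm.condensed()[0] if dm.n > 1 else 0):
        warnings.warn("all pairwise distances equal; configuration is arbitrary", stacklevel=2)
    rng = np.random.default_rng(seed)
    best_X, best_stress = None, np.inf
    inits = ["classical_mds"] + ["random"] * n_starts
    for init in inits:
        m = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init=init,
            max_iter=max_iter,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X = m.fit_transform(dm.data)
        if m.stress_ < best_stress:
            best_X, best_stress = X, float(m.stress_)
    X = best_X - best_X.mean(axis=0)
    # principal-axis rotation for a canonical orientation
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    for j in range(X.shape[1]):
        if np.abs(X[:, j]).max() > 0 and X[np.abs(X[:, j]).argmax(), j] < 0:
            X[:, j] = -X[:, j]
    coords = pd.DataFrame(
        X, index=list(dm.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, best_stress)


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    m = n * (n - 1) / 2
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)


def anosim(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> dict:
    """Analysis of similarities.

    ``R = (mean rank between - mean rank within) / (M / 2)`` with
    ``M = n(n-1)/2`` and mid-ranks for ties; R = 1 means all
    between-group dissimilarities exceed all within-group ones.  The
    permutation p-value uses the add-one convention
    ``p = (1 + #{R_perm >= R_obs}) / (1 + n_perm)``.

    With ``exact=True`` all label permutations are enumerated instead
    (feasible for small n) and ``p = #{R_perm >= R_obs} / n!`` with the
    identity permutation included; no add-one correction is needed since
    the identity guarantees p > 0.
    """
    groups = np.asarray(groups)
    if len(groups) != dm.n:
        raise ValueError("one group label per sample required")
    _, counts = np.unique(groups, return_counts=True)
    if len(counts) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two members")
    cond = dm.condensed()
    ranks = stats.rankdata(cond)
    n = dm.n
    ii, jj = np.triu_indices(n, k=1)

    def within_mask(g: np.ndarray) -> np.ndarray:
        return g[ii] == g[jj]

    r_obs = _anosim_r(ranks, within_mask(groups), n)
    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(groups):
            total += 1
            if _anosim_r(ranks, within_mask(np.asarray(perm)), n) >= r_obs - 1e-12:
                count += 1
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            if _anosim_r(ranks, within_mask(perm), n) >= r_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
    return {"R": float(r_obs), "p": float(p)}


def simper(table: CommunityTable, groups) -> dict:
    """Similarity percentages: per-taxon contributions to dissimilarity.

    For each pair of groups, the contribution of taxon t to a
    between-group sample pair (j, k) is ``|y_tj - y_tk| / sum_t (y_tj +
    y_tk)``; contributions are averaged over all between-group pairs and
    expressed as percentages of the mean between-group Bray-Curtis
    dissimilarity.  Contributions therefore sum to 100%.

    Returns ``{(group_a, group_b): DataFrame}`` with columns
    ``average_contribution_pct`` and ``cumulative_pct``, taxa sorted by
    contribution (descending).
    """
    groups = np.asarray(groups)
    rel = table.relative_abundance()
    y = rel.to_numpy()
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    out: dict = {}
    for ga, gb in itertools.combinations(names, 2):
        ia = np.nonzero(groups == ga)[0]
        ib = np.nonzero(groups == gb)[0]
        contrib = np.zeros(y.shape[1])
        total = 0.0
        n_pairs = 0
        for j in ia:
            for k in ib:
                denom = (y[j] + y[k]).sum()
                if denom == 0:
                    raise ValueError("pair of all-zero samples")
                terms = np.abs(y[j] - y[k]) / denom
                contrib += terms
                total += terms.sum()
                n_pairs += 1
        contrib /= n_pairs
        mean_bc = total / n_pairs
        pct = 100 * contrib / mean_bc
        df = pd.DataFrame(
            {"average_contribution_pct": pct}, index=rel.columns
        ).sort_values("average_contribution_pct", ascending=False)
        df["cumulative_pct"] = df["average_contribution_pct"].cumsum()
        df.attrs["mean_between_group_dissimilarity"] = mean_bc
        out[(ga, gb)] = df
    return out


def time_lag(dm: DistanceMatrix, dates) -> dict:
    """Dissimilarity vs. time lag in months, with an OLS trend.

    Lags are continuous: day difference / 30.44.  A positive significant
    slope indicates directional community change; divergence that slows
    or reverses shows as curvature (not fitted here).

    Returns ``{"pairs": DataFrame(lag_months, dissimilarity),
    "slope", "intercept", "r", "p"}``.
    """
    dates = pd.to_datetime(pd.Index(dates))
    if len(dates) != dm.n:
        raise ValueError("one date per sample required")
    ii, jj = np.triu_indices(dm.n, k=1)
    lag_days = np.abs((dates[jj] - dates[ii]) / np.timedelta64(1, "D"))
    lags = lag_days / DAYS_PER_MONTH
    diss = dm.data[ii, jj]
    if np.allclose(diss, diss[0]):
        slope, intercept, r, p = 0.0, float(diss[0]), 0.0, 1.0
    else:
        res = stats.linregress(lags, diss)
        slope, intercept, r, p = res.slope, res.intercept, res.rvalue, res.pvalue
    pairs = pd.DataFrame({"lag_months": lags, "dissimilarity": diss})
    return {
        "pairs": pairs,
        "slope": float(slope),
        "intercept": float(intercept),
        "r": float(r),
        "p": float(p),
    }


def period_pair_dissimilarity(dm: DistanceMatrix, periods, alpha: float = 0.05) -> dict:
    """Group pairwise dissimilarities by period combination and compare.

    Every unordered sample pair falls in exactly one of six bins (B-B,
    B-M, B-A, M-M, M-A, A-A).  The before-vs-after bin (B-A) being low
    relative to B-M is the recovery signature.  Bins are compared with
    Kruskal-Wallis plus a compact letter display.
    """
    periods = np.asarray(periods)
    if set(np.unique(periods)) != {"before", "mixing", "after"}:
        raise ValueError("all three periods must be represented")
    ii, jj = np.triu_indices(dm.n, k=1)
    order = {"B": 0, "M": 1, "A": 2}
    bins: dict[str, list] = {b: [] for b in PERIOD_PAIR_BINS}
    labels = []
    for a, b, d in zip(ii, jj, dm.data[ii, jj]):
        ca, cb = _PERIOD_CODE[periods[a]], _PERIOD_CODE[periods[b]]
        ca, cb = sorted((ca, cb), key=order.get)
        name = f"{ca}-{cb}"
        bins[name].append(float(d))
        labels.append(name)
    values = dm.data[ii, jj]
    kw = compare_groups_kw(values, labels, alpha=alpha)
    return {"bins": {k: np.asarray(v) for k, v in bins.items()}, "test": kw}
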