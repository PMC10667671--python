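"""Multi-nutrient cycling index and PLS path modelling.

The multi-nutrient cycling (MNC) index summarises eight carbon,
nitrogen and phosphorus variables (TC, TOC, TN, NH4, NO3, NO2, TP, PO4)
per sample: each variable is log(x+1)-transformed, z-scored over
samples, and the eight z-scores are averaged.  By construction the MNC
has mean ~0 over samples; positive values mark samples with above-
average nutrient status across the board.

Partial least squares path modelling (PLS-PM) then links environmental
drivers, community descriptors (NMDS axis scores, network properties,
abundances) and the MNC.  The estimation is Lohmoeller's alternating
algorithm with reflective (mode A) measurement and the centroid inner
weighting scheme; path coefficients are OLS regressions among the
unit-variance latent-variable scores; model quality is summarised by
per-endogenous-LV R-squared and the goodness of fit
GoF = sqrt(mean communality x mean R2).  Indicators with outer
loadings below 0.7 are iteratively pruned.  Highly collinear raw
variables are removed beforehand (squared Spearman rho >= 0.5 for
environmental variables, >= 0.6 for the few network properties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MNC_VARIABLES = ("TC", "TOC", "TN", "NH4", "NO3", "NO2", "TP", "PO4")

LOADING_PRUNE_THRESHOLD = 0.7
COLLINEARITY_SQ_RHO_ENV = 0.5
COLLINEARITY_SQ_RHO_NET = 0.6


def mnc_index(nutrients: pd.DataFrame, variables=MNC_VARIABLES) -> pd.Series:
    """Multi-nutrient cycling index per sample.

    ``z_v = (log(x_v + 1) - mean) / SD`` per variable over samples
    (sample SD, n-1); MNC = mean of the z-scores across variables.
    """
    missing = [v for v in variables if v not in nutrients.columns]
    if missing:
        raise ValueError(f"missing nutrient variables: {missing}")
    x = nutrients.loc[:, list(variables)].astype(float)
    if (x < 0).any().any():
        raise ValueError("nutrient concentrations must be non-negative")
    logged = np.log1p(x)
    sd = logged.std(ddof=1)
    zero_var = sd.index[sd == 0].tolist()
    if zero_var:
        raise ValueError(f"zero-variance nutrient variables: {zero_var}")
    z = (logged - logged.mean()) / sd
    out = z.mean(axis=1)
    out.name = "MNC"
    return out


def collinearity_filter(variables: pd.DataFrame, threshold_sq_rho: float) -> list:
    """Drop the later of any pair with squared Spearman rho >= threshold.

    A single deterministic greedy pass in column order: for each kept
    column, any later column correlating too strongly with it is
    dropped.  Returns the retained column names in input order.
    """
    cols = list(variables.columns)
    if len(cols) < 2:
        return cols
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(variables.to_numpy())[0]
    if np.ndim(rho) == 0:  # spearmanr returns a scalar for two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dropped: set = set()
    for i, a in enumerate(cols):
        if a in dropped:
            continue
        for j in range(i + 1, len(cols)):
            b = cols[j]
            if b in dropped:
                continue
            if np.isfinite(rho[i, j]) and rho[i, j] ** 2 >= threshold_sq_rho:
                dropped.add(b)
    return [c for c in cols if c not in dropped]


# ---------------------------------------------------------------------------
# PLS path modelling (Lohmoeller, mode A, centroid scheme)
# ---------------------------------------------------------------------------


class ConvergenceError(RuntimeError):
    def __init__(self, trace):
        self.trace = trace
        super().__init__(
            f"outer-weight iteration did not converge; last deltas: {trace[-5:]}"
        )


@dataclass
class PlsPathModel:
    """Fitted PLS path model."""

    blocks: dict  # LV name -> list of indicator columns (after pruning)
    inner: pd.DataFrame  # square 0/1 matrix, inner[j, i] = 1 for path i -> j
    weights: pd.Series  # outer weights per indicator
    loadings: pd.Series  # correlation of indicator with its LV score
    scores: pd.DataFrame  # unit-variance LV scores per sample
    paths: pd.DataFrame  # path coefficients, rows = endogenous LV
    r2: pd.Series  # per endogenous LV
    communality: pd.Series  # mean squared loading per block
    gof: float
    pruned: list = field(default_factory=list)  # indicators removed (<0.7)
    n_iter: int = 0


def _validate_inner(inner: pd.DataFrame, lvs: list) -> pd.DataFrame:
    inner = inner.loc[lvs, lvs].astype(float)
    a = inner.to_numpy()
    if np.any((a != 0) & (a != 1)):
        raise ValueError("inner matrix entries must be 0/1")
    if np.any(np.triu(a) != 0):
        raise ValueError(
            "inner matrix must be lower-triangular in the given LV order (acyclic)"
        )
    return inner


def _standardize(x: pd.DataFrame) -> pd.DataFrame:
    sd = x.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant indicators: {sd.index[sd == 0].tolist()}")
    return (x - x.mean()) / sd


def fit_plspm(
    data: pd.DataFrame,
    blocks: dict,
    inner: pd.DataFrame,
    scheme: str = "centroid",
    tol: float = 1e-6,
    max_iter: int = 100,
    prune_threshold: float | None = LOADING_PRUNE_THRESHOLD,
) -> PlsPathModel:
    """Fit a PLS path model (mode A outer, centroid/factorial inner).

    ``blocks`` maps each latent variable to its indicator columns;
    ``inner`` is a square 0/1 DataFrame over the LVs with
    ``inner.loc[target, source] = 1`` for a directed path, and must be
    lower-triangular in LV order (acyclic).  Indicators are standardized
    internally; LV scores have unit variance and are sign-aligned to
    correlate positively with their first indicator.  When
    ``prune_threshold`` is set, the model is refit after dropping
    indicators with |loading| below it, until none remain.
    """
    if scheme not in ("centroid", "factorial"):
        raise ValueError("scheme must be 'centroid' or 'factorial'")
    lvs = list(blocks)
    for lv, inds in blocks.items():
        if not inds:
            raise ValueError(f"block {lv!r} has no indicators")
        for c in inds:
            if c not in data.columns:
                raise ValueError(f"indicator {c!r} of block {lv!r} not in data")
    inner = _validate_inner(inner, lvs)
    blocks = {lv: list(inds) for lv, inds in blocks.items()}
    pruned: list = []

    while True:
        model = _fit_once(data, blocks, inner, scheme, tol, max_iter)
        if prune_threshold is None:
            break
        low = model.loadings[model.loadings.abs() < prune_threshold]
        if low.empty:
            break
        # drop the worst indicator, refit, repeat
        worst = low.abs().idxmin()
        lv = next(l for l, inds in blocks.items() if worst in inds)
        if len(blocks[lv]) == 1:
            raise ValueError(
                f"all indicators of block {lv!r} fall below the loading "
                f"threshold {prune_threshold}; refusing to empty the block"
            )
        blocks[lv].remove(worst)
        pruned.append(worst)
    model.pruned = pruned
    return model


def _fit_once(data, blocks, inner, scheme, tol, max_iter) -> PlsPathModel:
    lvs = list(blocks)
    all_inds = [c for lv in lvs for c in blocks[lv]]
    X = _standardize(data.loc[:, all_inds].astype(float))
    n = len(X)
    adj = inner.to_numpy()
    neighbours = adj + adj.T  # undirected adjacency for the inner estimate

    def lv_scores(w: dict) -> pd.DataFrame:
        Y = {}
        for lv in lvs:
            y = X[blocks[lv]].to_numpy() @ w[lv]
            y = y / y.std(ddof=1)
            Y[lv] = y
        return pd.DataFrame(Y, index=X.index)

    weights = {lv: np.ones(len(blocks[lv])) for lv in lvs}
    trace = []
    converged = False
    for it in range(1, max_iter + 1):
        Y = lv_scores(weights)
        C = np.corrcoef(Y.to_numpy(), rowvar=False)
        C = np.atleast_2d(C)
        new_weights = {}
        for a, lv in enumerate(lvs):
            nb = np.nonzero(neighbours[a])[0]
            if len(nb) == 0:
                raise ValueError(f"latent variable {lv!r} is isolated in the inner model")
            if scheme == "centroid":
                e = np.sign(C[a, nb])
                e[e == 0] = 1.0
            else:  # factorial
                e = C[a, nb]
            z = Y.to_numpy()[:, nb] @ e
            zsd = z.std(ddof=1)
            if zsd == 0:
                raise ValueError(f"degenerate inner estimate for {lv!r}")
            z = z / zsd
            # mode A: weights proportional to cov(indicator, inner estimate)
            w = X[blocks[lv]].to_numpy().T @ z / (n - 1)
            new_weights[lv] = w
        # scale-invariant convergence check on normalized weights
        delta = 0.0
        for lv in lvs:
            wo = weights[lv] / np.linalg.norm(weights[lv])
            wn = new_weights[lv] / np.linalg.norm(new_weights[lv])
            if np.dot(wo, wn) < 0:
                wo = -wo
            delta = max(delta, np.abs(wn - wo).max())
        weights = new_weights
        trace.append(delta)
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(trace)

    Y = lv_scores(weights)
    # sign convention: LV correlates positively with its first indicator
    for lv in lvs:
        first = blocks[lv][0]
        if np.corrcoef(Y[lv], X[first])[0, 1] < 0:
            Y[lv] = -Y[lv]
            weights[lv] = -weights[lv]

    loadings = pd.Series(
        {
            c: float(np.corrcoef(X[c], Y[lv])[0, 1])
            for lv in lvs
            for c in blocks[lv]
        }
    )
    w_ser = pd.Series(
        {c: float(w) for lv in lvs for c, w in zip(blocks[lv], weights[lv])}
    )

    paths = pd.DataFrame(0.0, index=lvs, columns=lvs)
    r2 = {}
    for a, lv in enumerate(lvs):
        preds = [lvs[b] for b in np.nonzero(adj[a])[0]]
        if not preds:
            continue
        Xp = Y[preds].to_numpy()
        yv = Y[lv].to_numpy()
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(n), Xp]), yv, rcond=None
        )
        if not np.all(np.isfinite(coef)):
            raise np.linalg.LinAlgError(f"singular inner regression for {lv!r}")
        paths.loc[lv, preds] = coef[1:]
        fitted = np.column_stack([np.ones(n), Xp]) @ coef
        r2[lv] = float(1 - ((yv - fitted) ** 2).sum() / ((yv - yv.mean()) ** 2).sum())
    r2 = pd.Series(r2)

    communality = pd.Series(
        {lv: float((loadings[blocks[lv]] ** 2).mean()) for lv in lvs}
    )
    gof = float(np.sqrt(communality.mean() * r2.mean())) if len(r2) else np.nan
    return PlsPathModel(
        blocks={lv: list(i) for lv, i in blocks.items()},
        inner=inner,
        weights=w_ser,
        loadings=loadings,
        scores=Y,
        paths=paths,
        r2=r2,
        communality=communality,
        gof=gof,
        n_iter=len(trace),
    )


def bootstrap_paths(
    data: pd.DataFrame,
    blocks: dict,
    inner: pd.DataFrame,
    n_boot: int = 999,
    seed: int | None = None,
    scheme: str = "centroid",
    max_redraws: int = 100,
) -> pd.DataFrame:
    """Case-resampling bootstrap of the inner path coefficients.

    Each resample refits the full model (without pruning, so the path
    set is stable across resamples).  Per path: the point estimate, the
    95% percentile interval, and a two-sided p from interval inversion
    with the add-one convention, ``p = 2 * min(#{b <= 0} + 1,
    #{b >= 0} + 1) / (n_boot + 1)`` capped at 1.  Resamples with a
    constant indicator are redrawn (up to ``max_redraws`` per draw).
    """
    fit = fit_plspm(data, blocks, inner, scheme=scheme, prune_threshold=None)
    path_idx = [
        (t, s) for t in fit.paths.index for s in fit.paths.columns
        if fit.inner.loc[t, s] == 1
    ]
    rng = np.random.default_rng(seed)
    n = len(data)
    boots = np.empty((n_boot, len(path_idx)))
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            sample = data.iloc[idx].reset_index(drop=True)
            try:
                m = fit_plspm(sample, blocks, inner, scheme=scheme, prune_threshold=None)
                break
            except (ValueError, ConvergenceError, np.linalg.LinAlgError):
                if attempt == max_redraws:
                    raise
        boots[b] = [m.paths.loc[t, s] for t, s in path_idx]
    rows = []
    for k, (t, s) in enumerate(path_idx):
        bs = boots[:, k]
        lo, hi = np.percentile(bs, [2.5, 97.5])
        p = 2 * min((bs <= 0).sum() + 1, (bs >= 0).sum() + 1) / (n_boot + 1)
        rows.append(
            {
                "target": t,
                "source": s,
                "estimate": float(fit.paths.loc[t, s]),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p": float(min(p, 1.0)),
            }
        )
    return pd.DataFrame(rows)


def build_inner_matrix(lvs: list, edges: list) -> pd.DataFrame:
    """Square 0/1 inner matrix from (source, target) directed edges.

    The LV order must be a topological order of the edges (sources
    before targets), giving a lower-triangular matrix.
    """
    inner = pd.DataFrame(0.0, index=lvs, columns=lvs)
    pos = {lv: i for i, lv in enumerate(lvs)}
    for s, t in edges:
        if pos[s] >= pos[t]:
            raise ValueError(f"edge {s!r} -> {t!r} violates the LV order")
        inner.loc[t, s] = 1.0
    return inner


def reservoir_inner_matrix(
    drivers: list,
    community: list,
    response: str = "MNC",
    excluded_driver_paths: tuple = ("Nutr",),
) -> pd.DataFrame:
    """Driver -> community -> nutrient-cycling inner structure.

    Every environmental driver points to every community LV and (except
    those in ``excluded_driver_paths``) directly to the response; every
    community LV points to the response.  The nutrient block's direct
    path to the MNC is structurally absent because the MNC is computed
    from the nutrient measurements themselves.
    """
    lvs = list(drivers) + list(community) + [response]
    edges = [(d, c) for d in drivers for c in community]
    edges += [(d, response) for d in drivers if d not in excluded_driver_paths]
    edges += [(c, response) for c in community]
    return build_inner_matrix(lvs, edges)
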