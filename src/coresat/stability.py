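"""Moving-window community stability (inverse coefficient of variation).

Temporal stability of a (sub)community is quantified per overlapping
time window as 1/CV = mu/sigma of its group-summed absolute abundance
(copies per mL); higher values mean abundance varies less relative to
its mean.  With 34 samples and 5-sample windows there are 30 windows;
under a 14/11/9 before/mixing/after design they split into group 1
(pre-disturbance only, n = 10), group 2 (containing at least one
complete-mixing sample, n = 15) and group 3 (post-disturbance only,
n = 5).  Windows are numbered 1-based: window 11 = samples 11-15 is the
first to include a mixing sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WINDOW = 5

WINDOW_GROUPS = ("group1", "group2", "group3")


def moving_windows(n_samples: int, w: int = DEFAULT_WINDOW) -> list[np.ndarray]:
    """Overlapping windows of ``w`` consecutive samples.

    Returns ``n_samples - w + 1`` arrays of 0-based sample positions;
    window i (1-based) covers samples i..i+w-1.
    """
    if w < 2:
        raise ValueError("window length must be at least 2")
    if n_samples < w:
        raise ValueError("need at least w samples")
    return [np.arange(i, i + w) for i in range(n_samples - w + 1)]


def window_stability(abundance_series, windows: list[np.ndarray]) -> pd.DataFrame:
    """1/CV per window of a group-summed absolute-abundance series.

    stability = mean / SD (sample SD, n-1 denominator) of the window's
    values; a zero-variance window is reported as ``inf``.  1/CV is
    scale invariant, so units cancel.

    Returns a DataFrame with 1-based ``window_index`` and ``stability``.
    """
    x = np.asarray(abundance_series, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("abundances must be finite and non-negative")
    rows = []
    for i, idx in enumerate(windows, start=1):
        vals = x[idx]
        sd = vals.std(ddof=1)
        stab = np.inf if sd == 0 else vals.mean() / sd
        rows.append((i, stab))
    return pd.DataFrame(rows, columns=["window_index", "stability"])


def assign_window_groups(windows: list[np.ndarray], periods) -> pd.Series:
    """Disturbance group of each window from its members' period labels.

    group1: all members before; group2: >= 1 complete-mixing member;
    group3: all members after.  A window spanning before and after with
    no mixing member cannot occur in a contiguous design and raises.
    """
    periods = np.asarray(periods)
    out = []
    for idx in windows:
        labs = set(periods[idx])
        if "mixing" in labs:
            out.append("group2")
        elif labs == {"before"}:
            out.append("group1")
        elif labs == {"after"}:
            out.append("group3")
        else:
            raise ValueError(
                f"window with members {idx + 1} spans before and after periods "
                "without a mixing sample; period labels are not contiguous"
            )
    return pd.Series(out, index=pd.RangeIndex(1, len(windows) + 1, name="window_index"))


def stability_series(
    abundance_series,
    periods,
    w: int = DEFAULT_WINDOW,
    subcommunity: str | None = None,
) -> pd.DataFrame:
    """Convenience: windows + 1/CV + disturbance groups in one frame."""
    windows = moving_windows(len(np.asarray(abundance_series)), w)
    df = window_stability(abundance_series, windows)
    df["window_group"] = assign_window_groups(windows, periods).to_numpy()
    if subcommunity is not None:
        df["subcommunity"] = subcommunity
    return df


def stability_relation(sub: pd.DataFrame, entire: pd.DataFrame) -> dict:
    """OLS relation between subcommunity and entire-community stability.

    Windows are aligned by ``window_index``; windows where either series
    is non-finite (zero-variance flag) are excluded pairwise.  A higher
    Pearson r for the core than the satellite subcommunity indicates the
    core dominates whole-community abundance stability.

    Returns ``{"slope", "intercept", "r", "p", "n"}``.
    """
    merged = sub.merge(entire, on="window_index", suffixes=("_sub", "_entire"))
    x = merged["stability_entire"].to_numpy(dtype=float)
    y = merged["stability_sub"].to_numpy(dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    if finite.sum() < 3:
        raise ValueError("need at least 3 windows with finite stability")
    res = stats.linregress(x[finite], y[finite])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "n": int(finite.sum()),
    }
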