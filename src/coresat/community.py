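"""Count-table preparation, core/satellite partitioning, absolute abundance.

The central object is :class:`CommunityTable`: a sample x taxon count
matrix plus per-sample metadata (depth layer, date, disturbance period).
Preparation follows the standard amplicon workflow: drop taxa with fewer
than 10 reads overall, rarefy every sample to a common depth, then

* partition taxa by occupancy — **core** (present in >= 75% of samples),
  **satellite** (< 50%), intermediate in between — and by per-sample
  relative abundance into six categories (always abundant, conditionally
  abundant, moderate, conditionally rare, conditionally rare-and-abundant,
  always rare);
* convert relative abundances to absolute abundances (copies per mL) by
  scaling with per-sample qPCR total 18S rRNA gene copy numbers.

Occupancy partitioning is done per depth layer: pass one depth's table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

OCCUPANCY_CORE_MIN = 0.75
OCCUPANCY_SATELLITE_MAX = 0.50
ABUNDANT_THRESHOLD = 0.01
RARE_THRESHOLD = 0.0001
MIN_TAXON_TOTAL = 10

ABUNDANCE_CLASSES = ("AAT", "CAT", "MT", "CRT", "CRAT", "ART")


@dataclass
class CommunityTable:
    """Sample x taxon counts with aligned sample metadata.

    ``counts``: DataFrame, rows = samples, columns = taxa, non-negative
    integers.  ``sample_meta``: DataFrame indexed like ``counts`` with at
    least the columns ``depth`` (surface/bottom), ``date`` and optionally
    ``period`` (before/mixing/after).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.counts.index)
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon identifiers: {dup}")
        arr = c.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {c.index[i]!r}, taxon {c.columns[j]!r}"
            )
        if not self.sample_meta.index.equals(c.index):
            raise ValueError("sample_meta index must match counts index")

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def taxa(self) -> pd.Index:
        return self.counts.columns

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        sums = self.sample_sums()
        if (sums == 0).any():
            empty = sums.index[sums == 0].tolist()
            raise ValueError(f"samples with zero total count: {empty}")
        return self.counts.div(sums, axis=0)

    def subset_taxa(self, taxa: Sequence) -> "CommunityTable":
        return CommunityTable(self.counts.loc[:, list(taxa)].copy(), self.sample_meta.copy())

    def subset_samples(self, samples: Sequence) -> "CommunityTable":
        return CommunityTable(
            self.counts.loc[list(samples)].copy(), self.sample_meta.loc[list(samples)].copy()
        )

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.sample_meta.equals(other.sample_meta)


def filter_low_count_taxa(
    table: CommunityTable, min_total: int = MIN_TAXON_TOTAL
) -> CommunityTable:
    """Remove taxa whose dataset-wide read total is below ``min_total``.

    Taxa with fewer than 10 reads overall are conventionally treated as
    likely sequencing errors.  Samples are never dropped here.
    """
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals >= min_total]
    if len(keep) == 0:
        warnings.warn("low-count filter removed every taxon", stacklevel=2)
    return CommunityTable(table.counts.loc[:, keep].copy(), table.sample_meta.copy())


def rarefy(
    table: CommunityTable,
    depth: Optional[int] = None,
    seed: Optional[int] = None,
) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    ``depth`` defaults to the minimum sample sum.  Sampling is
    multivariate hypergeometric (subsampling reads, not taxa), so a
    sample whose total already equals ``depth`` is returned unchanged.
    Samples with fewer than ``depth`` reads are dropped with a warning.
    """
    sums = table.sample_sums()
    if depth is None:
        depth = int(sums.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    shallow = sums.index[sums < depth]
    if len(shallow) > 0:
        warnings.warn(
            f"dropping {len(shallow)} samples below rarefaction depth {depth}: "
            f"{list(shallow)}",
            stacklevel=2,
        )
    keep = sums.index[sums >= depth]
    rng = np.random.default_rng(seed)
    out = {}
    for s in keep:
        row = table.counts.loc[s].to_numpy().astype(np.int64)
        if row.sum() == depth:
            out[s] = row
        else:
            out[s] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame.from_dict(out, orient="index", columns=table.taxa)
    counts = counts.loc[keep]
    return CommunityTable(counts, table.sample_meta.loc[keep].copy())


def partition_taxa(
    table: CommunityTable,
    core_min: float = OCCUPANCY_CORE_MIN,
    satellite_max: float = OCCUPANCY_SATELLITE_MAX,
    abundant_thr: float = ABUNDANT_THRESHOLD,
    rare_thr: float = RARE_THRESHOLD,
) -> pd.DataFrame:
    """Classify each taxon by occupancy and by abundance category.

    Occupancy (occurrence frequency) is the fraction of samples in which
    the taxon has a non-zero count: ``core`` if >= ``core_min``,
    ``satellite`` if < ``satellite_max``, else ``intermediate``.

    Abundance categories use per-sample relative abundances r with two
    cut-offs (abundant 1%, rare 0.01% by default):

    * AAT  — r >= abundant in every sample
    * CAT  — r >= rare everywhere, >= abundant somewhere but not everywhere
    * MT   — rare <= r < abundant in every sample
    * CRT  — r < abundant everywhere and r < rare somewhere but not everywhere
    * CRAT — r >= abundant somewhere and r < rare somewhere else
    * ART  — r < rare in every sample

    The six categories are mutually exclusive and exhaustive.

    Returns a DataFrame indexed by taxon with columns
    ``occurrence_frequency``, ``mean_relative_abundance``,
    ``occupancy_class``, ``abundance_class``.
    """
    if not rare_thr < abundant_thr:
        raise ValueError("rare threshold must be below abundant threshold")
    if not 0 < satellite_max <= core_min <= 1:
        raise ValueError("need 0 < satellite_max <= core_min <= 1")
    rel = table.relative_abundance()
    n = len(table.samples)
    freq = (table.counts > 0).sum(axis=0) / n
    mean_rel = rel.mean(axis=0)

    occupancy = pd.Series("intermediate", index=table.taxa, name="occupancy_class")
    occupancy[freq >= core_min] = "core"
    occupancy[freq < satellite_max] = "satellite"

    n_abundant = (rel >= abundant_thr).sum(axis=0)
    n_rare = (rel < rare_thr).sum(axis=0)
    abundance = pd.Series("MT", index=table.taxa, name="abundance_class")
    abundance[(n_abundant >= 1) & (n_rare == 0) & (n_abundant < n)] = "CAT"
    abundance[(n_abundant == 0) & (n_rare >= 1) & (n_rare < n)] = "CRT"
    abundance[(n_abundant >= 1) & (n_rare >= 1)] = "CRAT"
    abundance[n_abundant == n] = "AAT"
    abundance[n_rare == n] = "ART"

    return pd.DataFrame(
        {
            "occurrence_frequency": freq,
            "mean_relative_abundance": mean_rel,
            "occupancy_class": occupancy,
            "abundance_class": abundance,
        }
    )


def occupancy_sets(partition: pd.DataFrame) -> dict[str, list]:
    """Taxon id lists for the entire, core and satellite (sub)communities."""
    return {
        "entire": partition.index.tolist(),
        "core": partition.index[partition["occupancy_class"] == "core"].tolist(),
        "satellite": partition.index[partition["occupancy_class"] == "satellite"].tolist(),
    }


def absolute_abundance(
    table: CommunityTable,
    qpcr_totals: pd.Series,
    partition: Optional[pd.DataFrame] = None,
) -> dict:
    """Scale relative abundances to copies per mL with qPCR totals.

    ``abs(i, t) = qpcr_total(i) * count(i, t) / sum_t count(i, t)``.

    Returns ``{"per_taxon": DataFrame, "group_sums": DataFrame}`` where
    ``group_sums`` has one column per subcommunity (entire, and core /
    satellite when a partition is given).  The entire-community sum
    equals the qPCR total for every sample (conservation).
    """
    missing = [s for s in table.samples if s not in qpcr_totals.index]
    if missing:
        raise ValueError(f"missing qPCR totals for samples: {missing}")
    totals = qpcr_totals.loc[table.samples].astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"qPCR totals must be positive; offending samples: {bad}")
    per_taxon = table.relative_abundance().mul(totals, axis=0)
    groups = {"entire": per_taxon.sum(axis=1)}
    if partition is not None:
        for name, taxa in occupancy_sets(partition).items():
            if name == "entire":
                continue
            groups[name] = per_taxon.loc[:, taxa].sum(axis=1)
    return {"per_taxon": per_taxon, "group_sums": pd.DataFrame(groups)}


# ---------------------------------------------------------------------------
# Kruskal-Wallis group comparison with a compact letter display
# ---------------------------------------------------------------------------


def _compact_letters(groups: list, significant: set[frozenset]) -> dict:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different.  Starts from
    one column containing all groups; for every significant pair, each
    column containing both is split; columns that become subsets of
    another are absorbed.
    """
    columns: list[set] = [set(groups)]
    for pair in significant:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.append(col - {a})
            columns.append(col - {b})
        # absorb: drop columns contained in another
        columns = [
            c
            for i, c in enumerate(columns)
            if c and not any(c < d or (c == d and i > j) for j, d in enumerate(columns))
        ]
    # deterministic letter order: by first group in input order
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for k, col in enumerate(columns):
        for g in groups:
            if g in col:
                letters[g] += alphabet[k % len(alphabet)]
    return letters


def compare_groups_kw(
    values: Sequence[float],
    labels: Sequence,
    alpha: float = 0.05,
) -> dict:
    """Kruskal-Wallis test across groups with post-hoc letters.

    Post-hoc: pairwise two-sided Mann-Whitney U with Benjamini-Hochberg
    correction; the compact letter display marks groups that are not
    significantly different at ``alpha`` with a shared letter.

    Returns ``{"H", "p", "letters", "pairwise"}``.  Constant input is
    reported as ``p = 1`` with a single shared letter.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    group_names = list(pd.unique(labels))
    by_group = {g: values[labels == g] for g in group_names}
    if len(group_names) < 2 or any(len(v) < 2 for v in by_group.values()):
        raise ValueError("need >= 2 groups with >= 2 members each")
    if np.all(values == values[0]):
        return {
            "H": 0.0,
            "p": 1.0,
            "letters": {g: "a" for g in group_names},
            "pairwise": pd.DataFrame(columns=["group1", "group2", "p_raw", "p_adj"]),
        }
    H, p = stats.kruskal(*[by_group[g] for g in group_names])

    pairs = list(itertools.combinations(group_names, 2))
    raw = []
    for a, b in pairs:
        if np.all(by_group[a] == by_group[a][0]) and np.all(
            by_group[b] == by_group[b][0]
        ) and by_group[a][0] == by_group[b][0]:
            raw.append(1.0)
        else:
            raw.append(stats.mannwhitneyu(by_group[a], by_group[b], alternative="two-sided")[1])
    adj = multipletests(raw, method="fdr_bh")[1] if pairs else np.array([])
    significant = {
        frozenset(pair) for pair, q in zip(pairs, adj) if q < alpha
    }
    letters = _compact_letters(group_names, significant)
    pairwise = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "p_raw": raw,
            "p_adj": adj,
        }
    )
    return {"H": float(H), "p": float(p), "letters": letters, "pairwise": pairwise}
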