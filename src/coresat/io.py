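"""Readers, writers, run configuration and end-to-end orchestration.

File conventions (all plain text):

* count tables — TSV with taxa as rows and samples as columns, or
  BIOM-style JSON (v1.0 layout, sparse or dense matrix data);
* sample metadata — CSV: sample_id, depth, date (ISO-8601), period;
* qPCR totals — CSV: sample_id, copies_per_ml;
* environment — CSV: sample_id, depth, date, period, variables;
* temperature profiles — CSV: visit_id, depth_m, temperature_C;
* distance matrices — square TSV; ordinations — CSV with the stress in
  a header comment; networks — edge-list TSV and GraphML.

``run_pipeline`` executes the whole analysis per depth layer and writes
a machine-readable manifest (thresholds, seed, package versions and a
config hash) alongside the artefacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import beta as beta_mod
from . import hydrology
from . import networks as net_mod
from . import nutrient_function as nf
from . import stability as stab_mod
from .community import (
    CommunityTable,
    absolute_abundance,
    filter_low_count_taxa,
    occupancy_sets,
    partition_taxa,
    rarefy,
)
from .synthetic import ScenarioConfig, SyntheticDataset, generate_scenario, profiles_by_visit

log = logging.getLogger("coresat")

NUTRIENTS = list(nf.MNC_VARIABLES)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_community_tsv(table: CommunityTable, counts_path, meta_path=None) -> None:
    """Write counts as taxa rows x sample columns TSV (+ metadata CSV)."""
    for name in list(table.counts.index) + list(table.counts.columns):
        if any(c in str(name) for c in "\t\n\r"):
            raise ValueError(f"id {name!r} contains TSV delimiter characters")
    table.counts.T.rename_axis("taxon_id").to_csv(counts_path, sep="\t")
    if meta_path is not None:
        table.sample_meta.rename_axis("sample_id").to_csv(meta_path)


def write_community_biom(table: CommunityTable, path) -> None:
    """Write counts in the BIOM v1.0 JSON layout (sparse)."""
    counts = table.counts.T  # observations (taxa) x samples
    data = [
        [int(i), int(j), int(v)]
        for (i, j), v in np.ndenumerate(counts.to_numpy())
        if v != 0
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "coresat",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [counts.shape[0], counts.shape[1]],
        "rows": [{"id": str(t), "metadata": None} for t in counts.index],
        "columns": [{"id": str(s), "metadata": None} for s in counts.columns],
        "data": data,
    }
    Path(path).write_text(json.dumps(doc))


def read_community(path, format: str = "tsv", meta_path=None) -> CommunityTable:
    """Read a count table from TSV or BIOM-style JSON.

    Validation errors name the first offending cell.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.T  # back to samples x taxa
    elif format == "biom-json":
        doc = json.loads(Path(path).read_text())
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat = np.asarray(doc["data"], dtype=float)
        counts = pd.DataFrame(mat.T, index=samples, columns=taxa)
    else:
        raise ValueError(f"unknown community table format: {format!r}")
    arr = counts.to_numpy()
    if not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(
            f"non-finite count at sample {counts.index[i]!r}, taxon {counts.columns[j]!r}"
        )
    if np.any(arr != np.round(arr)):
        i, j = np.argwhere(arr != np.round(arr))[0]
        raise ValueError(
            f"non-integer count at sample {counts.index[i]!r}, taxon {counts.columns[j]!r}"
        )
    counts = counts.astype(np.int64)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col="sample_id")
        if "date" in meta.columns:
            meta["date"] = pd.to_datetime(meta["date"])
    return CommunityTable(counts, meta)


def read_qpcr(path) -> pd.Series:
    df = pd.read_csv(path)
    if not {"sample_id", "copies_per_ml"} <= set(df.columns):
        raise ValueError("qPCR CSV needs columns sample_id, copies_per_ml")
    s = df.set_index("sample_id")["copies_per_ml"].astype(float)
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in qPCR table")
    return s


def read_environment(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"visit_id", "depth_m", "temperature_C"}
    if not need <= set(df.columns):
        raise ValueError(f"profile CSV needs columns {sorted(need)}")
    return df


def write_distance_matrix(dm: beta_mod.DistanceMatrix, path) -> None:
    dm.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def read_distance_matrix(path) -> beta_mod.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return beta_mod.DistanceMatrix(df.to_numpy(), tuple(df.index))


def write_ordination(result: beta_mod.OrdinationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stress = {result.stress:.6f}\n")
        result.coordinates.rename_axis("sample_id").to_csv(fh)


def write_network(net: net_mod.CooccurrenceNetwork, edge_path, graphml_path=None) -> None:
    rows = [
        {"node1": a, "node2": b, "rho": d["rho"], "p_adj": d["p_adj"]}
        for a, b, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "rho", "p_adj"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write a synthetic dataset to disk; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for depth, table in dataset.community.items():
        counts = out / f"counts_{depth}.tsv"
        meta = out / f"samples_{depth}.csv"
        write_community_tsv(table, counts, meta)
        files[f"counts_{depth}"] = str(counts)
        files[f"samples_{depth}"] = str(meta)
    qpcr = out / "qpcr.csv"
    dataset.qpcr.rename_axis("sample_id").to_csv(qpcr)
    files["qpcr"] = str(qpcr)
    env = out / "environment.csv"
    dataset.environment.rename_axis("sample_id").to_csv(env)
    files["environment"] = str(env)
    prof = out / "profiles.csv"
    dataset.profiles.to_csv(prof, index=False)
    files["profiles"] = str(prof)
    return files


def read_dataset(in_dir, depths=("surface", "bottom")) -> SyntheticDataset:
    """Read a dataset previously written with :func:`write_dataset`."""
    d = Path(in_dir)
    community = {}
    for depth in depths:
        community[depth] = read_community(
            d / f"counts_{depth}.tsv", "tsv", d / f"samples_{depth}.csv"
        )
    return SyntheticDataset(
        community=community,
        qpcr=read_qpcr(d / "qpcr.csv"),
        environment=read_environment(d / "environment.csv"),
        profiles=read_profiles(d / "profiles.csv"),
        truth={},
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Thresholds and paths for one full analysis run.

    Defaults are the study's: core occupancy 0.75, satellite 0.50,
    abundant 1%, rare 0.01%, network |rho| 0.8 with FDR 0.01 and node
    abundance filter 0.05%, 5-sample windows, thermocline 0.2 degC/m.
    """

    input_dir: str | None = None  # None -> simulate with the default scenario
    output_dir: str = "results"
    depths: tuple = ("surface", "bottom")
    core_min: float = 0.75
    satellite_max: float = 0.50
    abundant_thr: float = 0.01
    rare_thr: float = 0.0001
    rho_threshold: float = 0.8
    fdr_threshold: float = 0.01
    node_min_rel_abund: float = 0.0005
    window: int = 5
    thermocline_gradient: float = 0.2
    min_taxon_total: int = 10
    anosim_permutations: int = 999
    n_boot: int = 199
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.satellite_max <= self.core_min <= 1:
            raise ValueError("need 0 < satellite_max <= core_min <= 1")
        if not 0 <= self.rare_thr < self.abundant_thr <= 1:
            raise ValueError("need 0 <= rare_thr < abundant_thr <= 1")
        if not 0 < self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in (0, 1]")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.thermocline_gradient < 0:
            raise ValueError("thermocline_gradient must be non-negative")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def matrix_concordance(
    dm1: beta_mod.DistanceMatrix, dm2: beta_mod.DistanceMatrix
) -> dict:
    """Pearson and Spearman correlation of two distance matrices.

    The matrices must cover the same samples (in any order); the
    correlation runs over the n(n-1)/2 paired off-diagonal entries.
    Used e.g. to check that two taxon-calling strategies give concordant
    beta diversity.
    """
    if set(dm1.ids) != set(dm2.ids):
        raise ValueError("distance matrices cover different sample sets")
    order = list(dm1.ids)
    f2 = dm2.to_frame().loc[order, order]
    a = dm1.condensed()
    b = beta_mod.DistanceMatrix(f2.to_numpy(), tuple(order)).condensed()
    pr, pp = stats.pearsonr(a, b)
    sr, sp = stats.spearmanr(a, b)
    return {
        "pearson_r": float(pr),
        "pearson_p": float(pp),
        "spearman_r": float(sr),
        "spearman_p": float(sp),
    }


def _periods_from_profiles(profiles: pd.DataFrame, gradient: float) -> np.ndarray:
    by_visit = profiles_by_visit(profiles)
    presence = [
        hydrology.thermocline_depth(by_visit[v], gradient) is not None
        for v in sorted(by_visit)
    ]
    return np.asarray(hydrology.label_periods(presence))


def _stage(name, t0):
    log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all artefacts under output_dir.

    Returns the manifest (also written as ``manifest.json``).  Any stage
    failure aborts with the stage name and cause.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_dir is None:
        dataset = generate_scenario(ScenarioConfig(seed=config.seed))
    else:
        dataset = read_dataset(config.input_dir, config.depths)

    artefacts: list[str] = []

    def save(name: str):
        artefacts.append(name)
        return out / name

    summary: dict = {}
    stage = "setup"
    try:
        stage = "periods"
        t0 = time.perf_counter()
        periods = _periods_from_profiles(dataset.profiles, config.thermocline_gradient)
        _stage(stage, t0)

        for depth in config.depths:
            dsum: dict = {}
            stage = f"{depth}:prepare"
            t0 = time.perf_counter()
            raw = dataset.community[depth]
            period_by_sample = pd.Series(periods[: len(raw.samples)], index=raw.samples)
            table = filter_low_count_taxa(raw, config.min_taxon_total)
            table = rarefy(table, seed=_stage_seed(config.seed, f"rarefy-{depth}"))
            table.sample_meta["period"] = period_by_sample.reindex(table.samples)
            _stage(stage, t0)

            stage = f"{depth}:partition"
            t0 = time.perf_counter()
            partition = partition_taxa(
                table,
                config.core_min,
                config.satellite_max,
                config.abundant_thr,
                config.rare_thr,
            )
            partition.rename_axis("taxon_id").to_csv(save(f"partition_{depth}.csv"))
            groups = occupancy_sets(partition)
            _stage(stage, t0)

            stage = f"{depth}:absolute"
            t0 = time.perf_counter()
            abs_ab = absolute_abundance(table, dataset.qpcr, partition)
            abs_ab["group_sums"].rename_axis("sample_id").to_csv(
                save(f"absolute_abundance_{depth}.csv")
            )
            _stage(stage, t0)

            stage = f"{depth}:stability"
            t0 = time.perf_counter()
            stab_frames = []
            stab_by_sub = {}
            for sub in ("entire", "core", "satellite"):
                s = stab_mod.stability_series(
                    abs_ab["group_sums"][sub].to_numpy(),
                    table.sample_meta["period"].to_numpy(),
                    config.window,
                    subcommunity=sub,
                )
                s.insert(0, "depth", depth)
                stab_frames.append(s)
                stab_by_sub[sub] = s
            pd.concat(stab_frames).to_csv(save(f"stability_{depth}.csv"), index=False)
            dsum["stability_relation"] = {
                sub: stab_mod.stability_relation(stab_by_sub[sub], stab_by_sub["entire"])
                for sub in ("core", "satellite")
            }
            _stage(stage, t0)

            for sub in ("core", "satellite"):
                subtable = table.subset_taxa(groups[sub])
                per = subtable.sample_meta["period"].to_numpy()

                stage = f"{depth}:{sub}:beta"
                t0 = time.perf_counter()
                dm = beta_mod.bray_curtis(subtable)
                write_distance_matrix(dm, save(f"braycurtis_{depth}_{sub}.tsv"))
                ord_res = beta_mod.nmds(
                    dm, seed=_stage_seed(config.seed, f"nmds-{depth}-{sub}")
                )
                if sub == "core":
                    core_ord = ord_res
                write_ordination(ord_res, save(f"nmds_{depth}_{sub}.csv"))
                anosim_res = beta_mod.anosim(
                    dm,
                    per,
                    n_perm=config.anosim_permutations,
                    seed=_stage_seed(config.seed, f"anosim-{depth}-{sub}"),
                )
                simper_res = beta_mod.simper(subtable, per)
                simper_top = {
                    f"{a}|{b}": df.head(20) for (a, b), df in simper_res.items()
                }
                tl = beta_mod.time_lag(dm, subtable.sample_meta["date"])
                ppd = beta_mod.period_pair_dissimilarity(dm, per)
                dsum.setdefault(sub, {})["beta"] = {
                    "nmds_stress": ord_res.stress,
                    "anosim": anosim_res,
                    "time_lag": {k: tl[k] for k in ("slope", "intercept", "r", "p")},
                    "period_pair_medians": {
                        k: float(np.median(v)) if len(v) else None
                        for k, v in ppd["bins"].items()
                    },
                    "period_pair_letters": ppd["test"]["letters"],
                    "simper_top": {
                        k: v["average_contribution_pct"].head(5).to_dict()
                        for k, v in simper_top.items()
                    },
                }
                _stage(stage, t0)

                stage = f"{depth}:{sub}:network"
                t0 = time.perf_counter()
                nodes = net_mod.network_node_filter(
                    subtable, per, config.node_min_rel_abund
                )
                metrics = None
                if len(nodes) >= 3:
                    nettab = subtable.subset_taxa(nodes)
                    net = net_mod.build_network(
                        nettab, config.rho_threshold, config.fdr_threshold
                    )
                    write_network(
                        net,
                        save(f"network_{depth}_{sub}.tsv"),
                        out / f"network_{depth}_{sub}.graphml",
                    )
                    artefacts.append(f"network_{depth}_{sub}.graphml")
                    metrics = net_mod.subnetwork_metrics(net, nettab)
                    metrics.rename_axis("sample_id").to_csv(
                        save(f"subnetwork_metrics_{depth}_{sub}.csv")
                    )
                    cmp_res = net_mod.compare_metrics_by_period(metrics, per)
                    dsum[sub]["network"] = {
                        "n_nodes": net.graph.number_of_nodes(),
                        "n_edges": net.graph.number_of_edges(),
                        "metric_letters": {
                            m: (r["letters"] if r else None) for m, r in cmp_res.items()
                        },
                    }
                else:
                    dsum[sub]["network"] = {"n_nodes": len(nodes), "n_edges": 0}
                if sub == "core":
                    core_metrics = metrics
                _stage(stage, t0)

            stage = f"{depth}:mnc"
            t0 = time.perf_counter()
            env = dataset.environment
            env_d = env.loc[env["depth"] == depth].loc[table.samples]
            mnc = nf.mnc_index(env_d)
            mnc.rename_axis("sample_id").to_csv(save(f"mnc_{depth}.csv"))
            _stage(stage, t0)

            stage = f"{depth}:plspm"
            t0 = time.perf_counter()
            dsum["plspm"] = _plspm_stage(
                config, depth, env_d, mnc, core_ord, core_metrics, out, save
            )
            _stage(stage, t0)

            summary[depth] = dsum
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    import coresat

    manifest = {
        "package_version": getattr(coresat, "__version__", "unknown"),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "artefacts": sorted(set(artefacts)),
        "summary": _jsonable(summary),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _plspm_stage(config, depth, env_d, mnc, ord_res, core_metrics, out, save):
    """Collinearity filtering, block construction and the PLS-PM fit."""
    phys_cols = nf.collinearity_filter(
        env_d[["DO", "pH"]], nf.COLLINEARITY_SQ_RHO_ENV
    )
    nutr_cols = nf.collinearity_filter(
        env_d[NUTRIENTS], nf.COLLINEARITY_SQ_RHO_ENV
    )
    data = env_d[["WT", "Chla"] + phys_cols + nutr_cols].copy()
    data["MNC"] = mnc
    # last fitted core-community ordination for this depth
    data["NMDS1"] = ord_res.coordinates["NMDS1"].reindex(data.index)
    data["NMDS2"] = ord_res.coordinates["NMDS2"].reindex(data.index)
    blocks = {
        "WT": ["WT"],
        "Phys": phys_cols,
        "Nutr": nutr_cols,
        "Chla": ["Chla"],
        "NMDS1": ["NMDS1"],
        "NMDS2": ["NMDS2"],
    }
    community_lvs = ["NMDS1", "NMDS2"]
    if core_metrics is not None:
        net_cols = [
            c for c in core_metrics.columns if np.isfinite(core_metrics[c]).all()
        ]
        net_cols = [c for c in net_cols if core_metrics[c].std() > 0]
        if net_cols:
            net_cols = nf.collinearity_filter(
                core_metrics[net_cols], nf.COLLINEARITY_SQ_RHO_NET
            )
            for c in net_cols:
                data[f"net_{c}"] = core_metrics[c].reindex(data.index)
            blocks["Net"] = [f"net_{c}" for c in net_cols]
            community_lvs.append("Net")
    inner = nf.reservoir_inner_matrix(
        ["WT", "Phys", "Nutr", "Chla"], community_lvs, "MNC"
    )
    blocks["MNC"] = ["MNC"]
    blocks = {lv: blocks[lv] for lv in inner.index}
    try:
        model = nf.fit_plspm(data, blocks, inner)
        pruned = model.pruned
    except (ValueError, nf.ConvergenceError):
        model = nf.fit_plspm(data, blocks, inner, prune_threshold=None)
        pruned = ["<pruning skipped: would empty a block>"]
    boot = nf.bootstrap_paths(
        data,
        model.blocks,
        inner,
        n_boot=config.n_boot,
        seed=_stage_seed(config.seed, f"plspm-{depth}"),
    )
    boot.to_csv(save(f"plspm_paths_{depth}.csv"), index=False)
    model.loadings.rename_axis("indicator").rename("loading").to_csv(
        save(f"plspm_loadings_{depth}.csv")
    )
    return {
        "gof": model.gof,
        "r2": model.r2.to_dict(),
        "pruned": pruned,
        "significant_paths_p_lt_0.1": [
            f"{r.source}->{r.target}" for r in boot.itertuples() if r.p < 0.1
        ],
    }
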