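"""End-to-end orchestration of the analysis stages.

Stage order mirrors the analysis: simulate (optional) -> filter ->
diversity -> network -> stability -> trends -> funcnet. Every stage
derives its own sub-seed from the global seed by stable hashing, writes
TSV outputs under the output directory, and the run ends with a
manifest recording version, config hash and seed (no timestamps, so
identical runs are byte-identical).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity import alpha_diversity, bray_curtis_matrix, compare_groups, dissimilarity_test
from .errors import AnalysisError, ConfigurationError, MenkitError
from .funcnet import build_pathway_network, cluster_overlap, mcode_clusters
from .modules import detect_modules, keystones, module_size_summary, relative_modularity, zi_pi_roles
from .rmt import build_network, pearson_matrix, scan_threshold
from .stability import global_efficiency, robustness, vulnerability
from .synthetic import SyntheticConfig, generate_counts, generate_pathway_table
from .table_io import (
    FeatureTable,
    filter_low_abundance,
    log_transform,
    prevalence_filter,
    rarefy,
    read_feature_table,
    write_feature_table,
)
from .topology import null_ensemble, scale_free_fit, topology_indices
from .trends import correlate_parameters, log_fc, regress_vs_time

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "diversity", "network", "stability", "trends", "funcnet")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "output_dir": "results",
    "input": {"table": None, "metadata": None},
    "simulate": {
        "enabled": True,
        "n_asv": 200,
        "n_blocks": 8,
        "block_size": 10,
        "rho_within": 0.9,
        "months": list(range(1, 15)),
        "samples_per_group_month": 8,
        "depth": 20000,
        "effect_richness": 0.3,
        "effect_dominance": 2.0,
        "effect_network": 0.3,
        "recovery_halflife": 3.0,
        "pathways": {"n_pathways": 60, "n_samples": 40, "planted_clique_size": 8, "rho": 0.95},
    },
    "filter": {"min_total": 10, "min_samples": 3, "rarefy_depth": None},
    "diversity": {"n_perm": 999, "alpha_level": 0.05},
    "network": {
        "threshold_method": "fixed",  # "fixed" or "rmt"
        "fixed_threshold": 0.8,
        "prevalence_min_fraction": 0.5,
        "log_base": 10,
        "pseudocount": 1,
        "rmt": {"s_min": 0.3, "s_max": 0.99, "step": 0.01, "alpha": 0.001, "min_eigs": 100},
        "null_ensemble": {"n_random": 20, "n_swaps_per_edge": 10},
        "zi_cut": 2.5,
        "pi_cut": 0.62,
    },
    "stability": {"fraction": 0.5, "n_reps": 100},
    "trends": {"method": "spearman", "logfc_base": 2, "alpha_level": 0.05},
    "funcnet": {
        "pathway_tables": None,  # mapping group -> TSV path; simulated otherwise
        "r_cut": 0.8,
        "p_cut": 0.05,
        "mcode": {"degree_cutoff": 2, "k_core": 2, "node_score_cutoff": 0.2, "max_depth": 100},
        "top_n": 3,
    },
}

_FLOAT_FORMAT = "%.10g"


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults, an optional YAML file, and in-memory overrides."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError("config file must contain a mapping")
        config = _merge(config, user)
    if overrides:
        config = _merge(config, overrides)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if not config["simulate"]["enabled"]:
        table = config["input"]["table"]
        meta = config["input"]["metadata"]
        if not table or not meta:
            raise ConfigurationError(
                "input.table and input.metadata are required when simulate is disabled"
            )
        for p in (table, meta):
            if not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")
    method = config["network"]["threshold_method"]
    if method not in ("fixed", "rmt"):
        raise ConfigurationError(f"unknown threshold_method {method!r}")


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def config_hash(config: dict) -> str:
    """Hash of the analysis-relevant config (output location excluded)."""
    payload = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT, na_rep="NA")


class Pipeline:
    """Runs stages against a shared output directory."""

    def __init__(self, config: dict, output_dir=None):
        validate_config(config)
        self.config = config
        self.outdir = Path(output_dir or config["output_dir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config["seed"])

    # -- helpers -------------------------------------------------------
    def _load_table(self) -> FeatureTable:
        filtered = self.outdir / "filtered_counts.tsv"
        meta = self.outdir / "metadata.tsv"
        if filtered.exists():
            return read_feature_table(filtered, meta)
        if self.config["simulate"]["enabled"]:
            table_path = self.outdir / "counts.tsv"
            if not table_path.exists():
                raise AnalysisError("run the simulate stage first")
            return read_feature_table(table_path, meta)
        return read_feature_table(
            self.config["input"]["table"], self.config["input"]["metadata"]
        )

    def _groups_months(self, table: FeatureTable):
        meta = table.metadata
        groups = sorted(meta["group"].unique())
        months = sorted(meta["month"].unique())
        return groups, months

    # -- stages --------------------------------------------------------
    def run_simulate(self) -> None:
        cfg = self.config["simulate"]
        if not cfg["enabled"]:
            logger.info("simulate disabled; skipping")
            return
        sim_seed = stage_seed(self.seed, "simulate")
        params = {
            k: v for k, v in cfg.items() if k not in ("enabled", "pathways")
        }
        params["months"] = tuple(params.get("months", range(1, 15)))
        sconf = SyntheticConfig(seed=sim_seed, **params)
        table, truth = generate_counts(sconf)
        write_feature_table(table, self.outdir / "counts.tsv", self.outdir / "metadata.tsv")
        truth.to_json(self.outdir / "truth.json")
        pw = cfg["pathways"]
        for i, group in enumerate(sconf.groups):
            ptable = generate_pathway_table(
                pw["n_pathways"], pw["n_samples"], pw["planted_clique_size"],
                pw["rho"], seed=stage_seed(self.seed, f"pathways:{group}"),
            )
            ptable.index.name = "pathway"
            _write_tsv(ptable, self.outdir / f"pathways_{group}.tsv")

    def run_filter(self) -> None:
        cfg = self.config["filter"]
        if self.config["simulate"]["enabled"]:
            table = read_feature_table(self.outdir / "counts.tsv", self.outdir / "metadata.tsv")
        else:
            table = read_feature_table(
                self.config["input"]["table"], self.config["input"]["metadata"]
            )
            write_feature_table(table, self.outdir / "counts.tsv", self.outdir / "metadata.tsv")
        table = filter_low_abundance(table, cfg["min_total"], cfg["min_samples"])
        if cfg["rarefy_depth"]:
            table = rarefy(table, cfg["rarefy_depth"], seed=stage_seed(self.seed, "rarefy"))
        write_feature_table(table, self.outdir / "filtered_counts.tsv", self.outdir / "metadata.tsv")

    def run_diversity(self) -> None:
        cfg = self.config["diversity"]
        table = self._load_table()
        groups, months = self._groups_months(table)
        alpha = alpha_diversity(table)
        alpha.index.name = "sample_id"
        _write_tsv(alpha, self.outdir / "alpha_diversity.tsv")
        seed = stage_seed(self.seed, "diversity")
        test_rows, alpha_rows = [], []
        for month in months:
            sub = table.subset(month=month)
            labels = sub.metadata["group"].to_numpy()
            if len(set(labels)) < 2:
                continue
            dist = bray_curtis_matrix(sub)
            for method in ("anosim", "adonis", "mrpp"):
                res = dissimilarity_test(
                    dist, labels, method=method, n_perm=cfg["n_perm"],
                    seed=seed + month,
                )
                test_rows.append({
                    "month": month, "method": method, "statistic": res.statistic,
                    "p_value": res.p_value, "n_permutations": res.n_permutations,
                    "seed": res.seed,
                })
            if len(groups) == 2:
                for index in ("chao1", "shannon", "dominance"):
                    vals = [
                        alpha.loc[list(sub.metadata.index[sub.metadata["group"] == g]), index]
                        .dropna().to_numpy()
                        for g in groups
                    ]
                    if min(len(v) for v in vals) < 3:
                        continue
                    res = compare_groups(vals[0], vals[1], alpha=cfg["alpha_level"])
                    alpha_rows.append({
                        "month": month, "index": index, "statistic": res.statistic,
                        "p_value": res.p_value, "branch": res.extra["branch"],
                    })
        _write_tsv(pd.DataFrame(test_rows), self.outdir / "dissimilarity_tests.tsv", index=False)
        if alpha_rows:
            _write_tsv(pd.DataFrame(alpha_rows), self.outdir / "alpha_tests.tsv", index=False)

    def _threshold_for(self, corr) -> tuple[float, list[dict]]:
        cfg = self.config["network"]
        if cfg["threshold_method"] == "fixed":
            return float(cfg["fixed_threshold"]), []
        scan = scan_threshold(corr, **cfg["rmt"])
        log = [
            {"threshold": r.threshold, "n_edges": r.n_edges,
             "n_eigenvalues": r.n_eigenvalues, "chi2": r.chi2, "p": r.p_value,
             "conforming": r.conforming}
            for r in scan.records
        ]
        return float(scan.chosen_threshold), log

    def run_network(self) -> None:
        cfg = self.config["network"]
        table = self._load_table()
        groups, months = self._groups_months(table)
        seed = stage_seed(self.seed, "network")
        netdir = self.outdir / "networks"
        netdir.mkdir(exist_ok=True)
        index_rows, scan_rows, node_frames = [], [], []
        for group in groups:
            for month in months:
                label = f"{group}_M{month:02d}"
                sub = table.subset(group=group, month=month)
                sub = prevalence_filter(sub, cfg["prevalence_min_fraction"])
                logab = log_transform(sub, base=cfg["log_base"], pseudocount=cfg["pseudocount"])
                variable = logab.std(axis=1) > 0
                logab = logab.loc[variable]
                row: dict = {"group": group, "month": month}
                if logab.shape[0] < 3:
                    logger.warning("network %s: too few variable ASVs", label)
                    index_rows.append(row)
                    continue
                corr = pearson_matrix(logab)
                threshold, scan_log = self._threshold_for(corr)
                for rec in scan_log:
                    scan_rows.append({"group": group, "month": month, **rec})
                men = build_network(corr, threshold, {"group": group, "month": int(month)})
                if men.number_of_edges() == 0:
                    index_rows.append({**row, "threshold": threshold, "nodes": 0, "links": 0})
                    continue
                nx.write_graphml(men, netdir / f"{label}.graphml")
                edges = pd.DataFrame(
                    [(u, v, d["weight"], d["sign"]) for u, v, d in men.edges(data=True)],
                    columns=["source", "target", "r", "sign"],
                )
                _write_tsv(edges, netdir / f"{label}_edges.tsv", index=False)
                row.update({"threshold": threshold, **topology_indices(men)})
                sf = scale_free_fit(men)
                if sf is not None:
                    row["scale_free_slope"], row["scale_free_r2"] = sf
                partition = detect_modules(men)
                row["modularity"] = partition.modularity
                row.update(module_size_summary(partition))
                roles = zi_pi_roles(men, partition, cfg["zi_cut"], cfg["pi_cut"])
                row["n_keystones"] = len(keystones(roles))
                if men.number_of_edges() >= 2:
                    nulls = null_ensemble(
                        men, seed=stage_seed(seed, f"null:{label}"),
                        **cfg["null_ensemble"],
                    )
                    rm = relative_modularity(partition.modularity, nulls.modularities)
                    row["relative_modularity"] = rm
                    row["modularity_z"] = nulls.z_scores["modularity"]
                roles_out = roles.reset_index()
                roles_out.insert(0, "month", month)
                roles_out.insert(0, "group", group)
                node_frames.append(roles_out)
                index_rows.append(row)
        _write_tsv(pd.DataFrame(index_rows), self.outdir / "network_indices.tsv", index=False)
        if node_frames:
            _write_tsv(pd.concat(node_frames), self.outdir / "node_roles.tsv", index=False)
        if scan_rows:
            _write_tsv(pd.DataFrame(scan_rows), self.outdir / "rmt_scan.tsv", index=False)

    def run_stability(self) -> None:
        cfg = self.config["stability"]
        netdir = self.outdir / "networks"
        roles_path = self.outdir / "node_roles.tsv"
        if not netdir.exists():
            raise AnalysisError("run the network stage first")
        roles = (
            pd.read_csv(roles_path, sep="\t") if roles_path.exists() else pd.DataFrame()
        )
        seed = stage_seed(self.seed, "stability")
        rows = []
        for path in sorted(netdir.glob("*.graphml")):
            men = nx.read_graphml(path)
            group = men.graph.get("group")
            month = int(men.graph.get("month"))
            hubs = []
            if not roles.empty:
                mask = (
                    (roles["group"] == group)
                    & (roles["month"] == month)
                    & roles["role"].isin(["module_hub", "network_hub"])
                )
                hubs = roles.loc[mask, "node"].tolist()
            rand = robustness(
                men, "random", fraction=cfg["fraction"], n_reps=cfg["n_reps"],
                seed=stage_seed(seed, f"robustness:{group}:{month}"),
            )
            targ = robustness(men, "targeted", module_hubs=hubs)
            vuln = vulnerability(men) if men.number_of_nodes() >= 3 else None
            rows.append({
                "group": group, "month": month,
                "robustness_random_mean": rand.mean,
                "robustness_random_sd": rand.sd,
                "robustness_targeted": targ.mean,
                "vulnerability": vuln,
                "global_efficiency": global_efficiency(men),
                "n_reps": cfg["n_reps"], "seed": seed,
            })
        frame = pd.DataFrame(rows).sort_values(["group", "month"])
        _write_tsv(frame, self.outdir / "stability.tsv", index=False)

    def run_trends(self) -> None:
        cfg = self.config["trends"]
        indices = pd.read_csv(self.outdir / "network_indices.tsv", sep="\t", na_values="NA")
        stab_path = self.outdir / "stability.tsv"
        if stab_path.exists():
            stab = pd.read_csv(stab_path, sep="\t", na_values="NA")
            indices = indices.merge(stab, on=["group", "month"], how="left", suffixes=("", "_stab"))
        params = [
            c for c in indices.columns
            if c not in ("group", "month", "seed", "n_reps")
            and pd.api.types.is_numeric_dtype(indices[c])
        ]
        groups = sorted(indices["group"].dropna().unique())
        reg_rows, logfc_frames = [], []
        for group in groups:
            gdf = indices[indices["group"] == group].set_index("month")
            for param in params:
                series = gdf[param].dropna()
                if len(series) < 3 or series.nunique() < 2:
                    continue
                fit = regress_vs_time(series)
                reg_rows.append({
                    "group": group, "parameter": param, "slope": fit.slope,
                    "intercept": fit.intercept, "r_squared": fit.r_squared,
                    "p_value": fit.p_value, "n": fit.n,
                })
        _write_tsv(pd.DataFrame(reg_rows), self.outdir / "regressions.tsv", index=False)
        if len(groups) == 2:
            a, c = groups[0], groups[1]
            adf = indices[indices["group"] == a].set_index("month")
            cdf = indices[indices["group"] == c].set_index("month")
            rows = []
            for param in params:
                try:
                    fc = log_fc(adf[param], cdf[param], base=cfg["logfc_base"])
                except AnalysisError:
                    continue
                for month, value in fc.items():
                    rows.append({"parameter": param, "month": month, "log_fc": value})
            _write_tsv(pd.DataFrame(rows), self.outdir / "logfc.tsv", index=False)
        complexity = [
            p for p in ("nodes", "links", "avg_degree", "avg_clustering",
                        "connectedness", "geodesic", "positive_links",
                        "relative_modularity", "nodes_in_large_modules", "n_keystones")
            if p in indices.columns
        ]
        stability_cols = [
            p for p in ("robustness_random_mean", "robustness_targeted", "vulnerability")
            if p in indices.columns
        ]
        corr_frames = []
        for group in groups:
            gdf = indices[indices["group"] == group].set_index("month")
            if not complexity or not stability_cols:
                continue
            cells = correlate_parameters(
                gdf[complexity], gdf[stability_cols], method=cfg["method"],
                alpha=cfg["alpha_level"],
            )
            cells.insert(0, "group", group)
            corr_frames.append(cells)
        if corr_frames:
            _write_tsv(
                pd.concat(corr_frames), self.outdir / "complexity_stability.tsv", index=False
            )

    def run_funcnet(self) -> None:
        cfg = self.config["funcnet"]
        tables: dict[str, pd.DataFrame] = {}
        if cfg["pathway_tables"]:
            for group, path in cfg["pathway_tables"].items():
                tables[group] = pd.read_csv(path, sep="\t", index_col=0)
        else:
            for path in sorted(self.outdir.glob("pathways_*.tsv")):
                group = path.stem.split("_", 1)[1]
                tables[group] = pd.read_csv(path, sep="\t", index_col=0)
        if not tables:
            raise AnalysisError("no pathway tables available for funcnet stage")
        cluster_rows = []
        clusters_by_group = {}
        for group, ptable in tables.items():
            net = build_pathway_network(ptable, cfg["r_cut"], cfg["p_cut"])
            nx.write_graphml(net, self.outdir / f"funcnet_{group}.graphml")
            clusters = mcode_clusters(net, **cfg["mcode"])
            clusters_by_group[group] = clusters
            for cl in clusters:
                cluster_rows.append({
                    "group": group, "rank": cl.rank, "score": cl.score,
                    "size": len(cl.members), "density": cl.density,
                    "members": ",".join(map(str, cl.members)),
                })
        _write_tsv(pd.DataFrame(cluster_rows), self.outdir / "funcnet_clusters.tsv", index=False)
        groups = sorted(clusters_by_group)
        if len(groups) == 2:
            overlap = cluster_overlap(
                clusters_by_group[groups[0]], clusters_by_group[groups[1]],
                top_n=cfg["top_n"],
            )
            frame = pd.DataFrame(
                overlap,
                index=[f"{groups[0]}_cluster{i + 1}" for i in range(overlap.shape[0])],
                columns=[f"{groups[1]}_cluster{j + 1}" for j in range(overlap.shape[1])],
            )
            _write_tsv(frame, self.outdir / "funcnet_overlap.tsv")

    # -- driver --------------------------------------------------------
    def run(self, stages=None) -> Path:
        stages = list(stages or STAGES)
        for stage in stages:
            if stage not in STAGES:
                raise ConfigurationError(f"unknown stage {stage!r}")
        for stage in STAGES:
            if stage not in stages:
                continue
            logger.info("stage %s", stage)
            try:
                getattr(self, f"run_{stage}")()
            except MenkitError as exc:
                logger.error("stage %s failed: %s", stage, exc)
                raise

        manifest = {
            "version": __version__,
            "config_sha256": config_hash(self.config),
            "seed": self.seed,
            "stages": [s for s in STAGES if s in stages],
        }
        with open(self.outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return self.outdir


def run_pipeline(config: dict, stages=None, output_dir=None) -> Path:
    """Convenience wrapper used by the CLI and tests."""
    return Pipeline(config, output_dir=output_dir).run(stages)
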