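"""Configuration-driven orchestration of the full analysis.

transforms -> phylogenetic correlations -> signal (K, lambda) -> pPCA ->
PGLS of every trait against the focal trait -> thresholded networks with
and without the focal trait -> paired comparison.  Every stage writes a
file under the output directory, and a run is fully determined by the
config plus inputs (fixed seed), so repeated runs are byte-identical.
"""

from __future__ import annotations

import io
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import (PGLSRegression, TraitCorrelations, blomberg_k,
                          evolutionary_rate_matrix, pagel_lambda, phylo_pca)
from .network import (NetworkComparison, compare_networks, build_network,
                      exclude_trait, network_summary, paired_t_test,
                      round_half_up)
from .traits import (DEFAULT_TRANSFORMS, TraitTable, align_tree_and_traits,
                     transform_traits)
from .tree import PhyloTree, parse_newick

__all__ = ["AnalysisConfig", "ReportBundle", "run_full_analysis",
           "run_network_stage", "load_correlations_csv",
           "transform_traits", "align_tree_and_traits"]

logger = logging.getLogger("rhizonet")


@dataclass
class AnalysisConfig:
    """Everything a full run needs; every field has a reproducible default."""

    tree_path: str | None = None
    traits_path: str | None = None
    out_dir: str = "rhizonet_out"
    transforms: dict = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))
    focal: str = "colM"
    threshold: float = 0.5
    alpha: float = 0.05
    n_perm: int = 999
    seed: int | None = None
    ppca_mode: str = "correlation"
    pgls_lambda: float | str = 1.0
    report_decimals: int = 1
    normalize_labels: bool = False

    def __post_init__(self):
        if not 0 <= self.threshold < 1:
            raise ValueError("threshold must be in [0, 1)")
        if self.focal not in self.transforms:
            raise ValueError(f"focal trait {self.focal!r} missing from the "
                             "transform map")
        if self.n_perm > 0 and self.seed is None:
            raise ValueError("a seed is required when permutations are requested")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class ReportBundle:
    """In-memory results of one full run plus the files written."""

    correlations: TraitCorrelations
    signal: pd.DataFrame
    ppca: object
    pgls: pd.DataFrame
    comparison: NetworkComparison
    files: dict


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               allow_nan=True) + "\n")


def _summary_dict(summary) -> dict:
    d = summary.whole_network_dict()
    d["per_trait"] = {
        t: {"degree": int(summary.degree[i]),
            "weighted_degree": float(summary.weighted_degree[i]),
            "betweenness": float(summary.betweenness[i])}
        for i, t in enumerate(summary.names)}
    d["hub_traits"] = list(summary.hub_traits)
    return d


def _table3_frame(sum_with, sum_without, focal: str, decimals: int) -> pd.DataFrame:
    """Report table shaped like the published network-parameter table."""
    rows = []
    rnd = lambda v: round_half_up(float(v), decimals)
    for label, s in (("included", sum_with), ("excluded", sum_without)):
        per = {t: {"degree": int(s.degree[i]),
                   "weighted_degree": rnd(s.weighted_degree[i]),
                   "betweenness": rnd(s.betweenness[i])}
               for i, t in enumerate(s.names)}
        for metric in ("degree", "weighted_degree", "betweenness"):
            row = {"parameter": metric, "focal": label}
            for t in sum_with.names:
                row[t] = per.get(t, {}).get(metric, np.nan)
            rows.append(row)
        rows.append({"parameter": "average_path_length", "focal": label,
                     "value": rnd(s.average_path_length)})
        rows.append({"parameter": "edge_density", "focal": label,
                     "value": rnd(s.edge_density)})
        rows.append({"parameter": "clustering", "focal": label,
                     "value": rnd(s.clustering)})
        rows.append({"parameter": "connectance", "focal": label,
                     "value": rnd(s.connectance)})
    return pd.DataFrame(rows)


def run_network_stage(corr: TraitCorrelations, focal: str, out_dir,
                      threshold: float = 0.5, alpha: float = 0.05,
                      report_decimals: int = 1) -> NetworkComparison:
    """Correlations -> two networks -> metrics, comparison and exports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("network: building networks (threshold=%s, alpha=%s, focal=%s)",
                threshold, alpha, focal)
    comparison = compare_networks(corr, focal, threshold=threshold, alpha=alpha)
    net_with = build_network(corr, threshold=threshold, alpha=alpha)
    net_without = build_network(exclude_trait(corr, focal),
                                threshold=threshold, alpha=alpha)
    for tag, net, summary in (("with", net_with, comparison.with_focal),
                              ("without", net_without, comparison.without_focal)):
        net.edge_frame().to_csv(out / f"edges_{tag}_{focal}.csv", index=False)
        buf = io.BytesIO()
        nx.write_graphml(net.to_networkx(), buf)
        (out / f"network_{tag}_{focal}.graphml").write_bytes(buf.getvalue())
        _write_json(out / f"network_{tag}_{focal}.json", _summary_dict(summary))
    # the same comparison at report precision: per-trait metrics rounded
    # to the display convention before pairing, which is how values read
    # off a printed table behave
    rounded_tests = {}
    sw, so = comparison.with_focal, comparison.without_focal
    for metric in ("degree", "weighted_degree", "betweenness"):
        va = [round_half_up(float(getattr(sw, metric)[sw.names.index(t)]),
                            report_decimals) for t in comparison.shared]
        vb = [round_half_up(float(getattr(so, metric)[so.names.index(t)]),
                            report_decimals) for t in comparison.shared]
        d = np.asarray(va) - np.asarray(vb)
        if np.ptp(d) == 0 and d[0] != 0:
            rounded_tests[metric] = None  # degenerate at this precision
        else:
            t, df, p = paired_t_test(va, vb)
            rounded_tests[metric] = {"t": t, "df": df, "p": p}
    _write_json(out / "comparison.json", {
        "focal": focal, "shared_traits": list(comparison.shared),
        "tests": {m: {"t": t, "df": df, "p": p}
                  for m, (t, df, p) in comparison.tests.items()},
        "tests_at_report_precision": rounded_tests})
    _table3_frame(comparison.with_focal, comparison.without_focal, focal,
                  report_decimals).to_csv(out / "network_parameters.csv",
                                          index=False)
    return comparison


def load_correlations_csv(path) -> TraitCorrelations:
    """Read a tidy pairwise-correlation CSV (trait_a, trait_b, r[, significant]).

    The optional ``significant`` column (0/1) substitutes for p-values,
    as with published-table fixtures; without it, callers must attach
    p-values before network construction.
    """
    df = pd.read_csv(path)
    names = list(dict.fromkeys(df["trait_a"]).keys())
    for t in df["trait_b"]:
        if t not in names:
            names.append(t)
    p = len(names)
    r = np.eye(p)
    sig = np.zeros((p, p), dtype=bool) if "significant" in df.columns else None
    for row in df.itertuples(index=False):
        i, j = names.index(row.trait_a), names.index(row.trait_b)
        r[i, j] = r[j, i] = row.r
        if sig is not None:
            sig[i, j] = sig[j, i] = bool(row.significant)
    return TraitCorrelations(names=tuple(names), mean=np.full(p, np.nan),
                             rate=r.copy(), corr=r, pvalues=None,
                             significant=sig)


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """The whole pipeline, deterministic given the config seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    logger.info("ingest: reading tree %s and traits %s",
                config.tree_path, config.traits_path)
    if config.tree_path is None or config.traits_path is None:
        raise ValueError("tree_path and traits_path are required")
    tree = parse_newick(Path(config.tree_path).read_text())
    table = TraitTable.from_csv(config.traits_path,
                                transforms=config.transforms)
    tree, table = align_tree_and_traits(tree, table,
                                        normalize_labels=config.normalize_labels)
    if config.focal not in table.trait_names:
        raise ValueError(f"focal trait {config.focal!r} not in trait table")

    logger.info("transform: applying per-trait transforms")
    table = transform_traits(table)
    vcv = tree.vcv()

    logger.info("correlations: GLS rate matrix on %d species x %d traits",
                len(table.species), len(table.trait_names))
    corr = evolutionary_rate_matrix(table, vcv)
    corr.corr_frame().to_csv(out / "correlations.csv", index_label="trait")
    corr.pvalue_frame().to_csv(out / "correlation_pvalues.csv",
                               index_label="trait")
    files["correlations"] = out / "correlations.csv"

    logger.info("signal: Blomberg K (%d permutations) and Pagel lambda",
                config.n_perm)
    seeds = np.random.SeedSequence(config.seed).spawn(len(table.trait_names))
    sig_rows = []
    for trait, ss in zip(table.trait_names, seeds):
        x = table.data[trait].to_numpy()
        kk = blomberg_k(x, vcv, n_perm=config.n_perm,
                        seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                        trait=trait)
        ll = pagel_lambda(x, vcv, trait=trait)
        sig_rows.append({"trait": trait, "K": kk.k, "p_K": kk.p_k,
                         "lambda": ll.lam, "logL": ll.loglik,
                         "logL0": ll.loglik0, "p_lambda": ll.p_lambda})
    signal = pd.DataFrame(sig_rows)
    signal.to_csv(out / "signal.csv", index=False)
    files["signal"] = out / "signal.csv"

    logger.info("ppca: %s mode", config.ppca_mode)
    ppca = phylo_pca(table, vcv, mode=config.ppca_mode)
    head = pd.DataFrame(
        [ppca.sdev, ppca.proportion, ppca.cumulative],
        index=["standard_deviation", "proportion_of_variance",
               "cumulative_proportion"],
        columns=ppca.loadings.columns)
    pd.concat([head, ppca.loadings]).to_csv(out / "ppca.csv",
                                            index_label="quantity")
    ppca.scores.to_csv(out / "ppca_scores.csv", index_label="species")
    files["ppca"] = out / "ppca.csv"

    logger.info("pgls: each trait ~ %s (lambda=%s)", config.focal,
                config.pgls_lambda)
    xfocal = table.data[config.focal].to_numpy()
    pgls_rows = []
    for trait in table.trait_names:
        if trait == config.focal:
            continue
        res = PGLSRegression(vcv=vcv, lam=config.pgls_lambda).fit(
            xfocal, table.data[trait].to_numpy()).results()
        pgls_rows.append({
            "trait": trait, "predictor": config.focal,
            "intercept": res.intercept, "slope": res.slope,
            "se_slope": res.se_slope, "t_slope": res.t_slope,
            "p_slope": res.p_slope, "sigma2": res.sigma2,
            "lambda": res.lam, "n": res.n})
    pgls = pd.DataFrame(pgls_rows)
    pgls.to_csv(out / "pgls.csv", index=False)
    files["pgls"] = out / "pgls.csv"

    comparison = run_network_stage(corr, config.focal, out,
                                   threshold=config.threshold,
                                   alpha=config.alpha,
                                   report_decimals=config.report_decimals)
    files["comparison"] = out / "comparison.json"
    files["network_parameters"] = out / "network_parameters.csv"

    meta = {"config": _config_echo(config),
            "versions": {"rhizonet": __version__,
                         "python": platform.python_version(),
                         "numpy": np.__version__,
                         "pandas": pd.__version__,
                         "networkx": nx.__version__},
            "n_species": len(table.species),
            "n_traits": len(table.trait_names)}
    _write_json(out / "run_meta.json", meta)
    files["run_meta"] = out / "run_meta.json"

    return ReportBundle(correlations=corr, signal=signal, ppca=ppca,
                        pgls=pgls, comparison=comparison,
                        files={k: str(v) for k, v in files.items()})


def _config_echo(config: AnalysisConfig) -> dict:
    d = asdict(config)
    d["pgls_lambda"] = str(d["pgls_lambda"])
    return d
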