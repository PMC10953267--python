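"""End-to-end orchestration: ingest -> score -> residualize -> networks -> stability -> export.

A run is fully described by a :class:`RunConfig`; every stochastic stage
draws its stream from the mandatory master seed, and the run directory
contains a machine-readable manifest (config echo with every default made
explicit, package versions, input hash) sufficient to replay the run and
byte-compare its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import derive_seed
from .centrality import expected_influence, temporal_centrality_table, variance_explained_prediction
from .clpn import CrossLaggedPanelNetwork, filter_edges
from .errors import ConfigurationError
from .ggm import GaussianGraphicalModel, average_edges
from .panel_io import (DEFAULT_COVARIATES, descriptives, drop_unreliable,
                       read_panel, residualize, score_scales)
from .report import average_layout, export_graphml, export_json_adjacency
from .stability import bootstrap_edges, case_drop_cs, difference_matrix
from .synthetic import (CONSTRUCTS, default_scale_definitions, default_spec,
                        spec_from_yaml, write_panel_csv, simulate_panel)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "replay"]

_COMPARED_SUFFIXES = (".csv", ".graphml", ".json")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; defaults are always echoed back."""

    output_dir: str
    seed: int | None = None
    input_path: str | None = None          # wide CSV; when None, simulate
    simulation_spec: str | None = None     # YAML spec path; None -> default spec
    simulation_n: int = 591
    likert_levels: int | str = 5
    alpha_threshold: float = 0.60
    scoring_method: str = "mean"
    min_answered: float = 0.75
    ebic_gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    cv_folds: int = 10
    bootstrap: bool = True
    n_boot_edges: int = 1000
    n_boot_casedrop: int = 250
    casedrop_grid: tuple = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.75)
    covariate_columns: tuple = DEFAULT_COVARIATES
    edge_threshold: float = 0.01

    def validate(self) -> "RunConfig":
        stochastic = self.bootstrap or self.input_path is None
        if stochastic and self.seed is None:
            raise ConfigurationError(
                "a master seed is mandatory when any stochastic stage "
                "(simulation or bootstrap) is enabled"
            )
        if self.scoring_method not in ("mean", "sum"):
            raise ConfigurationError(f"unknown scoring method {self.scoring_method!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("casedrop_grid", "covariate_columns"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


def _edge_dict_undirected(labels, weights) -> dict:
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[f"{labels[i]}--{labels[j]}"] = float(weights[i, j])
    return out


def _edge_dict_directed(labels, d) -> dict:
    out = {}
    for i in range(len(labels)):
        for j in range(len(labels)):
            if i != j:
                out[f"{labels[i]}->{labels[j]}"] = float(d[i, j])
    return out


def _wave_matrix(residuals: pd.DataFrame, wave_suffix: str) -> pd.DataFrame:
    cols = [c for c in residuals.columns if c.endswith(wave_suffix)]
    return residuals[cols].rename(columns={c: c[: -len(wave_suffix)] for c in cols})


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all outputs to the run directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("panelnet")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    input_hash = None
    try:
        # ---- stage: input -------------------------------------------------
        if config.input_path is not None:
            scale_defs = default_scale_definitions()
            data = read_panel(config.input_path, scale_defs,
                              covariate_columns=tuple(config.covariate_columns))
            input_hash = hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest()
            logger.info("read %d participants from %s (%d warnings)",
                        data.n, config.input_path, data.n_warnings)
        else:
            spec = (spec_from_yaml(config.simulation_spec)
                    if config.simulation_spec else
                    default_spec(n=config.simulation_n,
                                 likert_levels=config.likert_levels,
                                 seed=derive_seed(config.seed, 100)))
            if config.simulation_spec is None:
                spec.seed = derive_seed(config.seed, 100)
            data = simulate_panel(spec)
            write_panel_csv(data, outdir / "simulated_panel.csv")
            logger.info("simulated %d participants (seed %d)", data.n, spec.seed)

        # ---- stage: scoring & descriptives --------------------------------
        data = score_scales(data, method=config.scoring_method,
                            min_answered=config.min_answered)
        descr = descriptives(data)
        descr.round(6).to_csv(outdir / "descriptives.csv")
        retained = drop_unreliable(descr, threshold=config.alpha_threshold)
        logger.info("retained %d/%d scales after reliability screening",
                    len(retained), len(data.scale_defs))

        # ---- stage: residualization ---------------------------------------
        wide = pd.concat(
            {w: data.scores[w][retained] for w in data.scores}, axis=1)
        wide.columns = [f"{scale}{'_t1' if wave == 'T1' else '_t2'}"
                        for wave, scale in wide.columns]
        residuals = residualize(wide, data.covariates)
        residuals.round(10).to_csv(outdir / "residuals.csv")
        logger.info("residualized %d score columns on %d covariates; %d complete rows",
                    residuals.shape[1], len(config.covariate_columns), len(residuals))

        constructs = {k: v for k, v in CONSTRUCTS.items() if k in retained}

        # ---- stage: contemporaneous networks ------------------------------
        nets = {}
        for wave, suf in (("T1", "_t1"), ("T2", "_t2")):
            X = _wave_matrix(residuals, suf)
            est = GaussianGraphicalModel(
                gamma=config.ebic_gamma, n_lambdas=config.n_lambdas,
                lambda_min_ratio=config.lambda_min_ratio, constructs=constructs,
            ).fit(X)
            nets[wave] = est.network_
            pd.DataFrame(est.correlation_, index=X.columns, columns=X.columns
                         ).round(10).to_csv(outdir / f"correlation_{wave.lower()}.csv")
            est.network_.edge_frame().round(10).to_csv(
                outdir / f"ggm_{wave.lower()}_edges.csv", index=False)
            export_graphml(est.network_, outdir / f"ggm_{wave.lower()}.graphml")
            export_json_adjacency(est.network_, outdir / f"ggm_{wave.lower()}.json")
            logger.info("GGM %s: lambda=%.5f, %d edges", wave,
                        est.lambda_, est.network_.metadata["edge_count"])
        avg = average_edges(nets["T1"], nets["T2"], threshold=config.edge_threshold)
        avg.round(10).to_csv(outdir / "edge_average.csv", index=False)

        # ---- stage: temporal network --------------------------------------
        X1 = _wave_matrix(residuals, "_t1")
        X2 = _wave_matrix(residuals, "_t2")
        clpn_seed = derive_seed(config.seed, 200) if config.seed is not None else 0
        clpn_est = CrossLaggedPanelNetwork(
            cv=config.cv_folds, random_state=clpn_seed, constructs=constructs,
        ).fit(X1, X2)
        tnet = clpn_est.network_
        pd.DataFrame(tnet.d, index=tnet.node_labels, columns=tnet.node_labels
                     ).round(10).to_csv(outdir / "clpn_matrix.csv")
        filter_edges(tnet, threshold=config.edge_threshold).round(10).to_csv(
            outdir / "clpn_edges.csv", index=False)
        export_graphml(tnet, outdir / "clpn.graphml")
        export_json_adjacency(tnet, outdir / "clpn.json")
        logger.info("CLPN: per-node lambdas %s",
                    np.round(tnet.lambda_per_node, 4).tolist())

        # ---- stage: centrality & layout -----------------------------------
        cent = pd.concat([
            expected_influence(nets["T1"]).assign(network="contemporaneous_t1"),
            expected_influence(nets["T2"]).assign(network="contemporaneous_t2"),
            temporal_centrality_table(tnet).assign(network="temporal"),
            variance_explained_prediction(tnet, X1, X2, "cross_lagged").assign(network="temporal"),
            variance_explained_prediction(tnet, X1, X2, "cross_construct").assign(network="temporal"),
        ], ignore_index=True)
        cent.round(10).to_csv(outdir / "centrality.csv", index=False)
        layout = average_layout(nets["T1"], nets["T2"],
                                seed=derive_seed(config.seed, 300) if config.seed is not None else 0)
        layout.round(10).to_csv(outdir / "layout.csv", index=False)

        # ---- stage: stability ---------------------------------------------
        if config.bootstrap:
            (outdir / "cs_coefficients.csv").unlink(missing_ok=True)  # appended below
            _stability_stage(config, residuals, X1, X2, constructs, outdir)

        manifest = {
            "panelnet_version": __version__,
            "config": _jsonable(asdict(config)),
            "input_sha256": input_hash,
            "n_participants": int(data.n),
            "retained_scales": retained,
            "versions": _versions(),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("run complete: %s", outdir)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    return outdir


def _ggm_edge_estimator(config, labels):
    def estimator(rows, seed):
        X = pd.DataFrame(rows, columns=labels)
        est = GaussianGraphicalModel(
            gamma=config.ebic_gamma, n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio).fit(X)
        return _edge_dict_undirected(labels, est.partial_corr_)
    return estimator


def _ggm_ei_fn(config, labels):
    def fn(rows, seed):
        X = pd.DataFrame(rows, columns=labels)
        est = GaussianGraphicalModel(
            gamma=config.ebic_gamma, n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio).fit(X)
        return est.partial_corr_.sum(axis=1)
    return fn


def _stability_stage(config, residuals, X1, X2, constructs, outdir: Path) -> None:
    labels = list(X1.columns)

    for wave, X in (("t1", X1), ("t2", X2)):
        summary, reps = bootstrap_edges(
            X.to_numpy(), _ggm_edge_estimator(config, labels),
            n_boot=config.n_boot_edges,
            seed=derive_seed(config.seed, 400, 0 if wave == "t1" else 1))
        summary.round(10).to_csv(outdir / f"bootstrap_edges_ggm_{wave}.csv", index=False)
        nonzero = summary.loc[summary["point"] != 0, "estimand"]
        difference_matrix(reps, nonzero).to_csv(outdir / f"difference_edges_ggm_{wave}.csv")
        cs = case_drop_cs(X.to_numpy(), _ggm_ei_fn(config, labels),
                          drop_grid=config.casedrop_grid,
                          n_boot=config.n_boot_casedrop,
                          seed=derive_seed(config.seed, 401, 0 if wave == "t1" else 1),
                          index_name=f"EI_{wave}")
        cs.detail.round(10).to_csv(outdir / f"cs_ei_{wave}_detail.csv", index=False)
        logger.info("CS(EI, %s) = %.2f", wave, cs.cs)
        _append_cs(outdir, cs)

    def clpn_estimator(data_parts, seed):
        a1, a2 = data_parts
        est = CrossLaggedPanelNetwork(cv=config.cv_folds, random_state=seed,
                                      constructs=constructs).fit(
            pd.DataFrame(a1, columns=labels), pd.DataFrame(a2, columns=labels))
        return _edge_dict_directed(labels, est.d_)

    summary, reps = bootstrap_edges(
        (X1.to_numpy(), X2.to_numpy()), clpn_estimator,
        n_boot=config.n_boot_edges, seed=derive_seed(config.seed, 402))
    summary.round(10).to_csv(outdir / "bootstrap_edges_clpn.csv", index=False)
    nonzero = summary.loc[summary["point"] != 0, "estimand"]
    difference_matrix(reps, nonzero).to_csv(outdir / "difference_edges_clpn.csv")

    def pred_fn(direction):
        axis = 0 if direction == "in" else 1
        def fn(data_parts, seed):
            a1, a2 = data_parts
            est = CrossLaggedPanelNetwork(cv=config.cv_folds, random_state=seed,
                                          constructs=constructs).fit(
                pd.DataFrame(a1, columns=labels), pd.DataFrame(a2, columns=labels))
            d = est.d_.copy()
            np.fill_diagonal(d, 0.0)
            return d.sum(axis=axis)
        return fn

    for direction in ("in", "out"):
        cs = case_drop_cs((X1.to_numpy(), X2.to_numpy()), pred_fn(direction),
                          drop_grid=config.casedrop_grid,
                          n_boot=config.n_boot_casedrop,
                          seed=derive_seed(config.seed, 403, 0 if direction == "in" else 1),
                          index_name=f"{direction}_prediction")
        cs.detail.round(10).to_csv(outdir / f"cs_{direction}_prediction_detail.csv", index=False)
        logger.info("CS(%s-prediction) = %.2f", direction, cs.cs)
        _append_cs(outdir, cs)


def _append_cs(outdir: Path, cs) -> None:
    path = outdir / "cs_coefficients.csv"
    row = pd.DataFrame([{"centrality_index": cs.centrality_index, "cs": cs.cs,
                         "correlation_threshold": cs.correlation_threshold,
                         "probability_threshold": cs.probability_threshold}])
    header = not path.exists()
    row.to_csv(path, mode="a", header=header, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _versions() -> dict:
    import networkx
    import scipy
    import sklearn
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__, "scikit-learn": sklearn.__version__,
            "networkx": networkx.__version__}


def replay(manifest_path, work_dir: str | None = None):
    """Re-execute a run from its manifest and byte-compare the outputs.

    Returns the list of files whose bytes differ (empty on success).
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    original_dir = manifest_path.parent
    cfg_dict = dict(manifest["config"])
    for key in ("casedrop_grid", "covariate_columns"):
        cfg_dict[key] = tuple(cfg_dict[key])
    work_dir = work_dir or tempfile.mkdtemp(prefix="panelnet_replay_")
    cfg_dict["output_dir"] = str(work_dir)
    run_pipeline(RunConfig(**cfg_dict))
    differing = []
    for f in sorted(original_dir.iterdir()):
        if f.suffix not in _COMPARED_SUFFIXES or f.name == "manifest.json":
            continue
        replayed = Path(work_dir) / f.name
        if not replayed.exists() or replayed.read_bytes() != f.read_bytes():
            differing.append(f.name)
    return differing
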