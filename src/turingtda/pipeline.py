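"""End-to-end sweep: discretise the restricted Turing space, simulate each
node to a stable pattern, summarise it by four barcodes, build the
composite Wasserstein distance matrix, cluster, and report.

Filtration conventions follow the kinetics type: CIMA (pure kinetics, the
species' patterns are in phase) uses a lower-star filtration for u and an
upper-star filtration for v; Schnakenberg (cross kinetics, anti-phase
patterns) uses upper-star filtrations for both species.

Per-node results are cached on disk keyed by a hash of the node parameters,
seed and configuration, so sweeps are resumable and re-runs are
bit-identical.  Solver failures flag the node and the sweep continues.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import qmc

from .kinetics import Model, ModelParams, linearise
from .metrics import (
    BarcodeSet,
    ClusteringResult,
    distance_matrix,
    select_clustering,
)
from .persistence import (
    PersistenceDiagram,
    clean_barcode,
    compute_barcodes,
    star_filtration,
    triangulate_grid,
)
from .simulate import SimConfig, build_grid, integrate, random_ic

__all__ = [
    "SweepConfig",
    "NodeResult",
    "discretize_turing_space",
    "run_sweep",
    "cluster_sweep",
    "report",
    "load_report",
]

# default bar-length cutoffs (in filtration levels) for cleaned barcodes;
# degree-1 bars of u are kept in full
DEFAULT_CUTOFFS = {"b0u": 5.0, "b1u": 0.0, "b0v": 5.0, "b1v": 5.0}

_DIRECTIONS = {
    Model.CIMA: {"u": "lower", "v": "upper"},
    Model.SCHNAKENBERG: {"u": "upper", "v": "upper"},
}


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of a Turing-space sweep.

    Parameter boxes: CIMA samples (alpha, beta, sigma) at fixed delta;
    Schnakenberg samples (alpha, beta, delta) at sigma = 1.  Only points
    satisfying the Turing conditions C1-C4 become nodes.
    """

    model: Model = Model.CIMA
    delta: float = 1.5
    alpha_bounds: tuple[float, float] = (0.0, 20.0)
    beta_bounds: tuple[float, float] = (0.01, 17.0)
    sigma_bounds: tuple[float, float] = (1.0, 20.0)
    delta_bounds: tuple[float, float] = (25.0, 45.0)  # Schnakenberg only
    n_nodes: int = 549
    Lx: float = 20.0
    Ly: float = 20.0
    stepsize: float = 0.5
    sim: SimConfig = field(default_factory=lambda: SimConfig(method="imex"))
    n_levels: int = 20
    use_cleaned: bool = True
    cutoffs: tuple[tuple[str, float], ...] = tuple(DEFAULT_CUTOFFS.items())
    metric: str = "d1"
    linkages: tuple[str, ...] = ("single", "complete", "average")
    k_range: tuple[int, ...] = tuple(range(2, 13))
    master_seed: int = 0
    boundary_margin: float = 0.0

    def config_hash(self) -> str:
        payload = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("n_nodes", "metric", "linkages", "k_range")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class NodeResult:
    node_id: int
    params: ModelParams
    seed: int
    status: str
    amplitude_u: float
    barcodes: BarcodeSet | None


def _in_space(params: ModelParams, margin: float) -> bool:
    lin = linearise(params)
    det = lin.f_u * lin.g_v - lin.f_v * lin.g_u
    q = lin.d_v * lin.f_u + lin.d_u * lin.g_v
    disc = q * q - 4.0 * lin.d_u * lin.d_v * det
    return (
        lin.f_u + lin.g_v < -margin
        and det > margin
        and q > margin
        and disc > margin
    )


def discretize_turing_space(config: SweepConfig) -> list[ModelParams]:
    """Quasi-uniform parameter nodes strictly inside the Turing space.

    Low-discrepancy (Halton) points in the parameter box are rejection-
    sampled against C1-C4 (with a configurable margin) until the
    requested node count is reached.  Deterministic for a fixed
    master_seed.
    """
    if config.model is Model.CIMA:
        box = [config.alpha_bounds, config.beta_bounds, config.sigma_bounds]

        def make(point):
            return ModelParams(
                Model.CIMA,
                alpha=point[0],
                beta=point[1],
                delta=config.delta,
                sigma=point[2],
            )

    else:
        box = [config.alpha_bounds, config.beta_bounds, config.delta_bounds]

        def make(point):
            return ModelParams(
                Model.SCHNAKENBERG,
                alpha=point[0],
                beta=point[1],
                delta=point[2],
            )

    sampler = qmc.Halton(d=3, scramble=True, seed=config.master_seed)
    lows = [b[0] for b in box]
    highs = [b[1] for b in box]
    nodes: list[ModelParams] = []
    attempts = 0
    while len(nodes) < config.n_nodes:
        raw = sampler.random(max(64, config.n_nodes))
        points = qmc.scale(raw, lows, highs)
        for pt in points:
            try:
                params = make(pt)
            except ValueError:
                continue
            if _in_space(params, config.boundary_margin):
                nodes.append(params)
                if len(nodes) == config.n_nodes:
                    break
        attempts += len(points)
        if attempts > max(100_000, 1000 * config.n_nodes) and not nodes:
            raise ValueError("no Turing-space point found within the bounds")
        if attempts > 2_000_000:
            raise ValueError(
                f"only {len(nodes)} of {config.n_nodes} nodes found; "
                "region too small for the requested count"
            )
    return nodes


def _node_seed(master_seed: int, node_id: int) -> int:
    return int(
        np.random.SeedSequence((master_seed, node_id)).generate_state(1)[0]
        % (2**31)
    )


def _barcodes_for_fields(u, v, model: Model, n_levels: int, cutoffs, use_cleaned, node_id):
    cx = triangulate_grid(u.grid)
    dirs = _DIRECTIONS[model]
    diags: dict[str, PersistenceDiagram] = {}
    for species, fld in (("u", u), ("v", v)):
        fc = star_filtration(fld, cx, direction=dirs[species], n_levels=n_levels)
        bars = compute_barcodes(fc)
        for deg in (0, 1):
            key = f"b{deg}{species}"
            d = bars[deg]
            if use_cleaned:
                d = clean_barcode(d, dict(cutoffs).get(key, 0.0))
            diags[key] = d
    return BarcodeSet(node_id=node_id, **diags)


def _cache_path(cache_dir: Path, config: SweepConfig, params: ModelParams, seed: int) -> Path:
    key = hashlib.sha256(
        json.dumps(
            {
                "config": config.config_hash(),
                "params": asdict(params),
                "seed": seed,
            },
            sort_keys=True,
            default=str,
        ).encode()
    ).hexdigest()[:24]
    return cache_dir / f"node_{key}.json"


def _serialise_result(res: NodeResult) -> dict:
    out = {
        "node_id": res.node_id,
        "params": asdict(res.params),
        "seed": res.seed,
        "status": res.status,
        "amplitude_u": res.amplitude_u,
    }
    if res.barcodes is not None:
        out["diagrams"] = {
            key: [[b, None if math.isinf(d) else d] for b, d in diag.pairs]
            for key, diag in zip(
                ("b0u", "b1u", "b0v", "b1v"), res.barcodes.channels()
            )
        }
    return out


def _deserialise_result(data: dict) -> NodeResult:
    barcodes = None
    if "diagrams" in data:
        diags = {}
        for key, pairs in data["diagrams"].items():
            deg = int(key[1])
            diags[key] = PersistenceDiagram(
                degree=deg,
                pairs=tuple(
                    (b, math.inf if d is None else d) for b, d in pairs
                ),
            )
        barcodes = BarcodeSet(node_id=data["node_id"], **diags)
    p = dict(data["params"])
    p["model"] = Model(p["model"])
    return NodeResult(
        node_id=data["node_id"],
        params=ModelParams(**p),
        seed=data["seed"],
        status=data["status"],
        amplitude_u=data["amplitude_u"],
        barcodes=barcodes,
    )


def run_sweep(
    nodes: list[ModelParams],
    config: SweepConfig,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> list[NodeResult]:
    """Simulate every node and compute its (optionally cleaned) barcode
    set; failed nodes are flagged and skipped by downstream clustering."""
    grid = build_grid(config.Lx, config.Ly, config.stepsize)
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    results: list[NodeResult] = []
    for i, params in enumerate(nodes):
        seed = _node_seed(config.master_seed, i)
        path = _cache_path(cache, config, params, seed) if cache else None
        if path is not None and path.exists():
            data = json.loads(path.read_text())
            data["node_id"] = i
            results.append(_deserialise_result(data))
            continue
        try:
            u0, v0 = random_ic(params, grid, sd=config.sim.ic_sd, seed=seed)
            u, v, status = integrate(params, u0, v0, config.sim)
            amplitude = float(u.values.max() - u.values.min())
            barcodes = _barcodes_for_fields(
                u, v, config.model, config.n_levels, config.cutoffs,
                config.use_cleaned, i,
            )
            res = NodeResult(i, params, seed, status, amplitude, barcodes)
        except (RuntimeError, ValueError) as exc:
            res = NodeResult(i, params, seed, f"failed: {exc}", float("nan"), None)
        results.append(res)
        if path is not None:
            path.write_text(json.dumps(_serialise_result(res), sort_keys=True))
        if progress:  # pragma: no cover
            print(f"node {i + 1}/{len(nodes)}: {res.status}", flush=True)
    return results


def cluster_sweep(
    results: list[NodeResult], config: SweepConfig
) -> tuple[np.ndarray, ClusteringResult, list[int]]:
    """Distance matrix and silhouette-selected clustering over the
    successfully simulated nodes.  Returns (matrix, clustering, the node
    ids that entered the clustering)."""
    ok = [r for r in results if r.barcodes is not None]
    if len(ok) < 2:
        raise ValueError("need at least 2 successful nodes to cluster")
    D = distance_matrix([r.barcodes for r in ok], variant=config.metric)
    best = select_clustering(D, config.linkages, config.k_range)
    return D, best, [r.node_id for r in ok]


def report(
    results: list[NodeResult],
    config: SweepConfig,
    out_dir: str | Path,
    clustering: ClusteringResult | None = None,
    clustered_ids: list[int] | None = None,
    matrix: np.ndarray | None = None,
    plot: bool = False,
) -> dict:
    """Emit the report bundle: labels CSV, silhouette table, JSON summary
    and (optionally) a parameter-space scatter coloured by cluster.

    With fewer than 2 usable nodes the clustering section is omitted."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label_of = {}
    if clustering is not None and clustered_ids is not None:
        label_of = dict(zip(clustered_ids, (int(x) for x in clustering.labels)))
    node_rows = []
    for r in results:
        node_rows.append(
            {
                "node_id": r.node_id,
                "alpha": r.params.alpha,
                "beta": r.params.beta,
                "sigma": r.params.sigma,
                "delta": r.params.delta,
                "status": r.status,
                "amplitude_u": r.amplitude_u,
                "cluster": label_of.get(r.node_id),
            }
        )
    pd.DataFrame(node_rows).to_csv(out / "labels.csv", index=False)
    doc: dict = {
        "model": config.model.value,
        "metric": config.metric,
        "n_nodes": len(results),
        "n_failed": sum(r.barcodes is None for r in results),
        "nodes": node_rows,
    }
    if clustering is not None:
        doc["clustering"] = {
            "linkage": clustering.linkage,
            "k": int(clustering.k),
            "silhouette": float(clustering.silhouette),
        }
        if matrix is not None:
            sil_rows = []
            from .metrics import cluster as _cluster, silhouette as _sil

            for link in config.linkages:
                for k in config.k_range:
                    if not 2 <= k <= matrix.shape[0] - 1:
                        continue
                    labels = _cluster(matrix, link, k)
                    if len(np.unique(labels)) < 2:
                        continue
                    sil_rows.append(
                        {"linkage": link, "k": k, "silhouette": _sil(matrix, labels)}
                    )
            pd.DataFrame(sil_rows).to_csv(out / "silhouette.csv", index=False)
            doc["silhouette_table"] = sil_rows
    (out / "report.json").write_text(json.dumps(doc, sort_keys=True, default=float))
    if plot and label_of:  # pragma: no cover - plotting is cosmetic
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        xs = [r.params.alpha for r in results if r.node_id in label_of]
        ys = [r.params.beta for r in results if r.node_id in label_of]
        cs = [label_of[r.node_id] for r in results if r.node_id in label_of]
        sc = ax.scatter(xs, ys, c=cs, cmap="tab10", s=25)
        ax.set_xlabel("alpha")
        ax.set_ylabel("beta")
        fig.colorbar(sc, label="cluster")
        fig.savefig(out / "clusters.png", dpi=150)
        plt.close(fig)
    return doc


def load_report(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "report.json").read_text())
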