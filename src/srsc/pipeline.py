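"""End-to-end segmentation pipeline and multi-method comparison harness.

The full spectral route is: masked feature extraction -> per-parameter
standardization -> RBF affinity -> normalized-Laplacian embedding ->
spatially constrained GMM with an image-space 26-neighbor graph -> tissue
naming.  The baselines (kmeans / fcm / gmm) run on the standardized raw
features, matching how they are used as stand-alone competitors.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusterers import (
    NeighborGraph,
    build_neighbor_graph,
    constrained_gmm_fit,
    fcm_fit,
    gmm_fit,
    kmeans_fit,
    make_init,
)
from .evaluate import (
    SegmentationResult,
    TISSUE_ORDER,
    assign_tissue_names,
    compute_fractions,
    correlate_fractions,
    match_labels,
    segmentation_from_responsibilities,
)
from .io_model import (
    MultiparametricStack,
    extract_features,
    read_stack,
    standardize,
    write_segmentation,
)
from .spectral import choose_sigma, compute_affinity, spectral_embed

__all__ = ["RunConfig", "run_segmentation", "run_comparison"]

logger = logging.getLogger(__name__)

_METHODS = ("srsc", "kmeans", "fcm", "gmm")
_KNOWN_KEYS = {
    "method", "n_classes", "sigma_rule", "laplacian", "n_eigvecs",
    "standardize", "fcm_m", "tol", "max_iter", "seed", "n_restarts",
    "input_paths", "mask_path", "output_dir", "spatial_graph",
    "baselines_on_embedding", "assign_names",
}


@dataclass
class RunConfig:
    """Validated configuration for one segmentation run."""

    method: str = "srsc"
    n_classes: int = 3
    sigma_rule: str = "median"
    laplacian: str = "sym"
    n_eigvecs: int | None = None  # default: n_classes
    standardize: bool = True
    fcm_m: float = 2.0
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0
    n_restarts: int = 10
    input_paths: dict | None = None
    mask_path: str | None = None
    output_dir: str | None = None
    spatial_graph: bool = True  # False disables the 26-neighbor regularization
    baselines_on_embedding: bool = False
    assign_names: bool = True

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.laplacian not in ("sym", "rw"):
            raise ValueError("laplacian must be 'sym' or 'rw'")
        if self.fcm_m <= 1:
            raise ValueError("fcm_m must exceed 1")
        if self.tol <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("tol, max_iter, n_restarts out of range")
        if not (
            self.sigma_rule == "median"
            or self.sigma_rule.startswith("median:")
            or self.sigma_rule.startswith("fixed:")
        ):
            raise ValueError(f"unknown sigma rule {self.sigma_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @property
    def k_eig(self) -> int:
        return self.n_eigvecs if self.n_eigvecs is not None else self.n_classes


def _stage(name):
    """Wrap stage errors with the stage name for diagnosable CLI failures."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: %.2fs", name, dt)
            return False

    return _Ctx()


def run_segmentation(
    cfg: RunConfig, stack: MultiparametricStack | None = None
) -> SegmentationResult:
    """Run one clustering method on a stack and return a named segmentation.

    If ``stack`` is None the input volumes are read from ``cfg.input_paths``
    and ``cfg.mask_path``.  When ``cfg.output_dir`` is set, the label and
    probability volumes plus a JSON manifest sufficient to reproduce the run
    are written there.
    """
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
    }
    if stack is None:
        if not cfg.input_paths or not cfg.mask_path:
            raise ValueError("either a stack or input_paths + mask_path required")
        with _stage("read"):
            stack = read_stack(cfg.input_paths, cfg.mask_path)

    with _stage("features"):
        fm = extract_features(stack)
        if cfg.standardize:
            fm = standardize(fm)
    K = cfg.n_classes

    if cfg.method == "srsc" or cfg.baselines_on_embedding:
        with _stage("affinity"):
            sigma = choose_sigma(fm, cfg.sigma_rule, seed=cfg.seed)
            aff = compute_affinity(fm, sigma, sigma_rule=cfg.sigma_rule)
            manifest["sigma"] = sigma
        with _stage("embedding"):
            emb = spectral_embed(
                aff, k=cfg.k_eig, row_normalize=True, laplacian=cfg.laplacian
            )
            manifest["eigenvalues"] = emb.eigenvalues.tolist()
        Y = emb.Y
    else:
        Y = fm.X

    with _stage("clustering"):
        if cfg.method == "srsc":
            graph = (
                build_neighbor_graph(fm.coords, stack.shape)
                if cfg.spatial_graph
                else NeighborGraph.empty(fm.coords)
            )
            init = make_init(Y, K, strategy="kmeans", seed=cfg.seed)
            params, resp = constrained_gmm_fit(
                Y, graph, K, init=init, tol=cfg.tol,
                max_iter=cfg.max_iter, seed=cfg.seed,
            )
            R = resp.R
            manifest["em"] = {
                "n_iter": resp.n_iter,
                "converged": resp.converged,
                "objective_trace": resp.trace,
            }
        elif cfg.method == "gmm":
            params, resp = gmm_fit(
                Y, K, tol=cfg.tol, max_iter=cfg.max_iter, seed=cfg.seed
            )
            R = resp.R
            manifest["em"] = {
                "n_iter": resp.n_iter,
                "converged": resp.converged,
                "objective_trace": resp.trace,
            }
        elif cfg.method == "fcm":
            res = fcm_fit(
                Y, K, m=cfg.fcm_m, tol=cfg.tol, max_iter=cfg.max_iter, seed=cfg.seed
            )
            R = res.U
            manifest["em"] = {"n_iter": res.n_iter, "objective_trace": res.objective}
        else:  # kmeans
            res = kmeans_fit(Y, K, n_restarts=cfg.n_restarts, seed=cfg.seed)
            R = np.eye(K)[res.labels]
            manifest["inertia"] = res.inertia

    seg = segmentation_from_responsibilities(R, fm.coords, stack.mask, manifest)
    if cfg.assign_names and K >= 3 and "ADC" in stack.maps:
        seg = assign_tissue_names(seg, stack)

    if cfg.output_dir:
        with _stage("write"):
            out = Path(cfg.output_dir)
            write_segmentation(seg, out, affine=stack.affine)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return seg


def run_comparison(
    cfgs: list[RunConfig],
    stacks: list[MultiparametricStack],
    reference: list[dict] | None = None,
    truth_labels: list[np.ndarray] | None = None,
) -> dict:
    """Run several methods over a cohort and tabulate fractions/correlations.

    ``cfgs`` holds one config per method; every config is applied to every
    stack.  ``reference`` is a list (one per stack) of tissue -> fraction
    dicts; ``truth_labels`` optionally enables matched agreement metrics.
    Returns per-method fraction tables and a correlation table in the layout
    rows = (Viable, Necrotic, Peri-necrotic, All) x columns = methods.
    """
    if reference is None and truth_labels is None:
        raise ValueError("need reference fractions or truth labels")
    methods = [c.method for c in cfgs]
    if len(set(methods)) != len(methods):
        raise ValueError("duplicate methods in comparison")

    fractions: dict[str, list] = {m: [] for m in methods}
    agreement: dict[str, list] = {m: [] for m in methods}
    for i, stack in enumerate(stacks):
        for cfg in cfgs:
            seg = run_segmentation(cfg, stack=stack)
            fractions[cfg.method].append(compute_fractions(seg, basis="hard"))
            if truth_labels is not None:
                agreement[cfg.method].append(
                    match_labels(seg.labels, truth_labels[i], mask=stack.mask)
                )

    corr_cols = {}
    row_order = ["viable", "necrotic", "peri-necrotic", "All"]
    for m in methods:
        ref = reference
        if ref is None:
            ref = [
                {t: float((truth_labels[i][stacks[i].mask] == k + 1).sum())
                 / int(stacks[i].mask.sum())
                 for k, t in enumerate(TISSUE_ORDER)}
                for i in range(len(stacks))
            ]
        table = correlate_fractions(fractions[m], ref)
        corr_cols[m] = table["r"].reindex(row_order)
    correlation = pd.DataFrame(corr_cols)
    correlation.index = ["Viable", "Necrotic", "Peri-necrotic", "All"]

    return {
        "fractions": fractions,
        "agreement": agreement if truth_labels is not None else None,
        "correlation": correlation,
    }
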