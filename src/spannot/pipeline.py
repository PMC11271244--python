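"""Two-stage annotation pipeline: detect, then refine.

``prepare_state`` runs QC, size factors, denoising and the optional
spatial-autocorrelation gene filter; ``run_detector`` produces the initial
annotation (optionally autotuned); ``refine`` builds the MRF prior and the
skeleton-anchored count model and runs EM; ``annotate`` chains everything
and returns a result bundle plus a reproducibility manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from . import core
from .autotune import SearchSpace, expand_markers, rank_candidate_markers, search
from .detector import Annotation, DetectorParams, build_pixel_map, detect
from .em import (EMConfig, fit_em, pattern_mean_anchor, renew_labels,
                 skeletonize_mask)
from .mrf import MRFHyper, build_neighborhoods, build_prior

__all__ = ["RunConfig", "AnnotateResult", "prepare_state", "run_detector",
           "refine", "annotate"]


@dataclass
class RunConfig:
    """End-to-end configuration with the recommended operating defaults."""

    min_gene_frac: float = 0.01
    denoise_k: int = 6
    morans_top_frac: Optional[float] = 0.35   # None disables the filter
    detector: DetectorParams = field(default_factory=DetectorParams)
    autotune: Optional[SearchSpace] = None
    expand_per_pattern: int = 3               # 0 disables marker expansion
    mrf: MRFHyper = field(default_factory=lambda: MRFHyper(omega1=0.99, omega2=0.01))
    knn_transcriptomic: int = 6
    knn_spatial: int = 6
    em: EMConfig = field(default_factory=EMConfig)
    renewal: str = "argmax"
    seed: int = 0

    def manifest(self) -> dict:
        m = asdict(self)
        if self.autotune is not None:
            m["autotune"] = {"domains": self.autotune.domains,
                             "budget": self.autotune.budget,
                             "seed": self.autotune.seed}
        return m


@dataclass
class AnnotateResult:
    state: "core.SpotTable"
    initial: Annotation
    markers: Dict[str, list]
    posterior: np.ndarray
    labels: np.ndarray
    pattern_names: list
    em_state: object
    prior: object
    manifest: dict


def prepare_state(coords, counts, gene_names, spot_ids=None,
                  config: Optional[RunConfig] = None,
                  protect_genes=None) -> "core.SpotTable":
    """QC, size factors, denoising and the Moran's-I gene filter."""
    cfg = config or RunConfig()
    state = core.create_state(coords, counts, gene_names, spot_ids=spot_ids,
                              min_gene_frac=cfg.min_gene_frac)
    state.size_factors = core.size_factors(state.counts)
    state.denoised = core.denoise(state.counts, coords=state.coords,
                                  sf=state.size_factors, k=cfg.denoise_k)
    if cfg.morans_top_frac is not None:
        w = core.spatial_knn_weights(state.coords, k=6)
        always = state.gene_index(protect_genes) if protect_genes else None
        idx, scores = core.morans_filter(state.denoised, w,
                                         top_frac=cfg.morans_top_frac,
                                         always_keep=always)
        state.counts = state.counts[idx]
        state.denoised = state.denoised[idx]
        state.gene_names = state.gene_names[idx]
        state.qc_log["morans_kept"] = int(len(idx))
    return state


def run_detector(state, markers, config: Optional[RunConfig] = None):
    """Initial annotation, via hyperparameter search when configured."""
    cfg = config or RunConfig()
    if cfg.autotune is not None:
        params, ann, log = search(cfg.autotune, state, markers,
                                  base_params=cfg.detector)
        return ann, params, log
    ann = detect(state, markers, params=cfg.detector)
    return ann, cfg.detector, []


def refine(state, annotation: Annotation, markers: Dict[str, list],
           config: Optional[RunConfig] = None, pixel_map=None):
    """MRF prior + skeleton-anchored NB model + EM + label renewal.

    Returns (labels, posterior, em_state, prior_field).
    """
    cfg = config or RunConfig()
    if pixel_map is None:
        pixel_map = build_pixel_map(state.coords)
    R = annotation.feature_vectors.shape[1]
    labels = np.asarray(annotation.labels, dtype=int)

    graph = build_neighborhoods(state.denoised, state.coords,
                                K=cfg.knn_transcriptomic, spatial_k=cfg.knn_spatial)
    prior = build_prior(labels, annotation.feature_vectors, graph, R, hyper=cfg.mrf)

    marker_union, rho = _marker_union(markers, annotation.pattern_names,
                                      state.gene_names, R)
    rows = state.gene_index(marker_union)
    skeletons = _skeleton_stack(annotation, pixel_map, R)
    anchors = pattern_mean_anchor(state.counts, labels, skeletons, pixel_map,
                                  marker_rows=rows)
    em_cfg = replace(cfg.em, seed=cfg.seed)
    em_state = fit_em(state.counts[rows], state.size_factors, prior.prior,
                      anchors, rho, em_cfg)
    new_labels = renew_labels(em_state.posterior_, method=cfg.renewal,
                              pixel_map=pixel_map, params=cfg.detector,
                              pattern_names=annotation.pattern_names)
    return new_labels, em_state.posterior_, em_state, prior


def _marker_union(markers, pattern_names, gene_names, R):
    """Ordered union of marker genes present in the matrix, and rho (G_m, R).

    A pattern absent from ``pattern_names`` (or marker-free) contributes
    nothing; the marker-free/undefined pattern keeps an all-zero rho column.
    """
    present = set(map(str, gene_names))
    union = []
    for pat in pattern_names:
        for g in markers.get(pat, []):
            if g in present and g not in union:
                union.append(g)
    if not union:
        raise ValueError("no marker genes present in the matrix")
    rho = np.zeros((len(union), R))
    for r, pat in enumerate(list(pattern_names)[:R]):
        for g in markers.get(pat, []):
            if g in union:
                rho[union.index(g), r] = 1.0
    return union, rho


def _skeleton_stack(annotation: Annotation, pixel_map, R):
    masks = annotation.stack.positive_masks if annotation.stack is not None else None
    I, J = pixel_map.shape
    skel = np.zeros((I, J, R), dtype=bool)
    for r in range(R):
        if masks is not None and r < masks.shape[2]:
            skel[..., r] = skeletonize_mask(masks[..., r])
        else:
            lab_img = pixel_map.rasterize((annotation.labels == r).astype(float)) > 0.5
            skel[..., r] = skeletonize_mask(lab_img & pixel_map.mask)
    return skel


def annotate(coords, counts, gene_names, markers: Dict[str, list],
             spot_ids=None, config: Optional[RunConfig] = None) -> AnnotateResult:
    """Full pipeline from raw inputs to refined labels."""
    cfg = config or RunConfig()
    protect = [g for genes in markers.values() for g in genes]
    state = prepare_state(coords, counts, gene_names, spot_ids=spot_ids,
                          config=cfg, protect_genes=protect)
    pixel_map = build_pixel_map(state.coords)
    initial, params, trial_log = run_detector(state, markers, cfg)

    used_markers = {p: list(g) for p, g in markers.items()}
    if cfg.expand_per_pattern > 0:
        cands = rank_candidate_markers(state.counts, initial.labels,
                                       initial.pattern_names,
                                       sf=state.size_factors,
                                       top_k=cfg.expand_per_pattern * 3)
        used_markers = expand_markers(used_markers, cands, state.gene_names,
                                      per_pattern=cfg.expand_per_pattern)

    labels, post, em_state, prior = refine(state, initial, used_markers,
                                           config=cfg, pixel_map=pixel_map)
    manifest = {
        "config": cfg.manifest(),
        "seed": cfg.seed,
        "qc": state.qc_log,
        "markers": used_markers,
        "n_trials": len(trial_log),
        "detector_params": asdict(params) if not isinstance(params, dict) else params,
    }
    return AnnotateResult(state=state, initial=initial, markers=used_markers,
                          posterior=post, labels=labels,
                          pattern_names=initial.pattern_names,
                          em_state=em_state, prior=prior, manifest=manifest)
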