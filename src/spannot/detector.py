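"""Pattern detector: pseudo-images from marker expression and initial labels.

Spots are rasterized onto an integer pixel grid; each annotation pattern gets
a grayscale channel built by median-fusing its markers' denoised expression.
Channels are segmented with multi-Otsu thresholding, cleaned (small-component
removal, 2-means false-positive rejection, dilation), turned into feature
channels, and the per-spot argmax over feature channels gives the initial
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage
from skimage import filters, morphology, restoration

UNDEFINED = "undefined"

__all__ = [
    "PixelMap",
    "DetectorParams",
    "Annotation",
    "build_pixel_map",
    "create_pattern_channel",
    "multi_otsu",
    "split_positive",
    "filter_small_components",
    "reject_false_positives",
    "binarize_dilate",
    "extract_feature",
    "add_undefined_channel",
    "initialize_labels",
    "detect",
    "detect_from_stack",
]


@dataclass
class PixelMap:
    """Mapping between spots and pixels of an I x J raster.

    ``pixel_of_spot[s] = (i, j)``; ``spots_of_pixel[(i, j)]`` lists the spot
    indices sharing that pixel. ``mask`` is 1 exactly on mapped pixels.
    """

    pixel_of_spot: np.ndarray  # (S, 2) int, rows (i, j)
    shape: tuple  # (I, J)
    spots_of_pixel: Dict[tuple, list]
    mask: np.ndarray  # (I, J) bool

    def rasterize(self, values: np.ndarray) -> np.ndarray:
        """Paint per-spot values onto the grid, averaging within a pixel."""
        img = np.zeros(self.shape, dtype=float)
        cnt = np.zeros(self.shape, dtype=float)
        i, j = self.pixel_of_spot[:, 0], self.pixel_of_spot[:, 1]
        np.add.at(img, (i, j), np.asarray(values, dtype=float))
        np.add.at(cnt, (i, j), 1.0)
        np.divide(img, cnt, out=img, where=cnt > 0)
        return img

    def sample(self, image: np.ndarray) -> np.ndarray:
        """Per-spot values read back from an image (or image stack)."""
        i, j = self.pixel_of_spot[:, 0], self.pixel_of_spot[:, 1]
        return image[i, j]


@dataclass
class DetectorParams:
    """Tunable knobs of the pattern detector."""

    n_thresholds: int = 3          # multi-Otsu class count n (>= 2)
    min_component_area: int = 2
    dilation_radius: int = 2
    uncertainty: float = 0.5       # u of the undefined channel
    include_undefined: bool = False
    sharpen_amount: float = 1.0    # unsharp-mask amount; 0 disables
    sharpen_radius: float = 1.0
    gaussian_sigma: float = 0.5    # 0 disables
    tv_weight: float = 0.05        # 0 disables (feature post-processing)
    tv_weight_reject: float = 0.05  # TV denoise before component means
    hist_bins: int = 256
    connectivity: int = 2          # 8-connected

    def validate(self):
        if self.n_thresholds < 2:
            raise ValueError("n_thresholds must be >= 2")
        if not 0.0 <= self.uncertainty <= 1.0:
            raise ValueError("uncertainty must be in [0, 1]")
        return self


@dataclass
class Annotation:
    """Per-spot labels and feature vectors produced by the detector."""

    labels: np.ndarray            # (S,) int, 0-based pattern index; R = undefined
    feature_vectors: np.ndarray   # (S, R) or (S, R+1) floats in [0, 1]
    pattern_names: List[str]
    stack: Optional["PatternStack"] = None

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_names)

    def label_names(self) -> np.ndarray:
        names = list(self.pattern_names) + [UNDEFINED]
        return np.asarray([names[l] for l in self.labels], dtype=object)


@dataclass
class PatternStack:
    """Pattern image P, feature image F and per-pattern masks/skeletons."""

    pattern_image: np.ndarray          # (I, J, R)
    feature_image: np.ndarray          # (I, J, R) or (I, J, R+1)
    positive_masks: np.ndarray         # (I, J, R) bool
    skeletons: Optional[np.ndarray] = None  # (I, J, R) bool
    thresholds: Optional[list] = None


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5).astype(int) * np.sign(x).astype(int)


def build_pixel_map(coords) -> PixelMap:
    """Rasterize spot coordinates onto an integer grid.

    The grid pitch is estimated as the median nearest-neighbor distance;
    coordinates are shifted to be non-negative, divided by the pitch, and
    rounded half-away-from-zero. y defines rows (i), x defines columns (j).
    """
    coords = np.asarray(coords, dtype=float)
    if len(np.unique(coords, axis=0)) < 2:
        raise ValueError("need at least two distinct coordinates")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=2).fit(coords)
    d, _ = nn.kneighbors(coords)
    pitch = float(np.median(d[:, 1]))
    if pitch == 0:
        nz = d[:, 1][d[:, 1] > 0]
        if len(nz) == 0:
            raise ValueError("all coordinates coincident")
        pitch = float(np.median(nz))
    shifted = coords - coords.min(axis=0)
    ji = _round_half_away(shifted / pitch)
    pix = np.stack([ji[:, 1], ji[:, 0]], axis=1)  # (i, j) = (y, x)
    I, J = int(pix[:, 0].max()) + 1, int(pix[:, 1].max()) + 1
    spots_of_pixel: Dict[tuple, list] = {}
    for s, (i, j) in enumerate(map(tuple, pix)):
        spots_of_pixel.setdefault((i, j), []).append(s)
    mask = np.zeros((I, J), dtype=bool)
    mask[pix[:, 0], pix[:, 1]] = True
    return PixelMap(pixel_of_spot=pix, shape=(I, J), spots_of_pixel=spots_of_pixel, mask=mask)


def create_pattern_channel(denoised, marker_rows, pixel_map: PixelMap) -> np.ndarray:
    """Grayscale channel for one pattern.

    Per ROI pixel: mean over its spots of the median over the pattern's
    markers of the denoised expression, followed by a 3x3 median filter
    (background stays 0).
    """
    den = np.asarray(denoised, dtype=float)
    med = np.median(den[np.asarray(marker_rows, dtype=int)], axis=0)
    img = pixel_map.rasterize(med)
    img = ndimage.median_filter(img, size=3, mode="reflect")
    img[~pixel_map.mask] = 0.0
    return img


def multi_otsu(channel, mask, n: int = 3, nbins: int = 256) -> np.ndarray:
    """Multi-Otsu thresholds of the ROI intensities, descending.

    Exactly maximizes the between-class variance of an ``nbins``-bin
    histogram of the pixels under ``mask`` (dynamic programming over split
    positions, so the optimum is global for any class count). Thresholds
    are the bin centers of the last bin of each class but the top one, so
    a pixel belongs to the upper class iff its value exceeds the
    threshold. Raises on channels with fewer than ``n`` distinct ROI
    values.
    """
    vals = np.asarray(channel, dtype=float)[np.asarray(mask, dtype=bool)]
    if len(np.unique(vals)) < n:
        raise ValueError(f"degenerate channel: fewer than {n} distinct ROI values")
    hist, edges = np.histogram(vals, bins=nbins)
    if np.count_nonzero(hist) < n:
        raise ValueError(f"degenerate channel: fewer than {n} occupied histogram bins")
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    cp = np.concatenate([[0.0], np.cumsum(p)])
    cpm = np.concatenate([[0.0], np.cumsum(p * centers)])

    def seg_from(i_arr, j):
        # contribution w * mu^2 of classes spanning bins i..j inclusive
        w = cp[j + 1] - cp[i_arr]
        m = cpm[j + 1] - cpm[i_arr]
        return np.where(w > 0, m * m / np.where(w > 0, w, 1.0), 0.0)

    B = nbins
    prev = np.array([seg_from(np.array([0]), j)[0] for j in range(B)])
    back = np.zeros((n, B), dtype=int)
    for k in range(1, n):
        cur = np.full(B, -np.inf)
        for j in range(k, B):
            i_arr = np.arange(k, j + 1)
            v = prev[i_arr - 1] + seg_from(i_arr, j)
            bi = int(np.argmax(v))  # first index wins ties
            cur[j] = v[bi]
            back[k, j] = i_arr[bi]
        prev = cur
    splits = []
    j = B - 1
    for k in range(n - 1, 0, -1):
        i = back[k, j]
        splits.append(i - 1)  # last bin of the class below this boundary
        j = i - 1
    taus = centers[np.array(sorted(splits))]
    return np.sort(taus)[::-1]


def split_positive(channel, tau1: float):
    """Split a channel at the top threshold into positive/negative images."""
    ch = np.asarray(channel, dtype=float)
    pos = np.where(ch > tau1, ch, 0.0)
    neg = np.where(ch <= tau1, ch, 0.0)
    return pos, neg


def filter_small_components(pos, min_area: int = 2, connectivity: int = 2) -> np.ndarray:
    """Zero out 8-connected components of the support smaller than min_area."""
    pos = np.asarray(pos, dtype=float)
    support = pos > 0
    lab, n = ndimage.label(support, structure=np.ones((3, 3), dtype=int)
                           if connectivity == 2 else None)
    if n == 0:
        return pos.copy()
    areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep_ids = np.flatnonzero(areas >= min_area) + 1
    keep = np.isin(lab, keep_ids)
    return np.where(keep, pos, 0.0)


def _exact_two_means_split(values: np.ndarray) -> np.ndarray:
    """Exact 1-D 2-means by scanning all sorted split points.

    Returns a boolean array marking membership in the higher-mean cluster.
    Degenerate (all-equal) input puts everything in one cluster.
    """
    v = np.asarray(values, dtype=float)
    order = np.argsort(v)
    sv = v[order]
    n = len(sv)
    if n < 2 or sv[0] == sv[-1]:
        return np.zeros(n, dtype=bool)
    best_cost, best_k = np.inf, 1
    csum = np.cumsum(sv)
    csq = np.cumsum(sv**2)
    for k in range(1, n):  # low cluster = sv[:k]
        s1, q1 = csum[k - 1], csq[k - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        cost = (q1 - s1**2 / k) + (q2 - s2**2 / (n - k))
        if cost < best_cost - 1e-15:
            best_cost, best_k = cost, k
    hi = np.zeros(n, dtype=bool)
    hi[order[best_k:]] = True
    return hi


def reject_false_positives(pos, neg, tv_weight: float = 0.05, connectivity: int = 2):
    """Drop positive components clustering with the negative anchor.

    Component mean intensities (after a light total-variation denoise) are
    2-means-clustered together with the mean of the largest component of the
    negative image's support; components landing in the anchor's cluster are
    removed. An empty negative image skips rejection.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if not np.any(neg > 0):
        return pos
    smooth = restoration.denoise_tv_chambolle(pos, weight=tv_weight) if tv_weight > 0 else pos
    lab_pos, n_pos = ndimage.label(pos > 0, structure=np.ones((3, 3), dtype=int))
    if n_pos == 0:
        return pos
    lab_neg, n_neg = ndimage.label(neg > 0, structure=np.ones((3, 3), dtype=int))
    areas = ndimage.sum_labels(np.ones_like(lab_neg), lab_neg, index=range(1, n_neg + 1))
    biggest = int(np.argmax(areas)) + 1
    n_anchor = float(neg[lab_neg == biggest].mean())
    p_means = np.array(
        [float(smooth[lab_pos == k].mean()) for k in range(1, n_pos + 1)]
    )
    pool = np.concatenate([[n_anchor], p_means])
    hi = _exact_two_means_split(pool)
    if not hi[0]:  # anchor in the low cluster: keep components in high cluster
        keep_ids = np.flatnonzero(hi[1:]) + 1
    else:  # anchor ended up high (pathological): keep low cluster
        keep_ids = np.flatnonzero(~hi[1:]) + 1
    keep = np.isin(lab_pos, keep_ids)
    return np.where(keep, pos, 0.0)


def binarize_dilate(pos, mask, radius: int = 2) -> np.ndarray:
    """Binary positive mask: support of the image, dilated by a disk, inside ROI."""
    support = np.asarray(pos) > 0
    if radius > 0:
        support = morphology.dilation(support, morphology.disk(radius))
    return support & np.asarray(mask, dtype=bool)


def extract_feature(channel, pos_mask, roi_mask, params: DetectorParams) -> np.ndarray:
    """Feature channel: masked pattern channel with sharpen/blur/TV polish.

    F = channel * mask, then unsharp mask -> Gaussian blur -> TV denoise
    (each disabled at strength 0), restricted to the ROI, min-max rescaled
    to [0, 1] over ROI pixels.
    """
    f = np.asarray(channel, dtype=float) * np.asarray(pos_mask, dtype=float)
    if params.sharpen_amount > 0:
        f = filters.unsharp_mask(f, radius=params.sharpen_radius, amount=params.sharpen_amount)
    if params.gaussian_sigma > 0:
        f = filters.gaussian(f, sigma=params.gaussian_sigma)
    if params.tv_weight > 0:
        f = restoration.denoise_tv_chambolle(f, weight=params.tv_weight)
    roi = np.asarray(roi_mask, dtype=bool)
    f = np.where(roi, f, 0.0)
    vals = f[roi]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        f = np.where(roi, (f - lo) / (hi - lo), 0.0)
    else:
        f = np.zeros_like(f)
    return f


def add_undefined_channel(feature_stack, roi_mask, u: float = 0.5) -> np.ndarray:
    """Append the uncertainty channel u - mean_r F_r, clipped at 0."""
    F = np.asarray(feature_stack, dtype=float)
    extra = np.clip(u - F.mean(axis=2), 0.0, None)
    extra = np.where(np.asarray(roi_mask, dtype=bool), extra, 0.0)
    return np.concatenate([F, extra[..., None]], axis=2)


def initialize_labels(feature_stack, pixel_map: PixelMap, pattern_names) -> Annotation:
    """Per-spot argmax over feature channels; ties go to the lowest index."""
    F = np.asarray(feature_stack, dtype=float)
    fvec = pixel_map.sample(F)  # (S, C)
    labels = np.argmax(fvec, axis=1).astype(int)
    return Annotation(labels=labels, feature_vectors=fvec, pattern_names=list(pattern_names))


def _process_channel(channel, roi_mask, params: DetectorParams):
    taus = multi_otsu(channel, roi_mask, n=params.n_thresholds, nbins=params.hist_bins)
    pos, neg = split_positive(channel, taus[0])
    pos = filter_small_components(pos, params.min_component_area, params.connectivity)
    pos = reject_false_positives(pos, neg, tv_weight=params.tv_weight_reject,
                                 connectivity=params.connectivity)
    pos_mask = binarize_dilate(pos, roi_mask, radius=params.dilation_radius)
    feat = extract_feature(channel, pos_mask, roi_mask, params)
    return feat, pos_mask, taus


def detect_from_stack(pattern_image, pixel_map: PixelMap, pattern_names,
                      params: DetectorParams) -> Annotation:
    """Run segmentation through label assignment on a prepared pattern stack.

    Shared by the main detector and by posterior-image label renewal, which
    feeds the EM posterior back through these stages.
    """
    params.validate()
    P = np.asarray(pattern_image, dtype=float)
    R = P.shape[2]
    feats, masks, taus = [], [], []
    for r in range(R):
        f, m, t = _process_channel(P[..., r], pixel_map.mask, params)
        feats.append(f)
        masks.append(m)
        taus.append(t)
    F = np.stack(feats, axis=2)
    if params.include_undefined:
        F = add_undefined_channel(F, pixel_map.mask, u=params.uncertainty)
    ann = initialize_labels(F, pixel_map, pattern_names)
    ann.stack = PatternStack(
        pattern_image=P,
        feature_image=F,
        positive_masks=np.stack(masks, axis=2),
        thresholds=taus,
    )
    return ann


def detect(state, markers: Dict[str, list], params: Optional[DetectorParams] = None,
           pixel_map: Optional[PixelMap] = None) -> Annotation:
    """Full pattern detection from a SpotTable and a marker list.

    ``markers`` maps pattern name -> list of gene symbols; at most one
    pattern may be empty and is treated as the undefined pattern.
    """
    params = (params or DetectorParams()).validate()
    if state.denoised is None:
        raise ValueError("state has no denoised matrix; run denoising first")
    empties = [p for p, genes in markers.items() if not genes]
    if len(empties) > 1:
        raise ValueError(f"more than one marker-free pattern: {empties}")
    named = {p: genes for p, genes in markers.items() if genes}
    if empties:
        params = replace(params, include_undefined=True)
    if pixel_map is None:
        pixel_map = build_pixel_map(state.coords)
    channels = []
    for pattern, genes in named.items():
        rows = state.gene_index(genes)
        channels.append(create_pattern_channel(state.denoised, rows, pixel_map))
    P = np.stack(channels, axis=2)
    ann = detect_from_stack(P, pixel_map, list(named.keys()), params)
    if empties:
        # the marker-free pattern takes the undefined channel's wins
        ann.pattern_names = list(named.keys()) + [empties[0]]
    return ann
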