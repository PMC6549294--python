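"""Morphological profiling of fixed neuronal-culture fields.

Segments nuclei (DAPI), the dendrite network (MAP2) and pre-/postsynaptic
puncta (synaptophysin / PSD-95) from a multi-channel, multi-z field image and
extracts per-field descriptors in three classes (nuclei, dendrite, synapse).

Conventions
-----------
* All masks live on the 2-D pixel lattice of the field (after max projection
  or sharpest-slice selection).
* Connected components use 8-connectivity throughout.
* A synapse is operationally a presynaptic spot whose footprint overlaps a
  postsynaptic spot by at least ``min_overlap_px`` pixels (default 1); the
  synapse count is the number of distinct presynaptic spots participating in
  at least one such pair.
* Intensity-derived descriptors are flagged (they are excluded from the
  connectivity score downstream as outlier-sensitive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import frangi, gaussian
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import dilation, disk, skeletonize
from skimage.segmentation import watershed

__all__ = [
    "FieldImage",
    "SegmentationResult",
    "NucleusRecord",
    "MorphoConfig",
    "INTENSITY_DESCRIPTORS",
    "is_intensity_descriptor",
    "max_project",
    "select_sharpest_slice",
    "segment_nuclei",
    "segment_dendrites",
    "skeleton_length",
    "count_nodes",
    "classify_nuclei",
    "build_search_region",
    "filter_small_components",
    "detect_spots",
    "call_synapses",
    "count_synapses",
    "pearson_colocalization",
    "compute_morphological_descriptors",
    "segment_field",
    "profile_field",
]

#: channel roles every field must map to distinct channel indices
CHANNEL_ROLES = ("nuclear", "dendrite", "presynaptic", "postsynaptic")


@dataclass
class FieldImage:
    """One imaged field: 4-channel, multi-z pixel data plus metadata.

    Parameters
    ----------
    pixels : ndarray, shape (n_channels, n_z, H, W)
        Raw intensities (a.u.).
    channel_roles : mapping
        Maps each of ``nuclear, dendrite, presynaptic, postsynaptic`` to a
        channel index.
    pixel_size : float
        Lateral pixel size in micrometres per pixel (0.149 for the 40x
        confocal configuration this pipeline targets).
    metadata : dict
        Plate-layout keys (plate, well, field, DIV, condition, ...).
    """

    pixels: np.ndarray
    channel_roles: Mapping[str, int] = field(
        default_factory=lambda: {r: i for i, r in enumerate(CHANNEL_ROLES)}
    )
    pixel_size: float = 0.149
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be 4-D (channels, z, H, W), got shape {self.pixels.shape}"
            )
        missing = [r for r in CHANNEL_ROLES if r not in self.channel_roles]
        if missing:
            raise ValueError(f"channel_roles missing roles: {missing}")
        idx = [self.channel_roles[r] for r in CHANNEL_ROLES]
        if len(set(idx)) != len(idx):
            raise ValueError("channel_roles must map roles to distinct channels")
        if self.pixels.shape[1] < 1:
            raise ValueError("field must contain at least one z slice")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    def stack(self, role: str) -> np.ndarray:
        """Return the (n_z, H, W) stack for one channel role."""
        return self.pixels[self.channel_roles[role]]


@dataclass
class NucleusRecord:
    """Per-nucleus measurements used for the neuronal/non-neuronal decision."""

    id: int
    projected_area: float  # um^2
    circularity: float
    occupancy: float
    texture: float
    mean_intensity: float
    is_neuronal: bool
    touches_border: bool = False


@dataclass
class SegmentationResult:
    """All label masks produced for one field, on a common 2-D lattice."""

    nuclei_labels: np.ndarray
    dendrite_mask: np.ndarray
    dendrite_skeleton: np.ndarray
    search_region: np.ndarray
    pre_spots: np.ndarray
    post_spots: np.ndarray
    synapse_pairs: list[tuple[int, int, int]]
    nucleus_records: list[NucleusRecord]

    @property
    def neuronal_nucleus_ids(self) -> set[int]:
        return {r.id for r in self.nucleus_records if r.is_neuronal}

    @property
    def non_neuronal_nucleus_ids(self) -> set[int]:
        return {r.id for r in self.nucleus_records if not r.is_neuronal}


@dataclass
class MorphoConfig:
    """All user-defined thresholds of the morphological pipeline.

    Defaults are tuned on the synthetic renderer of :mod:`morphofun.synth`
    (intensities in its arbitrary units); on real data every value is expected
    to be adjusted per staining batch.
    """

    nuclear_threshold: float = 55.0
    min_nucleus_area_px: int = 120
    nucleus_split_min_distance: int = 12
    dendrite_rough_threshold: float = 80.0
    dendrite_fine_threshold: float = 0.10
    frangi_scales: tuple[float, ...] = (1.0, 2.0, 3.0)
    dendrite_dilation_px: int = 3
    nucleus_dilation_px: int = 2
    dog_sigma_narrow: float = 1.0
    dog_sigma_wide: float = 3.0
    spot_threshold: float = 40.0
    min_spot_px: int = 5  # "larger than 4 pixels" -> keep >= 5
    min_overlap_px: int = 1
    max_nucleus_area_um2: float = 40.0
    min_nucleus_circularity: float = 0.6
    min_nucleus_occupancy: float = 0.02


# ---------------------------------------------------------------------------
# projections and slice selection
# ---------------------------------------------------------------------------

def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (n_z, H, W) stack along z."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected nonempty (n_z, H, W) stack, got shape {stack.shape}")
    return stack.max(axis=0)


def select_sharpest_slice(stack: np.ndarray) -> int:
    """Index of the z slice with the highest intensity standard deviation.

    Ties resolve to the lowest index.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected nonempty (n_z, H, W) stack, got shape {stack.shape}")
    sds = stack.reshape(stack.shape[0], -1).std(axis=1)
    return int(np.argmax(sds))


# ---------------------------------------------------------------------------
# nuclei
# ---------------------------------------------------------------------------

def segment_nuclei(
    nuclear_image: np.ndarray,
    threshold: float,
    min_area_px: int = 120,
    split_touching: bool = True,
    split_min_distance: int = 12,
) -> np.ndarray:
    """Threshold-based nucleus segmentation with watershed splitting.

    Pixels at or above ``threshold`` form the foreground; touching nuclei are
    split by a watershed on the distance transform (markers at distance-map
    maxima at least ``split_min_distance`` apart); components smaller than
    ``min_area_px`` are discarded. Returns an integer label mask (0 =
    background); an empty mask is a valid result.
    """
    img = np.asarray(nuclear_image, dtype=float)
    mask = img >= threshold
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    if split_touching:
        dist = ndi.distance_transform_edt(mask)
        coords = peak_local_max(
            dist, min_distance=split_min_distance, labels=mask, exclude_border=False
        )
        if len(coords) == 0:
            labels = cc_label(mask, connectivity=2)
        else:
            markers = np.zeros(mask.shape, dtype=np.int32)
            markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
            labels = watershed(-dist, markers, mask=mask)
    else:
        labels = cc_label(mask, connectivity=2)
    # size filter + sequential relabel
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    retained = ids[counts >= min_area_px]
    keep[retained] = np.arange(1, len(retained) + 1)
    return keep[labels]


def classify_nuclei(
    nuclei_labels: np.ndarray,
    dendrite_mask: np.ndarray,
    nuclear_image: np.ndarray,
    max_area_um2: float,
    min_circularity: float,
    min_occupancy: float,
    pixel_size: float = 0.149,
    ring_dilation_px: int = 2,
) -> list[NucleusRecord]:
    """Classify each nucleus as neuronal or non-neuronal.

    A nucleus is neuronal iff all three criteria hold: projected area at most
    ``max_area_um2``, circularity (4*pi*A/P^2) at least ``min_circularity``
    and occupancy at least ``min_occupancy``. Occupancy is the fraction of the
    dilated-nucleus ring (a ``ring_dilation_px``-px dilation minus the nucleus
    footprint) covered by the dendrite mask — neurons have dendrites emanating
    through that ring, glia do not. The texture score is the variance of a
    Laplacian-of-Gaussian response inside the nucleus normalised by squared
    mean intensity, capturing the spot-like chromocenters that distinguish
    neuronal nuclei.
    """
    nuclei_labels = np.asarray(nuclei_labels)
    if nuclei_labels.shape != np.asarray(dendrite_mask).shape:
        raise ValueError("nuclei_labels and dendrite_mask must be co-registered")
    img = np.asarray(nuclear_image, dtype=float)
    log = ndi.gaussian_laplace(img, sigma=2.0)
    records: list[NucleusRecord] = []
    h, w = nuclei_labels.shape
    selem = disk(ring_dilation_px)
    for rp in regionprops(nuclei_labels, intensity_image=img):
        area_um2 = rp.area * pixel_size**2
        perim = rp.perimeter
        circ = 4.0 * np.pi * rp.area / perim**2 if perim > 0 else 1.0
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        # occupancy on a padded crop so the ring survives at the border
        pad = ring_dilation_px + 1
        r0, c0 = max(minr - pad, 0), max(minc - pad, 0)
        r1, c1 = min(maxr + pad, h), min(maxc + pad, w)
        local = nuclei_labels[r0:r1, c0:c1] == rp.label
        ring = dilation(local, selem) & ~local
        n_ring = ring.sum()
        occ = float((ring & dendrite_mask[r0:r1, c0:c1]).sum() / n_ring) if n_ring else 0.0
        inside = rp.image
        log_local = log[minr:maxr, minc:maxc][inside]
        mean_int = float(rp.intensity_mean)
        texture = float(log_local.var() / (mean_int**2 + 1e-12))
        is_neuronal = (
            area_um2 <= max_area_um2 and circ >= min_circularity and occ >= min_occupancy
        )
        records.append(
            NucleusRecord(
                id=int(rp.label),
                projected_area=float(area_um2),
                circularity=float(circ),
                occupancy=occ,
                texture=texture,
                mean_intensity=mean_int,
                is_neuronal=bool(is_neuronal),
                touches_border=bool(touches),
            )
        )
    return records


# ---------------------------------------------------------------------------
# dendrites
# ---------------------------------------------------------------------------

def segment_dendrites(
    dendrite_image: np.ndarray,
    rough_threshold: float,
    fine_threshold: float,
    frangi_scales: Sequence[float] = (1.0, 2.0, 3.0),
    min_object_px: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass dendrite segmentation: rough threshold OR Frangi vesselness.

    The mask is the union of the rough intensity threshold and a threshold on
    the Frangi tubularity response (bright ridges) at the given scales; small
    speckle components are removed and the mask is skeletonised.

    Returns ``(dendrite_mask, skeleton)`` as boolean arrays.
    """
    if len(frangi_scales) == 0:
        raise ValueError("frangi_scales must be nonempty")
    img = np.asarray(dendrite_image, dtype=float)
    rough = img >= rough_threshold
    if img.max() > 0:
        vessel = frangi(img, sigmas=tuple(frangi_scales), black_ridges=False)
        fine = vessel >= fine_threshold
    else:
        fine = np.zeros_like(rough)
    mask = rough | fine
    if min_object_px > 0 and mask.any():
        comps = cc_label(mask, connectivity=2)
        sizes = np.bincount(comps.ravel())
        sizes[0] = 0
        mask = sizes[comps] >= min_object_px
    skeleton = skeletonize(mask)
    return mask, skeleton


_ORTH_OFFSETS = ((0, 1), (1, 0))
_DIAG_OFFSETS = ((1, 1), (1, -1))


def skeleton_length(skeleton: np.ndarray, pixel_size: float = 0.149) -> float:
    """Skeleton length in micrometres with sqrt(2) weighting of diagonal steps.

    Counts each unique 8-neighbour edge between skeleton pixels once
    (orthogonal edges weight 1, diagonal weight sqrt(2)); diagonal edges that
    shortcut an existing orthogonal path are still counted — the residual
    overestimate is below the 10% tolerance this measure is used at.
    """
    sk = np.asarray(skeleton, dtype=bool)
    if not sk.any():
        return 0.0
    n_orth = sum(
        int((sk[max(dr, 0): sk.shape[0] + min(dr, 0), max(dc, 0): sk.shape[1] + min(dc, 0)]
             & sk[max(-dr, 0): sk.shape[0] + min(-dr, 0), max(-dc, 0): sk.shape[1] + min(-dc, 0)]).sum())
        for dr, dc in _ORTH_OFFSETS
    )
    n_diag = sum(
        int((sk[max(dr, 0): sk.shape[0] + min(dr, 0), max(dc, 0): sk.shape[1] + min(dc, 0)]
             & sk[max(-dr, 0): sk.shape[0] + min(-dr, 0), max(-dc, 0): sk.shape[1] + min(-dc, 0)]).sum())
        for dr, dc in _DIAG_OFFSETS
    )
    return float((n_orth + np.sqrt(2.0) * n_diag) * pixel_size)


def count_nodes(skeleton: np.ndarray) -> int:
    """Number of branch points of a 1-px skeleton.

    A junction pixel has >= 3 skeleton neighbours (8-connectivity); adjacent
    junction pixels are clustered and counted once.
    """
    sk = np.asarray(skeleton, dtype=bool)
    if not sk.any():
        return 0
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    nbrs = ndi.convolve(sk.astype(int), kernel, mode="constant")
    junctions = sk & (nbrs >= 3)
    if not junctions.any():
        return 0
    _, n = ndi.label(junctions, structure=np.ones((3, 3), dtype=int))
    return int(n)


# ---------------------------------------------------------------------------
# search region, spots, synapses
# ---------------------------------------------------------------------------

def build_search_region(
    dendrite_mask: np.ndarray,
    neuronal_nuclei_mask: np.ndarray,
    dendrite_dilation_px: int = 3,
    nucleus_dilation_px: int = 2,
) -> np.ndarray:
    """Dilated dendrite mask minus dilated neuronal-nuclei mask.

    This is the only region in which synaptic spots are detected: puncta must
    sit on or near a dendrite but away from neuronal somata.
    """
    dmask = np.asarray(dendrite_mask, dtype=bool)
    nmask = np.asarray(neuronal_nuclei_mask, dtype=bool)
    if dmask.shape != nmask.shape:
        raise ValueError("masks must be co-registered")
    dil_d = dilation(dmask, disk(dendrite_dilation_px)) if dendrite_dilation_px else dmask
    dil_n = dilation(nmask, disk(nucleus_dilation_px)) if nucleus_dilation_px else nmask
    return dil_d & ~dil_n


def filter_small_components(labels: np.ndarray, min_px: int) -> np.ndarray:
    """Drop labelled components smaller than ``min_px`` pixels; relabel 1..n.

    With ``min_px`` = 5 this implements the noise-suppression rule that only
    spots larger than 4 pixels are retained.
    """
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.astype(np.int32)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    retained = ids[counts >= min_px]
    keep[retained] = np.arange(1, len(retained) + 1)
    return keep[labels]


def detect_spots(
    channel_image: np.ndarray,
    search_region: np.ndarray,
    dog_sigma_narrow: float = 1.0,
    dog_sigma_wide: float = 3.0,
    spot_threshold: float = 40.0,
    min_spot_px: int = 5,
) -> np.ndarray:
    """Difference-of-Gaussians spot detection inside the search region.

    The image is enhanced with ``G(sigma_narrow)*I - G(sigma_wide)*I``,
    thresholded, intersected with the search region and labelled with
    8-connectivity. To minimise noise contributions only spots larger than
    4 pixels are retained (``min_spot_px`` = 5 keeps exactly those with
    >= 5 px).
    """
    if not dog_sigma_narrow < dog_sigma_wide:
        raise ValueError("dog_sigma_narrow must be smaller than dog_sigma_wide")
    img = np.asarray(channel_image, dtype=float)
    enhanced = gaussian(img, dog_sigma_narrow, preserve_range=True) - gaussian(
        img, dog_sigma_wide, preserve_range=True
    )
    mask = (enhanced >= spot_threshold) & np.asarray(search_region, dtype=bool)
    labels = cc_label(mask, connectivity=2)
    return filter_small_components(labels, min_spot_px)


def call_synapses(
    pre_spots: np.ndarray,
    post_spots: np.ndarray,
    min_overlap_px: int = 1,
) -> list[tuple[int, int, int]]:
    """All (pre_id, post_id, overlap_px) pairs overlapping by >= min_overlap_px.

    Works on co-registered integer label masks. The overlap of every
    co-occurring label pair is counted in one pass over the pixels where both
    masks are foreground.
    """
    pre = np.asarray(pre_spots)
    post = np.asarray(post_spots)
    if pre.shape != post.shape:
        raise ValueError("label masks must be co-registered")
    both = (pre > 0) & (post > 0)
    if not both.any():
        return []
    pairs = np.stack([pre[both], post[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return [
        (int(p), int(q), int(c))
        for (p, q), c in zip(uniq, counts)
        if c >= min_overlap_px
    ]


def count_synapses(synapse_pairs: Sequence[tuple[int, int, int]]) -> int:
    """Synapse count: distinct presynaptic spots with >= 1 overlapping partner."""
    return len({p for p, _, _ in synapse_pairs})


def pearson_colocalization(
    pre_image: np.ndarray,
    post_image: np.ndarray,
    region: np.ndarray,
) -> float:
    """Pearson correlation of pre/post intensities over the region pixels.

    Intensity-based colocalization complement to the object-overlap synapse
    call. A constant channel (zero variance) yields 0 by convention.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    x = np.asarray(pre_image, dtype=float)[region]
    y = np.asarray(post_image, dtype=float)[region]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

#: descriptors computed from raw fluorescence intensity; excluded from the
#: connectivity score downstream (outlier-sensitive)
INTENSITY_DESCRIPTORS = frozenset(
    {
        "nuclei_mean_intensity",
        "dendrite_mean_intensity",
        "pre_mean_intensity",
        "post_mean_intensity",
    }
)


def is_intensity_descriptor(name: str) -> bool:
    """True for descriptors derived from raw intensity values."""
    return name in INTENSITY_DESCRIPTORS or "intensity" in name


def compute_morphological_descriptors(
    seg: SegmentationResult,
    field_image: FieldImage,
) -> dict[str, float]:
    """Per-field morphological descriptor vector (nuclei, dendrite, synapse).

    Spot and synapse densities are reported both per 100 um of skeleton
    length and per um^2 of dendrite-mask area. When the field has no dendrite
    mask the densities are undefined and emitted as NaN (such fields are
    dropped by the downstream field filter).
    """
    ps = field_image.pixel_size
    out: dict[str, float] = {}

    recs = seg.nucleus_records
    interior = [r for r in recs if not r.touches_border]
    shape_recs = interior if interior else recs  # border nuclei counted, not measured
    out["nuclei_count"] = float(len(recs))
    out["neuronal_count"] = float(sum(r.is_neuronal for r in recs))
    out["non_neuronal_count"] = out["nuclei_count"] - out["neuronal_count"]
    out["neuronal_fraction"] = (
        out["neuronal_count"] / out["nuclei_count"] if recs else np.nan
    )
    out["nuclei_mean_area"] = (
        float(np.mean([r.projected_area for r in shape_recs])) if recs else np.nan
    )
    out["nuclei_mean_circularity"] = (
        float(np.mean([r.circularity for r in shape_recs])) if recs else np.nan
    )
    out["nuclei_mean_texture"] = (
        float(np.mean([r.texture for r in shape_recs])) if recs else np.nan
    )
    out["nuclei_mean_intensity"] = (
        float(np.mean([r.mean_intensity for r in recs])) if recs else np.nan
    )

    dmask = seg.dendrite_mask
    area_px = float(dmask.sum())
    area_um2 = area_px * ps**2
    length_um = skeleton_length(seg.dendrite_skeleton, ps)
    out["dendrite_density"] = area_px / dmask.size
    out["skeleton_length_um"] = length_um
    out["node_count"] = float(count_nodes(seg.dendrite_skeleton))
    out["dendrite_mean_width_um"] = area_um2 / length_um if length_um > 0 else np.nan
    dend_img = max_project(field_image.stack("dendrite"))
    out["dendrite_mean_intensity"] = (
        float(dend_img[dmask].mean()) if area_px > 0 else np.nan
    )

    n_pre = int(seg.pre_spots.max())
    n_post = int(seg.post_spots.max())
    n_syn = count_synapses(seg.synapse_pairs)
    out["pre_count"] = float(n_pre)
    out["post_count"] = float(n_post)
    out["synapse_count"] = float(n_syn)
    if length_um > 0 and area_um2 > 0:
        per100 = 100.0 / length_um
        out["pre_density_per_100um"] = n_pre * per100
        out["post_density_per_100um"] = n_post * per100
        out["synapse_density_per_100um"] = n_syn * per100
        out["pre_density_per_area"] = n_pre / area_um2
        out["post_density_per_area"] = n_post / area_um2
        out["synapse_density_per_area"] = n_syn / area_um2
    else:
        for k in (
            "pre_density_per_100um",
            "post_density_per_100um",
            "synapse_density_per_100um",
            "pre_density_per_area",
            "post_density_per_area",
            "synapse_density_per_area",
        ):
            out[k] = np.nan

    pre_stack = field_image.stack("presynaptic")
    post_stack = field_image.stack("postsynaptic")
    z_pre = select_sharpest_slice(pre_stack)
    pre_img, post_img = pre_stack[z_pre], post_stack[z_pre]
    for prefix, spots, img in (("pre", seg.pre_spots, pre_img), ("post", seg.post_spots, post_img)):
        n = int(spots.max())
        if n:
            sizes = np.bincount(spots[spots > 0])[1:]
            out[f"{prefix}_mean_area_um2"] = float(sizes.mean()) * ps**2
            out[f"{prefix}_mean_intensity"] = float(img[spots > 0].mean())
        else:
            out[f"{prefix}_mean_area_um2"] = np.nan
            out[f"{prefix}_mean_intensity"] = np.nan
    if seg.search_region.any():
        out["pearson_colocalization"] = pearson_colocalization(
            pre_img, post_img, seg.search_region
        )
    else:
        out["pearson_colocalization"] = np.nan
    return out


# ---------------------------------------------------------------------------
# full-field pipeline
# ---------------------------------------------------------------------------

def segment_field(field_image: FieldImage, config: MorphoConfig | None = None) -> SegmentationResult:
    """Run the full morphological segmentation pipeline on one field.

    Steps: max-project DAPI and MAP2; segment nuclei and dendrites; classify
    nuclei; build the search region; DoG spot detection on the sharpest
    pre/post slices; >= 1-px overlap synapse calling.
    """
    cfg = config or MorphoConfig()
    nuc_img = max_project(field_image.stack("nuclear"))
    dend_img = max_project(field_image.stack("dendrite"))
    nuclei = segment_nuclei(
        nuc_img,
        cfg.nuclear_threshold,
        min_area_px=cfg.min_nucleus_area_px,
        split_min_distance=cfg.nucleus_split_min_distance,
    )
    dmask, skel = segment_dendrites(
        dend_img,
        cfg.dendrite_rough_threshold,
        cfg.dendrite_fine_threshold,
        cfg.frangi_scales,
    )
    records = classify_nuclei(
        nuclei,
        dmask,
        nuc_img,
        cfg.max_nucleus_area_um2,
        cfg.min_nucleus_circularity,
        cfg.min_nucleus_occupancy,
        pixel_size=field_image.pixel_size,
        ring_dilation_px=cfg.nucleus_dilation_px,
    )
    neuronal_ids = [r.id for r in records if r.is_neuronal]
    neuronal_mask = np.isin(nuclei, neuronal_ids)
    region = build_search_region(
        dmask, neuronal_mask, cfg.dendrite_dilation_px, cfg.nucleus_dilation_px
    )
    pre_stack = field_image.stack("presynaptic")
    post_stack = field_image.stack("postsynaptic")
    z = select_sharpest_slice(pre_stack)
    pre_spots = detect_spots(
        pre_stack[z], region, cfg.dog_sigma_narrow, cfg.dog_sigma_wide,
        cfg.spot_threshold, cfg.min_spot_px,
    )
    post_spots = detect_spots(
        post_stack[z], region, cfg.dog_sigma_narrow, cfg.dog_sigma_wide,
        cfg.spot_threshold, cfg.min_spot_px,
    )
    pairs = call_synapses(pre_spots, post_spots, cfg.min_overlap_px)
    return SegmentationResult(
        nuclei_labels=nuclei,
        dendrite_mask=dmask,
        dendrite_skeleton=skel,
        search_region=region,
        pre_spots=pre_spots,
        post_spots=post_spots,
        synapse_pairs=pairs,
        nucleus_records=records,
    )


def profile_field(
    field_image: FieldImage, config: MorphoConfig | None = None
) -> dict[str, float]:
    """Segment one field and return its descriptor vector plus metadata."""
    seg = segment_field(field_image, config)
    desc = compute_morphological_descriptors(seg, field_image)
    row = dict(field_image.metadata)
    row.update(desc)
    return row
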