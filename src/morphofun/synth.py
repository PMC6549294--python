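"""Synthetic fluorescence-microscopy ground truth for the profiling pipeline.

Renders multi-channel, multi-z field images (nuclear / dendrite / pre- /
postsynaptic channels), calcium time-lapse recordings and per-well descriptor
tables with fully known ground truth, so every downstream stage can be tested
without microscope data.

Renderer summary
----------------
* Two nucleus populations: neuronal (small discs with bright internal
  chromocenter-like spots) and glial (large, flat discs).
* Dendrites as random branched trees grown from neuronal somata, rendered as
  tubes of Gaussian cross-section (sigma ~ 2 px).
* Pre/post puncta as 2-D Gaussians placed on dendrite centerlines. True
  synapses place a postsynaptic punctum centre within 1 px of a presynaptic
  one; non-synaptic puncta keep >= 8 px from any opposite-channel punctum, so
  the >= 1 px overlap ground truth is unambiguous.
* Per-z defocus (focus weight + blur), Poisson shot noise on the signal plus
  additive Gaussian read noise.

All randomness comes from one ``numpy.random.Generator`` seeded per call;
identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .morpho import CHANNEL_ROLES, FieldImage

__all__ = [
    "FieldParams",
    "FieldTruth",
    "MaturationModel",
    "CalciumParams",
    "CalciumTruth",
    "generate_field",
    "generate_plate",
    "generate_calcium",
    "simulate_descriptor_table",
    "DESCRIPTOR_CLASSES",
]


class ParameterError(ValueError):
    """A generator parameter is outside the renderable range."""


# ---------------------------------------------------------------------------
# parameters and truth records
# ---------------------------------------------------------------------------

@dataclass
class FieldParams:
    """Tunable parameters of the synthetic field renderer."""

    shape: tuple[int, int, int] = (3, 512, 512)  # (n_z, H, W)
    pixel_size: float = 0.149
    n_neuronal: int = 8
    n_glial: int = 3
    neuronal_radius: tuple[float, float] = (16.0, 20.0)
    glial_radius: tuple[float, float] = (28.0, 34.0)
    n_pre_spots: int = 55
    n_post_spots: int = 55
    n_true_synapses: int = 30
    dendrite_length_scale: float = 1.0
    n_primary_branches: int = 3
    dendrite_sigma_px: float = 2.0
    punctum_sigma_px: float = 1.4
    nuclear_amp: float = 130.0
    glial_amp: float = 110.0
    dendrite_amp: float = 160.0
    punctum_amp: float = 180.0
    background: float = 10.0
    read_noise_sd: float = 3.0
    noise: bool = True

    def validate(self) -> None:
        nz, h, w = self.shape
        if h < 256 or w < 256:
            raise ParameterError(f"shape: field must be at least 256x256, got {h}x{w}")
        if nz < 1:
            raise ParameterError("shape: need at least one z slice")
        for name in ("n_neuronal", "n_glial", "n_pre_spots", "n_post_spots", "n_true_synapses"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name}: counts must be >= 0")
        if self.n_true_synapses > min(self.n_pre_spots, self.n_post_spots):
            raise ParameterError(
                "n_true_synapses: must not exceed min(n_pre_spots, n_post_spots)"
            )
        if self.n_true_synapses > 0 and self.n_neuronal == 0:
            raise ParameterError("n_neuronal: puncta require dendrites to sit on")
        if not self.pixel_size > 0:
            raise ParameterError("pixel_size: must be positive")


@dataclass
class FieldTruth:
    """Ground truth of one rendered field."""

    n_neuronal_nuclei: int
    n_glial_nuclei: int
    dendrite_total_length: float  # um
    n_branch_nodes: int
    n_pre_spots: int
    n_post_spots: int
    n_true_synapses: int
    pixel_size: float
    seed: int
    nucleus_centers: list[tuple[float, float]] = field(default_factory=list)
    pre_centers: list[tuple[float, float]] = field(default_factory=list)
    post_centers: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.n_neuronal_nuclei, self.n_glial_nuclei, self.n_branch_nodes,
            self.n_pre_spots, self.n_post_spots, self.n_true_synapses,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all truth counts must be >= 0")
        if self.n_true_synapses > min(self.n_pre_spots, self.n_post_spots):
            raise ValueError("n_true_synapses exceeds available pre/post spots")

    def to_dict(self) -> dict:
        return {
            "n_neuronal_nuclei": self.n_neuronal_nuclei,
            "n_glial_nuclei": self.n_glial_nuclei,
            "dendrite_total_length": self.dendrite_total_length,
            "n_branch_nodes": self.n_branch_nodes,
            "n_pre_spots": self.n_pre_spots,
            "n_post_spots": self.n_post_spots,
            "n_true_synapses": self.n_true_synapses,
            "pixel_size": self.pixel_size,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# low-level rendering helpers
# ---------------------------------------------------------------------------

def _place_centers(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    shape: tuple[int, int],
    existing: list[tuple[float, float, float]],
    margin: float,
    clearance: float = 10.0,
    max_tries: int = 4000,
) -> list[tuple[float, float]]:
    """Rejection-sample n disc centres with pairwise clearance."""
    h, w = shape
    placed: list[tuple[float, float]] = []
    for i in range(n):
        r = radii[i]
        for _ in range(max_tries):
            y = rng.uniform(r + margin, h - r - margin)
            x = rng.uniform(r + margin, w - r - margin)
            ok = all(
                math.hypot(y - cy, x - cx) > r + cr + clearance
                for cy, cx, cr in existing
            )
            if ok:
                placed.append((y, x))
                existing.append((y, x, r))
                break
        else:
            raise ParameterError(
                "n_neuronal/n_glial: could not place all nuclei in the field"
            )
    return placed


def _soft_disc(canvas: np.ndarray, cy: float, cx: float, radius: float, amp: float) -> None:
    """Add a disc with a ~1.5 px soft edge."""
    h, w = canvas.shape
    r_ext = int(radius + 5)
    y0, y1 = max(int(cy) - r_ext, 0), min(int(cy) + r_ext + 1, h)
    x0, x1 = max(int(cx) - r_ext, 0), min(int(cx) + r_ext + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    canvas[y0:y1, x0:x1] += amp / (1.0 + np.exp((d - radius) / 1.5))


def _add_gaussian(canvas: np.ndarray, cy: float, cx: float, sigma: float, amp: float) -> None:
    h, w = canvas.shape
    r_ext = int(4 * sigma + 2)
    y0, y1 = max(int(cy) - r_ext, 0), min(int(cy) + r_ext + 1, h)
    x0, x1 = max(int(cx) - r_ext, 0), min(int(cx) + r_ext + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] += amp * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)
    )


def _grow_tree(
    rng: np.random.Generator,
    start: tuple[float, float],
    direction: float,
    length: float,
    shape: tuple[int, int],
    depth: int = 0,
    max_depth: int = 2,
    branch_prob: float = 0.012,
) -> tuple[list[tuple[float, float]], float, int]:
    """Grow one curvature-perturbed branch; returns (points, length_px, n_nodes)."""
    h, w = shape
    step = 2.0
    pts: list[tuple[float, float]] = []
    total = 0.0
    nodes = 0
    y, x = start
    travelled = 0.0
    while travelled < length:
        direction += rng.normal(0.0, 0.12)
        y += step * math.sin(direction)
        x += step * math.cos(direction)
        if not (6.0 <= y < h - 6.0 and 6.0 <= x < w - 6.0):
            break
        pts.append((y, x))
        total += step
        travelled += step
        if (
            depth < max_depth
            and travelled > 30.0
            and length - travelled > 30.0
            and rng.random() < branch_prob
        ):
            nodes += 1
            side = 1.0 if rng.random() < 0.5 else -1.0
            sub_pts, sub_len, sub_nodes = _grow_tree(
                rng, (y, x), direction + side * rng.uniform(0.6, 1.1),
                (length - travelled) * 0.7, shape, depth + 1, max_depth, branch_prob,
            )
            pts.extend(sub_pts)
            total += sub_len
            nodes += sub_nodes
    return pts, total, nodes


def _select_sites(
    rng: np.random.Generator,
    candidates: np.ndarray,
    n: int,
    keepout: list[tuple[np.ndarray, float]],
    self_sep: float,
) -> list[tuple[float, float]]:
    """Greedy selection of n candidate points honouring separation constraints.

    ``keepout`` is a list of (points array, min distance) pairs; selected
    points additionally stay ``self_sep`` apart from one another.
    """
    if n == 0:
        return []
    order = rng.permutation(len(candidates))
    chosen: list[tuple[float, float]] = []
    for idx in order:
        p = candidates[idx]
        ok = all(
            len(pts) == 0 or np.min(np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1])) >= dmin
            for pts, dmin in keepout
        )
        if ok and all(math.hypot(c[0] - p[0], c[1] - p[1]) >= self_sep for c in chosen):
            chosen.append((float(p[0]), float(p[1])))
            if len(chosen) == n:
                return chosen
    raise ParameterError(
        "n_pre_spots/n_post_spots/n_true_synapses: not enough dendrite length "
        "to place the requested puncta with the required separations"
    )


# per-z focus weights and defocus blur for a 3-slice stack; the middle slice
# is in focus (highest contrast), so sharpest-slice selection picks index 1
_FOCUS_W = (0.55, 1.0, 0.7)
_FOCUS_BLUR = (1.6, 0.0, 1.1)


def _render_stack(
    rng: np.random.Generator,
    signal: np.ndarray,
    n_z: int,
    background: float,
    read_noise_sd: float,
    noise: bool,
) -> np.ndarray:
    """Turn a 2-D in-focus signal into a defocused z-stack with noise."""
    ws = [_FOCUS_W[i % 3] for i in range(n_z)] if n_z != 3 else list(_FOCUS_W)
    blurs = [_FOCUS_BLUR[i % 3] for i in range(n_z)] if n_z != 3 else list(_FOCUS_BLUR)
    if n_z == 1:
        ws, blurs = [1.0], [0.0]
    out = np.empty((n_z, *signal.shape), dtype=np.float32)
    for z in range(n_z):
        s = ndi.gaussian_filter(signal, blurs[z]) if blurs[z] > 0 else signal
        plane = s * ws[z] + background
        if noise:
            plane = rng.poisson(np.clip(plane, 0.0, None)).astype(np.float32)
            plane = plane + rng.normal(0.0, read_noise_sd, size=plane.shape)
        out[z] = plane
    return out


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------

def generate_field(
    params: FieldParams | None = None,
    seed: int = 0,
    **overrides,
) -> tuple[FieldImage, FieldTruth]:
    """Render one 4-channel, multi-z synthetic field with known ground truth.

    Returns the :class:`~morphofun.morpho.FieldImage` (channel order nuclear,
    dendrite, presynaptic, postsynaptic) and the :class:`FieldTruth` recording
    all counts and placements. With ``noise=False`` the render is exact: a
    correctly configured downstream pipeline recovers every count.
    """
    p = replace(params or FieldParams(), **overrides) if (params or overrides) else FieldParams()
    p.validate()
    # placement is rejection-sampled; an unlucky dendrite layout can leave too
    # few valid puncta sites, so retry the whole render on a seed-derived
    # substream before declaring the parameters unrenderable
    last_exc: ParameterError | None = None
    for attempt in range(5):
        rng = np.random.default_rng(seed if attempt == 0 else [seed, attempt])
        try:
            return _render_field(p, rng, seed)
        except ParameterError as exc:
            last_exc = exc
    raise last_exc


def _render_field(
    p: FieldParams, rng: np.random.Generator, seed: int
) -> tuple[FieldImage, FieldTruth]:
    n_z, h, w = p.shape
    shape2d = (h, w)

    # --- nuclei ---
    existing: list[tuple[float, float, float]] = []
    neuronal_r = rng.uniform(*p.neuronal_radius, size=p.n_neuronal)
    glial_r = rng.uniform(*p.glial_radius, size=p.n_glial)
    neuronal_centers = _place_centers(rng, p.n_neuronal, neuronal_r, shape2d, existing, margin=6.0)
    glial_centers = _place_centers(rng, p.n_glial, glial_r, shape2d, existing, margin=6.0)
    nuc = np.zeros(shape2d, dtype=np.float64)
    for (cy, cx), r in zip(neuronal_centers, neuronal_r):
        _soft_disc(nuc, cy, cx, r, p.nuclear_amp)
        for _ in range(6):  # chromocenter-like internal texture
            ty = cy + rng.uniform(-0.55, 0.55) * r
            tx = cx + rng.uniform(-0.55, 0.55) * r
            _add_gaussian(nuc, ty, tx, 2.2, 0.7 * p.nuclear_amp)
    for (cy, cx), r in zip(glial_centers, glial_r):
        _soft_disc(nuc, cy, cx, r, p.glial_amp)

    # --- dendrites ---
    centerline_pts: list[tuple[float, float]] = []
    total_len_px = 0.0
    n_nodes = 0
    for (cy, cx), r in zip(neuronal_centers, neuronal_r):
        angles = rng.uniform(0, 2 * np.pi) + np.arange(p.n_primary_branches) * (
            2 * np.pi / max(p.n_primary_branches, 1)
        )
        for ang in angles:
            start = (cy + 0.8 * r * math.sin(ang), cx + 0.8 * r * math.cos(ang))
            length = p.dendrite_length_scale * rng.uniform(110.0, 170.0)
            pts, seg_len, seg_nodes = _grow_tree(rng, start, float(ang), length, shape2d)
            centerline_pts.extend(pts)
            total_len_px += seg_len
            n_nodes += seg_nodes
    dend = np.zeros(shape2d, dtype=np.float64)
    if centerline_pts:
        cl = np.zeros(shape2d, dtype=bool)
        arr = np.asarray(centerline_pts)
        cl[np.clip(arr[:, 0].round().astype(int), 0, h - 1),
           np.clip(arr[:, 1].round().astype(int), 0, w - 1)] = True
        d_to_line = ndi.distance_transform_edt(~cl)
        dend = p.dendrite_amp * np.exp(-(d_to_line**2) / (2.0 * p.dendrite_sigma_px**2))

    # --- puncta on dendrites ---
    pre_centers: list[tuple[float, float]] = []
    post_centers: list[tuple[float, float]] = []
    if p.n_pre_spots or p.n_post_spots:
        if not centerline_pts:
            raise ParameterError("n_pre_spots/n_post_spots: no dendrites to place puncta on")
        cand = np.asarray(centerline_pts)
        # candidates must clear every nucleus (search region excludes somata)
        for (cy, cx), r in zip(
            neuronal_centers + glial_centers, np.concatenate([neuronal_r, glial_r])
        ):
            keep = np.hypot(cand[:, 0] - cy, cand[:, 1] - cx) > r + 7.0
            cand = cand[keep]
        keep = (
            (cand[:, 0] > 10) & (cand[:, 0] < h - 10)
            & (cand[:, 1] > 10) & (cand[:, 1] < w - 10)
        )
        cand = cand[keep]
        if len(cand) == 0:
            raise ParameterError("no valid dendrite positions for puncta")

        syn_sites = _select_sites(rng, cand, p.n_true_synapses, [], self_sep=9.0)
        for sy, sx in syn_sites:
            pre_centers.append((sy, sx))
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.0, 1.0)
            post_centers.append((sy + rad * math.sin(ang), sx + rad * math.cos(ang)))
        pre_arr = np.asarray(pre_centers).reshape(-1, 2)
        post_arr = np.asarray(post_centers).reshape(-1, 2)
        pre_only = _select_sites(
            rng, cand, p.n_pre_spots - p.n_true_synapses,
            [(pre_arr, 9.0), (post_arr, 8.0)], self_sep=9.0,
        )
        pre_centers.extend(pre_only)
        pre_arr = np.asarray(pre_centers).reshape(-1, 2)
        post_only = _select_sites(
            rng, cand, p.n_post_spots - p.n_true_synapses,
            [(post_arr, 9.0), (pre_arr, 8.0)], self_sep=9.0,
        )
        post_centers.extend(post_only)
    pre = np.zeros(shape2d, dtype=np.float64)
    post = np.zeros(shape2d, dtype=np.float64)
    for cy, cx in pre_centers:
        _add_gaussian(pre, cy, cx, p.punctum_sigma_px, p.punctum_amp)
    for cy, cx in post_centers:
        _add_gaussian(post, cy, cx, p.punctum_sigma_px, p.punctum_amp)

    pixels = np.stack(
        [
            _render_stack(rng, sig, n_z, p.background, p.read_noise_sd, p.noise)
            for sig in (nuc, dend, pre, post)
        ]
    )
    image = FieldImage(
        pixels=pixels,
        channel_roles={r: i for i, r in enumerate(CHANNEL_ROLES)},
        pixel_size=p.pixel_size,
        metadata={"seed": seed},
    )
    truth = FieldTruth(
        n_neuronal_nuclei=p.n_neuronal,
        n_glial_nuclei=p.n_glial,
        dendrite_total_length=total_len_px * p.pixel_size,
        n_branch_nodes=n_nodes,
        n_pre_spots=p.n_pre_spots,
        n_post_spots=p.n_post_spots,
        n_true_synapses=p.n_true_synapses,
        pixel_size=p.pixel_size,
        seed=seed,
        nucleus_centers=[*neuronal_centers, *glial_centers],
        pre_centers=pre_centers,
        post_centers=post_centers,
    )
    return image, truth


# ---------------------------------------------------------------------------
# maturation model and plates
# ---------------------------------------------------------------------------

@dataclass
class MaturationModel:
    """Deterministic ramps of truth parameters over pseudo culture age (DIV).

    Directions emulate the maturation of primary cultures: dendrite density
    and synapse density increase (the latter saturating), neuron count slowly
    decreases, and calcium synchrony switches on after an onset age.
    """

    div_levels: tuple[int, ...] = (3, 7, 10, 14, 18)
    n_neuronal_start: float = 10.0
    n_neuronal_end: float = 7.0
    n_glial: int = 3
    dendrite_scale_range: tuple[float, float] = (0.55, 1.25)
    max_synapses: int = 38
    synapse_halfway_div: float = 8.0
    synchrony_onset_div: float = 10.0
    synchrony_slope: float = 2.5

    def __post_init__(self) -> None:
        if len(self.div_levels) == 0:
            raise ValueError("div_levels must be nonempty")

    # -- continuous ramps (monotone by construction) --
    def neuron_count_ramp(self, div: float) -> float:
        lo, hi = min(self.div_levels), max(self.div_levels)
        t = (div - lo) / max(hi - lo, 1e-12)
        return self.n_neuronal_start + t * (self.n_neuronal_end - self.n_neuronal_start)

    def dendrite_scale_ramp(self, div: float) -> float:
        lo, hi = self.dendrite_scale_range
        return lo + (hi - lo) * (1.0 - math.exp(-div / 9.0)) / (1.0 - math.exp(-48 / 9.0))

    def synapse_ramp(self, div: float) -> float:
        """Saturating increase of the true synapse count."""
        return self.max_synapses * div**2 / (div**2 + self.synapse_halfway_div**2)

    def synchrony_ramp(self, div: float) -> float:
        return 1.0 / (1.0 + math.exp(-(div - self.synchrony_onset_div) / self.synchrony_slope))

    def ramps(self) -> dict[str, tuple[Callable[[float], float], int]]:
        """Named ramp functions with their expected monotone direction (+1/-1)."""
        return {
            "neuron_count": (self.neuron_count_ramp, -1),
            "dendrite_scale": (self.dendrite_scale_ramp, +1),
            "synapse_count": (self.synapse_ramp, +1),
            "synchrony": (self.synchrony_ramp, +1),
        }

    def truth_params(self, div: float) -> dict:
        """Field-renderer overrides for one pseudo-age."""
        n_syn = int(round(self.synapse_ramp(div)))
        return {
            "n_neuronal": int(round(self.neuron_count_ramp(div))),
            "n_glial": self.n_glial,
            "dendrite_length_scale": self.dendrite_scale_ramp(div),
            "n_true_synapses": n_syn,
            "n_pre_spots": n_syn + int(round(18 * self.synapse_ramp(div) / self.max_synapses)) + 6,
            "n_post_spots": n_syn + int(round(18 * self.synapse_ramp(div) / self.max_synapses)) + 6,
        }


def generate_plate(
    maturation: MaturationModel | None = None,
    n_wells_per_div: int = 3,
    n_fields_per_well: int = 2,
    seed: int = 0,
    base_params: FieldParams | None = None,
    plate: str = "P1",
    cell_type: str = "cortical",
    condition: str = "control",
    experiment: str = "E1",
    replicate: int = 1,
) -> tuple[list[tuple[FieldImage, FieldTruth]], pd.DataFrame]:
    """Render a synthetic plate: wells across pseudo-ages, fields per well.

    Returns the list of (image, truth) pairs and a metadata table with one
    row per field (plate, well, field, DIV, cell_type, condition, dose,
    experiment, replicate, seed). Field seeds derive deterministically from
    ``seed``.
    """
    mm = maturation or MaturationModel()
    base = base_params or FieldParams()
    records = []
    fields_out: list[tuple[FieldImage, FieldTruth]] = []
    well_idx = 0
    field_counter = 0
    seen_keys: set[tuple[str, int]] = set()
    for div in mm.div_levels:
        overrides = mm.truth_params(div)
        for _ in range(n_wells_per_div):
            well = f"{chr(ord('A') + well_idx // 12)}{well_idx % 12 + 1:02d}"
            well_idx += 1
            for f in range(1, n_fields_per_well + 1):
                key = (well, f)
                if key in seen_keys:
                    raise ValueError(f"duplicate well/field key {key}")
                seen_keys.add(key)
                fseed = (seed * 100003 + field_counter * 7919 + 1) % (2**31)
                field_counter += 1
                img, truth = generate_field(base, seed=fseed, **overrides)
                img.metadata.update(
                    plate=plate, well=well, field=f, DIV=div, cell_type=cell_type,
                    condition=condition, dose=0.0, experiment=experiment,
                    replicate=replicate, seed=fseed,
                )
                fields_out.append((img, truth))
                records.append(dict(img.metadata))
    return fields_out, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# calcium recordings
# ---------------------------------------------------------------------------

@dataclass
class CalciumParams:
    """Parameters of the synthetic calcium recording generator."""

    n_neurons: int = 10
    frame_rate: float = 2.0  # Hz
    duration_s: float = 180.0
    burst_rate_hz: float = 0.05
    synchrony_fraction: float = 0.5
    noise_sd: float = 2.0
    baseline: float = 50.0
    amplitude: float = 60.0
    tau_decay_s: float = 1.5  # GCaMP6f-like fast indicator
    shape: tuple[int, int] = (128, 128)
    soma_radius: tuple[float, float] = (5.0, 7.0)
    n_z_ref: int = 3
    min_burst_gap_s: float = 3.0

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise ParameterError("n_neurons: must be >= 1")
        if not 0.0 <= self.synchrony_fraction <= 1.0:
            raise ParameterError("synchrony_fraction: must lie in [0, 1]")
        if self.frame_rate * self.duration_s < 2:
            raise ParameterError("duration_s x frame_rate must give at least 2 frames")


@dataclass
class CalciumTruth:
    """Ground truth of one synthetic recording."""

    n_neurons: int
    frame_rate: float
    duration_s: float
    burst_times: list[np.ndarray]
    network_event_times: np.ndarray
    synchrony_fraction: float
    noise_sd: float
    seed: int

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.duration_s))


def _thin(times: np.ndarray, min_gap: float) -> np.ndarray:
    """Sort and drop events closer than min_gap to the previous kept one."""
    times = np.sort(times)
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap:
            kept.append(float(t))
    return np.asarray(kept)


def generate_calcium(
    params: CalciumParams | None = None,
    seed: int = 0,
    **overrides,
):
    """Render a synthetic calcium recording with known burst trains.

    Returns ``(CalciumRecording, CalciumTruth)``. Each neuron's burst train
    mixes shared network events (adopted with probability
    ``synchrony_fraction``) with an independent Poisson train at rate
    ``burst_rate_hz * (1 - synchrony_fraction)``, keeping the expected burst
    rate constant across synchrony levels; at synchrony 1 every neuron fires
    exactly the network train. Each burst injects an instantaneous-rise,
    exponential-decay transient (tau ``tau_decay_s``).
    """
    from .calcium import CalciumRecording  # local import avoids a cycle

    p = replace(params or CalciumParams(), **overrides) if (params or overrides) else CalciumParams()
    p.validate()
    rng = np.random.default_rng(seed)
    n_frames = int(round(p.frame_rate * p.duration_s))
    # auto-expand the field so dense populations still pack with clearance
    d = 2 * p.soma_radius[1] + 4.0
    min_side = int(math.ceil(math.sqrt(p.n_neurons) * d * 1.6))
    h = max(p.shape[0], min_side)
    w = max(p.shape[1], min_side)
    t = np.arange(n_frames) / p.frame_rate

    # somata placement
    radii = rng.uniform(*p.soma_radius, size=p.n_neurons)
    existing: list[tuple[float, float, float]] = []
    try:
        centers = _place_centers(
            rng, p.n_neurons, radii, (h, w), existing, margin=4.0, clearance=4.0
        )
    except ParameterError as exc:
        raise ParameterError(f"n_neurons: {exc}") from exc

    # burst trains
    margin = 4.0
    n_net = rng.poisson(p.burst_rate_hz * (p.duration_s - 2 * margin))
    network = _thin(
        rng.uniform(margin, p.duration_s - margin, size=max(n_net, 1)), p.min_burst_gap_s
    )
    burst_times: list[np.ndarray] = []
    s = p.synchrony_fraction
    for _ in range(p.n_neurons):
        if s >= 1.0:
            times = network.copy()
        else:
            adopted = network[rng.random(len(network)) < s]
            n_own = rng.poisson(p.burst_rate_hz * (1.0 - s) * (p.duration_s - 2 * margin))
            own = rng.uniform(margin, p.duration_s - margin, size=n_own)
            times = _thin(np.concatenate([adopted, own]), p.min_burst_gap_s)
        burst_times.append(times)

    # traces and frames
    traces = np.zeros((p.n_neurons, n_frames))
    for i, times in enumerate(burst_times):
        for tb in times:
            mask = t >= tb
            traces[i, mask] += np.exp(-(t[mask] - tb) / p.tau_decay_s)
    frames = np.full((n_frames, h, w), 0.2 * p.baseline, dtype=np.float32)
    soma_masks = []
    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx), r in zip(centers, radii):
        soma_masks.append(np.hypot(yy - cy, xx - cx) <= r)
    for i, m in enumerate(soma_masks):
        frames[:, m] = (p.baseline + p.amplitude * traces[i])[:, None]
    if p.noise_sd > 0:
        frames = frames + rng.normal(0.0, p.noise_sd, size=frames.shape).astype(np.float32)

    # reference stack (nuclear reporter)
    ref_sig = np.zeros((h, w))
    for (cy, cx), r in zip(centers, radii):
        _soft_disc(ref_sig, cy, cx, r, 120.0)
    ref = _render_stack(
        rng, ref_sig, p.n_z_ref, background=8.0,
        read_noise_sd=min(p.noise_sd, 2.0), noise=p.noise_sd > 0,
    )

    rec = CalciumRecording(frames=frames, reference_stack=ref, frame_rate=p.frame_rate)
    truth = CalciumTruth(
        n_neurons=p.n_neurons,
        frame_rate=p.frame_rate,
        duration_s=p.duration_s,
        burst_times=burst_times,
        network_event_times=network,
        synchrony_fraction=s,
        noise_sd=p.noise_sd,
        seed=seed,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# direct descriptor-table simulation
# ---------------------------------------------------------------------------

#: representative descriptor set for table-level simulations, by class.
#: (name, direction of the maturation trend: +1 up, -1 down, 0 flat,
#:  baseline value, full-maturation change)
DESCRIPTOR_CLASSES: dict[str, list[tuple[str, int, float, float]]] = {
    "nuclei": [
        ("neuronal_count", -1, 10.0, -3.0),
        ("non_neuronal_count", 0, 3.0, 0.0),
        ("nuclei_mean_area", 0, 30.0, 0.0),
        ("nuclei_mean_texture", 0, 0.05, 0.0),
        ("nuclei_mean_intensity", +1, 800.0, 250.0),
    ],
    "dendrite": [
        ("dendrite_density", +1, 0.04, 0.10),
        ("skeleton_length_um", +1, 900.0, 1400.0),
        ("node_count", +1, 6.0, 18.0),
        ("dendrite_mean_width_um", +1, 0.60, 0.12),
        ("dendrite_mean_intensity", +1, 600.0, 200.0),
    ],
    "synapse": [
        ("synapse_density_per_100um", +1, 0.8, 2.6),
        ("pre_density_per_100um", +1, 1.5, 3.0),
        ("post_density_per_100um", +1, 1.4, 3.1),
        ("pearson_colocalization", +1, 0.05, 0.25),
    ],
    "functional": [
        ("burst_correlation", +1, 0.05, 0.80),
        ("percent_active", +1, 30.0, 55.0),
        ("network_burst_rate_hz", +1, 0.005, 0.040),
        ("burst_rate_hz", +1, 0.03, 0.03),
    ],
}


def simulate_descriptor_table(
    maturation: MaturationModel | None = None,
    n_wells_per_div: int = 6,
    n_experiments: int = 3,
    noise_scale: float = 0.3,
    class_noise_share: float = 0.5,
    seed: int = 0,
    condition: str = "control",
    damp_classes: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a per-well descriptor table directly from the maturation ramps.

    Bypasses image rendering: each descriptor follows its class trend over
    pseudo-age (scaled by the model's synapse/synchrony/dendrite ramps) with
    Gaussian noise proportional to its dynamic range. Part of the noise
    (``class_noise_share``) is a latent per-row, per-class factor: descriptors
    of one class co-fluctuate within a well (as staining intensity or culture
    state make them do in practice) while different classes stay only
    ramp-correlated. ``damp_classes`` maps a descriptor class to a factor in
    [0, 1] that shrinks that class's maturation effect toward the
    youngest-age value — a controlled "connectivity degradation" of only that
    class.

    Returns one row per (experiment, well, DIV) with full metadata columns.
    """
    mm = maturation or MaturationModel()
    rng = np.random.default_rng(seed)
    damp = damp_classes or {}
    lo_div = min(mm.div_levels)
    rows = []
    well_idx = 0
    for e in range(1, n_experiments + 1):
        for div in mm.div_levels:
            # normalised maturation progress for each driving ramp
            prog = {
                "nuclei": _progress(mm.neuron_count_ramp, div, mm.div_levels),
                "dendrite": _progress(mm.dendrite_scale_ramp, div, mm.div_levels),
                "synapse": _progress(mm.synapse_ramp, div, mm.div_levels),
                "functional": _progress(mm.synchrony_ramp, div, mm.div_levels),
            }
            for _ in range(n_wells_per_div):
                well = f"{chr(ord('A') + well_idx // 12)}{well_idx % 12 + 1:02d}"
                well_idx = (well_idx + 1) % 96
                row: dict = {
                    "plate": f"P{e}",
                    "well": well,
                    "field": 1,
                    "DIV": div,
                    "cell_type": "cortical",
                    "condition": condition,
                    "dose": 0.0,
                    "experiment": f"E{e}",
                    "replicate": 1,
                    "seed": seed,
                }
                a = math.sqrt(class_noise_share)
                b = math.sqrt(1.0 - class_noise_share)
                for cls, descs in DESCRIPTOR_CLASSES.items():
                    eff = damp.get(cls, 1.0) * prog[cls]
                    eps_class = rng.normal()
                    for name, direction, base, change in descs:
                        mean = base + direction * abs(change) * eff if direction else base
                        scale = abs(change) if change else 0.2 * abs(base)
                        eps = a * eps_class + b * rng.normal()
                        row[name] = mean + noise_scale * scale * eps
                rows.append(row)
    return pd.DataFrame.from_records(rows)


def _progress(ramp: Callable[[float], float], div: float, div_levels: Sequence[float]) -> float:
    """Normalised ramp progress in [0, 1] between the youngest and oldest age."""
    lo, hi = ramp(min(div_levels)), ramp(max(div_levels))
    if hi == lo:
        return 0.0
    return (ramp(div) - lo) / (hi - lo)
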