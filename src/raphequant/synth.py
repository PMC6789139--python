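"""Synthetic data with planted ground truth.

Emulates the four data modalities of a DR Cre-line characterization study:

* ``make_section`` -- a multichannel confocal-like section with soma-shaped
  objects whose per-subregion marker co-expression probability is planted;
* ``make_brain_series`` -- a pseudo whole-brain section series with an atlas
  label map, planted input neurons per region, neurite clutter and bright
  artifacts (the rabies input-mapping scenario);
* ``make_axon_field`` -- a curvilinear terminal field of configurable true
  coverage (the axon-density scenario);
* ``make_sweeps`` -- voltage-clamp sweep sets with planted light-evoked EPSCs
  (difference-of-exponentials kernel) and a drug-block condition.

Every generator returns a :class:`SyntheticTruth` holding one truth record per
rendered object, and is bit-deterministic: the single spec seed drives
per-object counter-based substreams (``numpy`` ``SeedSequence`` spawn keys),
so adding objects never shifts unrelated draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cellcount import Section, SubregionLayout
from .ephys import SweepSet
from .inputmap import LabelMap

__all__ = [
    "SectionSpec",
    "BrainSeriesSpec",
    "AxonFieldSpec",
    "SweepSpec",
    "SyntheticTruth",
    "CapacityError",
    "make_section",
    "make_brain_series",
    "make_axon_field",
    "make_sweeps",
    "epsc_kernel",
]


class CapacityError(RuntimeError):
    """More cells requested than can be packed at the hard-core distance."""


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every synthetic dataset."""

    cells: pd.DataFrame | None = None          # id, channel, x_um, y_um, subregion/region, coexpress
    region_counts: dict[str, int] | None = None
    artifact_rois: list[list[tuple[float, float]]] | None = None
    soma_mask: np.ndarray | None = None        # pre-noise foreground mask (somata only)
    axon_coverage: float | None = None
    epsc: pd.DataFrame | None = None           # cell_id, responder, amp_pa


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: one root seed, per-object spawn key."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# sections with co-expressing somata


@dataclass
class SectionSpec:
    width_um: float = 600.0
    height_um: float = 600.0
    um_per_px: float = 2.0
    channels: tuple[str, ...] = ("reporter", "marker")
    subregion_layout: SubregionLayout = field(default_factory=SubregionLayout.grid_2x2)
    cells_per_subregion: int = 40
    p_coexpress: float | dict[str, float] = 0.9
    soma_diameter_um: tuple[float, float] = (15.0, 1.0)  # mean, sd; sampled, clipped to +/-3 sd
    intensity_levels: dict[str, tuple[float, float]] | None = None  # channel -> (fg, bg)
    noise_sd: float = 0.02
    clutter_density: float = 0.2  # neurite strokes per 10^4 um^2
    seed: int = 0

    def validate(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        for p in self.p_by_subregion().values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("p_coexpress must lie in [0, 1]")
        for name, (x0, y0, x1, y1) in self.subregion_layout.boxes.items():
            if x0 < 0 or y0 < 0 or x1 > self.width_um or y1 > self.height_um:
                raise ValueError(f"subregion {name!r} exceeds the section bounds")

    def p_by_subregion(self) -> dict[str, float]:
        names = list(self.subregion_layout.boxes)
        if isinstance(self.p_coexpress, dict):
            return {n: float(self.p_coexpress[n]) for n in names}
        return {n: float(self.p_coexpress) for n in names}

    def levels(self, channel: str) -> tuple[float, float]:
        if self.intensity_levels and channel in self.intensity_levels:
            return self.intensity_levels[channel]
        return (0.8, 0.05)

    @property
    def shape_px(self) -> tuple[int, int]:
        return (int(round(self.height_um / self.um_per_px)),
                int(round(self.width_um / self.um_per_px)))


def _dart_throw(rng: np.random.Generator, n: int, box_px: tuple[float, float, float, float],
                min_dist_px: float, margin_px: float, max_tries_per_pt: int = 400
                ) -> np.ndarray:
    """Hard-core placement of n points in a box; raises CapacityError on failure."""
    r0, c0, r1, c1 = box_px
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries_per_pt * max(n, 1)
    while len(pts) < n:
        if tries >= budget:
            raise CapacityError(
                f"could not place {n} cells at hard-core distance {min_dist_px:.1f}px "
                f"in a {r1 - r0:.0f}x{c1 - c0:.0f}px box (placed {len(pts)})")
        tries += 1
        r = rng.uniform(r0 + margin_px, r1 - margin_px)
        c = rng.uniform(c0 + margin_px, c1 - margin_px)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_dist_px**2 for pr, pc in pts):
            pts.append((r, c))
    return np.array(pts).reshape(n, 2)


def _draw_disk(img: np.ndarray, r: float, c: float, radius_px: float, level: float) -> None:
    """Paint a filled disk (maximum blend) into img."""
    h, w = img.shape
    rr0 = max(int(math.floor(r - radius_px)) - 1, 0)
    rr1 = min(int(math.ceil(r + radius_px)) + 2, h)
    cc0 = max(int(math.floor(c - radius_px)) - 1, 0)
    cc1 = min(int(math.ceil(c + radius_px)) + 2, w)
    rows, cols = np.mgrid[rr0:rr1, cc0:cc1]
    disk = (rows - r) ** 2 + (cols - c) ** 2 <= radius_px**2
    patch = img[rr0:rr1, cc0:cc1]
    patch[disk] = np.maximum(patch[disk], level)


def _draw_strokes(img: np.ndarray, rng: np.random.Generator, n_strokes: int,
                  level: float, n_steps: int = 40, step_px: float = 2.0) -> np.ndarray:
    """Random-walk neurite strokes 1-2 px wide; returns the stroke mask."""
    h, w = img.shape
    mask = np.zeros((h, w), dtype=bool)
    for k in range(n_strokes):
        r = rng.uniform(0, h)
        c = rng.uniform(0, w)
        theta = rng.uniform(0, 2 * math.pi)
        wide = rng.random() < 0.5
        for _ in range(n_steps):
            theta += rng.normal(0, 0.4)
            r += step_px * math.sin(theta)
            c += step_px * math.cos(theta)
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < h and 0 <= ci < w:
                mask[ri, ci] = True
                if wide:
                    if ri + 1 < h:
                        mask[ri + 1, ci] = True
                    if ci + 1 < w:
                        mask[ri, ci + 1] = True
    img[mask] = np.maximum(img[mask], level)
    return mask


def _finish_channel(img: np.ndarray, rng: np.random.Generator, noise_sd: float,
                    blur_sigma_px: float = 1.0) -> np.ndarray:
    """PSF-like Gaussian blur, additive Gaussian noise, clip to [0, 1]."""
    out = ndimage.gaussian_filter(img, blur_sigma_px)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def make_section(spec: SectionSpec) -> tuple[Section, SyntheticTruth]:
    """Render a two-channel section with planted co-expression structure."""
    spec.validate()
    shape = spec.shape_px
    mean_d, sd_d = spec.soma_diameter_um
    # hard-core on the maximum clipped diameter: guarantees a blur-separable
    # gap between any two somata, so planted counts are recoverable exactly
    min_dist_px = 1.2 * (mean_d + 3 * sd_d) / spec.um_per_px
    reporter_ch, marker_ch = spec.channels[0], spec.channels[1]
    imgs = {ch: np.full(shape, spec.levels(ch)[1], dtype=np.float64) for ch in spec.channels}

    records = []
    p_map = spec.p_by_subregion()
    cell_id = 0
    for sub_idx, (name, (x0, y0, x1, y1)) in enumerate(spec.subregion_layout.boxes.items()):
        box_px = (y0 / spec.um_per_px, x0 / spec.um_per_px,
                  y1 / spec.um_per_px, x1 / spec.um_per_px)
        place_rng = _rng(spec.seed, 1, sub_idx)
        max_r_px = (mean_d + 3 * sd_d) / 2 / spec.um_per_px
        pts = _dart_throw(place_rng, spec.cells_per_subregion, box_px,
                          min_dist_px, margin_px=max_r_px + 1)
        for j in range(spec.cells_per_subregion):
            cell_rng = _rng(spec.seed, 2, sub_idx, j)
            d_um = float(np.clip(cell_rng.normal(mean_d, sd_d),
                                 mean_d - 3 * sd_d, mean_d + 3 * sd_d))
            radius_px = d_um / 2 / spec.um_per_px
            r, c = pts[j]
            coexpress = bool(cell_rng.random() < p_map[name])
            _draw_disk(imgs[reporter_ch], r, c, radius_px, spec.levels(reporter_ch)[0])
            if coexpress:
                _draw_disk(imgs[marker_ch], r, c, radius_px, spec.levels(marker_ch)[0])
            records.append({"id": cell_id, "channel": reporter_ch,
                            "x_um": c * spec.um_per_px, "y_um": r * spec.um_per_px,
                            "subregion": name, "coexpress": coexpress,
                            "diameter_um": d_um})
            cell_id += 1

    area_um2 = spec.width_um * spec.height_um
    n_strokes = int(round(spec.clutter_density * area_um2 / 1e4))
    for ch_idx, ch in enumerate(spec.channels):
        fg, bg = spec.levels(ch)
        # clutter sits midway between background and soma foreground so it is
        # removable by the area gate, not only by threshold
        _draw_strokes(imgs[ch], _rng(spec.seed, 3, ch_idx), n_strokes, (fg + bg) / 2)
        imgs[ch] = _finish_channel(imgs[ch], _rng(spec.seed, 4, ch_idx), spec.noise_sd)

    truth = SyntheticTruth(cells=pd.DataFrame(records))
    return Section(channels=imgs, um_per_px=spec.um_per_px), truth


# ---------------------------------------------------------------------------
# pseudo-brain series with an atlas label map


@dataclass
class RegionSpec:
    name: str
    group: str = "other"
    excluded: bool = False


@dataclass
class BrainSeriesSpec:
    n_sections: int = 6
    regions: list[RegionSpec] = field(default_factory=lambda: [
        RegionSpec(f"R{i:02d}") for i in range(12)])
    planted_counts: dict[str, int] = field(default_factory=dict)
    artifact_rate: float = 0.5  # artifacts per section (Poisson)
    clutter_density: float = 0.2
    noise_sd: float = 0.02
    um_per_px: float = 2.0
    region_box_px: tuple[int, int] = (150, 150)  # rows, cols per region tile
    grid: tuple[int, int] | None = None          # tiles (rows, cols); default near-square
    soma_diameter_um: tuple[float, float] = (15.0, 1.0)
    intensity_fg: float = 0.8
    intensity_bg: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        names = {r.name for r in self.regions}
        if len(names) != len(self.regions):
            raise ValueError("duplicate region names")
        if not any(not r.excluded for r in self.regions):
            raise ValueError("at least one region must be non-excluded")
        for name, cnt in self.planted_counts.items():
            if name not in names:
                raise KeyError(f"planted region {name!r} absent from the label map")
            if cnt < 0:
                raise ValueError("planted counts must be >= 0")
            if next(r for r in self.regions if r.name == name).excluded:
                raise ValueError(f"cannot plant input neurons in excluded region {name!r}")


def make_brain_series(spec: BrainSeriesSpec
                      ) -> tuple[list[Section], list[LabelMap], SyntheticTruth]:
    """Render a section series; every section carries the full region grid.

    Regions tile each section as a near-square grid of
    ``region_box_px`` tiles; planted input neurons are placed only inside
    their designated tile, artifacts (bright square blobs) uniformly at
    random, with their true ROIs reported in the truth record.
    """
    spec.validate()
    n_reg = len(spec.regions)
    if spec.grid is not None:
        g_rows, g_cols = spec.grid
        if g_rows * g_cols < n_reg:
            raise ValueError("grid too small for the region list")
    else:
        g_cols = int(math.ceil(math.sqrt(n_reg)))
        g_rows = int(math.ceil(n_reg / g_cols))
    tile_r, tile_c = spec.region_box_px
    shape = (g_rows * tile_r, g_cols * tile_c)

    raster = np.zeros(shape, dtype=np.int32)
    table = []
    tiles: dict[str, tuple[int, int, int, int]] = {}
    for idx, reg in enumerate(spec.regions):
        gr, gc = divmod(idx, g_cols)
        r0, c0 = gr * tile_r, gc * tile_c
        raster[r0:r0 + tile_r, c0:c0 + tile_c] = idx + 1
        tiles[reg.name] = (r0, c0, r0 + tile_r, c0 + tile_c)
        table.append({"id": idx + 1, "name": reg.name, "group": reg.group,
                      "excluded": reg.excluded})
    labelmap = LabelMap(raster=raster, table=pd.DataFrame(table))

    mean_d, sd_d = spec.soma_diameter_um
    min_dist_px = 1.2 * (mean_d + 3 * sd_d) / spec.um_per_px
    max_r_px = (mean_d + 3 * sd_d) / 2 / spec.um_per_px

    # split each region's planted count across sections as evenly as possible,
    # remainder sections chosen by a dedicated substream
    per_section: dict[str, np.ndarray] = {}
    for reg_idx, (name, count) in enumerate(sorted(spec.planted_counts.items())):
        base = count // spec.n_sections
        alloc = np.full(spec.n_sections, base, dtype=int)
        extra = count - base * spec.n_sections
        if extra:
            pick = _rng(spec.seed, 10, reg_idx).choice(spec.n_sections, size=extra,
                                                       replace=False)
            alloc[pick] += 1
        per_section[name] = alloc

    sections: list[Section] = []
    cell_records = []
    soma_masks = []
    artifact_rois: list[list[tuple[float, float]]] = []
    cell_id = 0
    for s in range(spec.n_sections):
        img = np.full(shape, spec.intensity_bg, dtype=np.float64)
        soma_mask = np.zeros(shape, dtype=bool)
        for reg_idx, (name, alloc) in enumerate(sorted(per_section.items())):
            n_here = int(alloc[s])
            if n_here == 0:
                continue
            r0, c0, r1, c1 = tiles[name]
            pts = _dart_throw(_rng(spec.seed, 11, s, reg_idx), n_here,
                              (r0, c0, r1, c1), min_dist_px, margin_px=max_r_px + 1)
            for j in range(n_here):
                cell_rng = _rng(spec.seed, 12, s, reg_idx, j)
                d_um = float(np.clip(cell_rng.normal(mean_d, sd_d),
                                     mean_d - 3 * sd_d, mean_d + 3 * sd_d))
                radius_px = d_um / 2 / spec.um_per_px
                r, c = pts[j]
                _draw_disk(img, r, c, radius_px, spec.intensity_fg)
                _draw_disk(soma_mask.view(np.uint8).reshape(shape), r, c, radius_px, 1)
                cell_records.append({"id": cell_id, "section": s, "region": name,
                                     "x_um": c * spec.um_per_px,
                                     "y_um": r * spec.um_per_px})
                cell_id += 1
        # clutter below soma brightness
        area_um2 = shape[0] * shape[1] * spec.um_per_px**2
        n_strokes = int(round(spec.clutter_density * area_um2 / 1e4))
        _draw_strokes(img, _rng(spec.seed, 13, s), n_strokes,
                      (spec.intensity_fg + spec.intensity_bg) / 2)
        # bright square artifacts at soma-level intensity, with true ROIs
        art_rng = _rng(spec.seed, 14, s)
        for _ in range(art_rng.poisson(spec.artifact_rate)):
            size = int(art_rng.integers(10, 20))
            r = int(art_rng.integers(0, shape[0] - size))
            c = int(art_rng.integers(0, shape[1] - size))
            img[r:r + size, c:c + size] = spec.intensity_fg
            artifact_rois.append([(r - 0.5, c - 0.5), (r - 0.5, c + size + 0.5),
                                  (r + size + 0.5, c + size + 0.5),
                                  (r + size + 0.5, c - 0.5)])
        img = _finish_channel(img, _rng(spec.seed, 15, s), spec.noise_sd)
        sections.append(Section(channels={"gfp": img}, um_per_px=spec.um_per_px))
        soma_masks.append(soma_mask)

    counts = {r.name: int(per_section.get(r.name, np.zeros(1)).sum())
              for r in spec.regions}
    truth = SyntheticTruth(
        cells=pd.DataFrame(cell_records),
        region_counts=counts,
        artifact_rois=artifact_rois,
        soma_mask=np.stack(soma_masks) if soma_masks else None,
    )
    return sections, [labelmap] * spec.n_sections, truth


# ---------------------------------------------------------------------------
# axon terminal fields


@dataclass
class AxonFieldSpec:
    width_um: float = 600.0
    height_um: float = 600.0
    um_per_px: float = 2.0
    intensity_fg: float = 0.8
    intensity_bg: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0


def make_axon_field(coverage_target: float, spec: AxonFieldSpec | None = None
                    ) -> tuple[Section, SyntheticTruth]:
    """Curvilinear strokes rendered until the pre-blur mask reaches the target.

    The recorded truth coverage is counted from the pre-blur stroke mask, so
    it is exact regardless of PSF blur and noise.
    """
    spec = spec or AxonFieldSpec()
    if not 0.0 <= coverage_target < 1.0:
        raise ValueError("coverage_target must lie in [0, 1)")
    shape = (int(round(spec.height_um / spec.um_per_px)),
             int(round(spec.width_um / spec.um_per_px)))
    img = np.full(shape, spec.intensity_bg, dtype=np.float64)
    mask = np.zeros(shape, dtype=bool)
    rng = _rng(spec.seed, 20)
    k = 0
    while mask.mean() < coverage_target:
        stroke = _draw_strokes(img, _rng(spec.seed, 21, k), 1, spec.intensity_fg)
        mask |= stroke
        k += 1
        if k > 200_000:  # pragma: no cover - safeguard
            raise RuntimeError("stroke budget exhausted before reaching coverage")
    del rng
    true_cov = float(mask.mean())
    img = _finish_channel(img, _rng(spec.seed, 22), spec.noise_sd)
    section = Section(channels={"axon": img}, um_per_px=spec.um_per_px)
    return section, SyntheticTruth(axon_coverage=true_cov, soma_mask=mask)


# ---------------------------------------------------------------------------
# voltage-clamp sweeps


@dataclass
class SweepSpec:
    n_cells: int = 20
    sweeps_per_cell: int = 10
    sampling_rate_hz: float = 10_000.0
    trace_dur_s: float = 0.5
    stim_onset_s: float = 0.2
    pulse_dur_s: float = 0.005
    p_responder: float = 0.5
    amp_pa: tuple[float, float] = (70.0, 10.0)  # mean, sd of planted magnitude
    latency_s: float = 0.005
    tau_rise_s: float = 0.001
    tau_decay_s: float = 0.010
    baseline_noise_sd_pa: float = 5.0
    sweep_jitter_frac: float = 0.05  # per-sweep multiplicative amplitude jitter
    block_factor: float = 0.05      # post-drug amplitude scaling (CNQX-like)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_responder <= 1.0:
            raise ValueError("p_responder must lie in [0, 1]")
        if not 0.0 <= self.block_factor <= 1.0:
            raise ValueError("block_factor must lie in [0, 1]")
        if self.sweeps_per_cell < 1:
            raise ValueError("sweeps_per_cell must be >= 1")
        if not 0 <= self.stim_onset_s < self.trace_dur_s:
            raise ValueError("stimulus onset must lie inside the trace")


def epsc_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials EPSC waveform, normalized to unit peak.

    The analytic peak of exp(-t/tau_d) - exp(-t/tau_r) sits at
    t* = tau_r*tau_d/(tau_d - tau_r) * ln(tau_d/tau_r); dividing by the value
    there makes the planted magnitude equal the waveform peak exactly.
    """
    if tau_decay <= tau_rise:
        raise ValueError("tau_decay must exceed tau_rise")
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                   - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_star = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    peak = math.exp(-t_star / tau_decay) - math.exp(-t_star / tau_rise)
    return raw / peak


def make_sweeps(spec: SweepSpec) -> tuple[list[SweepSet], SyntheticTruth]:
    """Generate paired baseline / post-drug sweep sets per cell.

    Responder cells carry a negative-going (inward at -70 mV) EPSC of the
    planted magnitude starting at stimulus onset + latency; non-responders
    carry baseline noise only.  The post condition scales the EPSC by
    ``block_factor`` with independent noise.
    """
    spec.validate()
    n_samples = int(round(spec.trace_dur_s * spec.sampling_rate_hz))
    t = np.arange(n_samples) / spec.sampling_rate_hz
    kern = epsc_kernel(t - spec.stim_onset_s - spec.latency_s,
                       spec.tau_rise_s, spec.tau_decay_s)
    sweepsets: list[SweepSet] = []
    rows = []
    for i in range(spec.n_cells):
        cell_rng = _rng(spec.seed, 30, i)
        responder = bool(cell_rng.random() < spec.p_responder)
        amp = float(max(cell_rng.normal(*spec.amp_pa), 0.0)) if responder else 0.0
        for cond_idx, (cond, scale) in enumerate(
                [("baseline", 1.0), ("post", spec.block_factor)]):
            noise_rng = _rng(spec.seed, 31, i, cond_idx)
            sweeps = noise_rng.normal(0.0, spec.baseline_noise_sd_pa,
                                      size=(spec.sweeps_per_cell, n_samples))
            if amp > 0:
                jit = 1.0 + noise_rng.normal(0.0, spec.sweep_jitter_frac,
                                             size=(spec.sweeps_per_cell, 1))
                sweeps = sweeps - scale * amp * np.clip(jit, 0.0, None) * kern[None, :]
            sweepsets.append(SweepSet(
                cell_id=f"cell{i:03d}", condition=cond, sweeps=sweeps,
                sampling_rate_hz=spec.sampling_rate_hz,
                stim_onset_s=spec.stim_onset_s, pulse_dur_s=spec.pulse_dur_s))
        rows.append({"cell_id": f"cell{i:03d}", "responder": responder, "amp_pa": amp})
    return sweepsets, SyntheticTruth(epsc=pd.DataFrame(rows))
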