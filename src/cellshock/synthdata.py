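"""Synthetic single-cell shock-loading experiments.

Emulates the statistical structure of a high-speed-imaging impact study
on adherent macrophages: a population of cells with Gaussian initial
area/perimeter and uniform inclination angle, constant-rate pressure
ramps shorter than 0.1 ms sampled at 2x10^5 fps, peak pressures drawn
around fifteen group centres spanning roughly 156-3604 kPa, deformation
responses generated by a chosen area-pressure state equation with
water-exchange fluctuation noise (uniform under stationary fluid,
Gaussian under directed flow), occasional detachment, and optional
rendering of 160x48 px, 0.75 µm/px, 12-bit frame stacks with paired
ground-truth masks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from skimage.draw import polygon2mask

from . import eos
from ._geometry import polygon_area, scale_to_area, star_polygon

__all__ = [
    "PopulationSpec",
    "LoadingWaveform",
    "NoiseSpec",
    "SizeCouplingSpec",
    "ImageSpec",
    "CellSeed",
    "DeformationRecord",
    "DatasetConfig",
    "STUDY_GROUP_CENTERS_KPA",
    "STUDY_GROUP_SDS_KPA",
    "STUDY_GROUP_SIZES",
    "PRESSURE_SPAN_KPA",
    "sample_cell_population",
    "generate_waveform",
    "couple_params",
    "simulate_response",
    "render_frames",
    "generate_dataset",
    "RECORD_COLUMNS",
]

# Peak-pressure group structure of the emulated study: fifteen levels,
# centre +/- dispersion in kPa, n=198 experiments in total (the two
# highest groups hold 13 and 9 experiments; the remainder is spread
# evenly over the lower levels).
STUDY_GROUP_CENTERS_KPA = (
    478.0, 550.0, 640.0, 760.0, 837.0, 986.0, 1094.0, 1198.0,
    1315.0, 1489.0, 1703.0, 1880.0, 2261.0, 2598.0, 3178.0,
)
STUDY_GROUP_SDS_KPA = (
    24.2, 18.1, 22.7, 18.3, 27.6, 44.2, 16.2, 36.0,
    37.0, 35.4, 43.7, 58.4, 85.1, 115.6, 195.2,
)
STUDY_GROUP_SIZES = (14, 14, 14, 14, 14, 14, 14, 13, 13, 13, 13, 13, 13, 13, 9)
PRESSURE_SPAN_KPA = (156.48, 3603.85)

RECORD_COLUMNS = [
    "cell_id", "group_label", "p0_kPa", "pmax_kPa", "A_initial_um2",
    "A_final_um2", "zeta", "perimeter_um", "angle_deg", "detached",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Initial-shape distribution of the cell population.

    Areas and perimeters are Gaussian (truncated at zero by resampling);
    the inclination angle is uniform on [angle_low, angle_high) degrees.
    """

    n_cells: int = 198
    area_mean: float = 450.0   # µm²
    area_sd: float = 120.0     # µm²
    perim_mean: float = 90.0   # µm
    perim_sd: float = 18.0     # µm
    angle_low: float = 0.0     # degrees
    angle_high: float = 180.0  # degrees
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.area_sd < 0 or self.perim_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0.0 <= self.angle_low < self.angle_high <= 180.0):
            raise ValueError("need 0 <= angle_low < angle_high <= 180")


@dataclass(frozen=True)
class CellSeed:
    """One sampled cell: initial area, perimeter and inclination angle."""

    cell_id: int
    area: float       # µm²
    perimeter: float  # µm
    angle: float      # degrees in [0, 180)


@dataclass(frozen=True)
class LoadingWaveform:
    """Sampled pressure trace: baseline segment plus a constant-rate ramp."""

    times: np.ndarray      # ms, uniform grid
    pressures: np.ndarray  # kPa
    p0: float              # kPa, baseline
    p_dot: float           # kPa/ms, constant ramp rate
    arrival_index: int     # first ramp sample
    peak_index: int        # argmax(pressures)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        seg = np.asarray(self.pressures)[self.arrival_index : self.peak_index + 1]
        if np.any(np.diff(seg) < -1e-9):
            raise ValueError("ramp segment must be non-decreasing")


@dataclass(frozen=True)
class NoiseSpec:
    """Water-exchange fluctuation of the observed final area.

    Multiplicative: A_final = A_model * (1 + e) with e uniform on
    [-amplitude, amplitude] under stationary fluid and
    Normal(0, amplitude) under unidirectional flow.
    """

    flow_mode: str = "unidirectional"
    amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.flow_mode not in ("stationary", "unidirectional"):
            raise ValueError("flow_mode must be 'stationary' or 'unidirectional'")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.amplitude == 0:
            return 0.0
        while True:
            if self.flow_mode == "stationary":
                e = rng.uniform(-self.amplitude, self.amplitude)
            else:
                e = rng.normal(0.0, self.amplitude)
            if e > -0.999:  # keep the observed area positive
                return float(e)


@dataclass(frozen=True)
class SizeCouplingSpec:
    """How state-equation parameters vary with the cell's initial area.

    Multiplicative scaling theta(A0) = theta_ref * (reference_area/A0)**eta
    of the per-family gain parameter, with a per-family sign convention
    chosen so that larger cells deform relatively less (d zeta/dA0 < 0):
    the exponential family scales B0 by the factor; the Tait and li
    families scale alpha3 / alpha1 by its reciprocal (larger cells are
    stiffer).
    """

    reference_area: float = 450.0  # µm²
    eta: float = 0.5

    def __post_init__(self):
        if self.reference_area <= 0:
            raise ValueError("reference_area must be positive")

    def factor(self, A0: float) -> float:
        return (self.reference_area / A0) ** self.eta


@dataclass(frozen=True)
class ImageSpec:
    """Sensor geometry of the rendered frames."""

    height: int = 48       # px (rows)
    width: int = 160       # px (cols)
    pixel_size: float = 0.75  # µm per pixel side
    bit_depth: int = 12
    fps: float = 2.0e5     # frames/s

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("canvas must be at least 1x1")
        if self.pixel_size <= 0 or self.fps <= 0:
            raise ValueError("pixel_size and fps must be positive")
        if not 1 <= self.bit_depth <= 16:
            raise ValueError("bit_depth must be in [1, 16]")

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class DeformationRecord:
    """Outcome of one simulated experiment."""

    cell_id: int
    A_initial: float   # µm²
    A_final: float     # µm²
    zeta: float
    p_max: float       # kPa actually experienced (pre-detachment if detached)
    p0: float          # kPa
    detached: bool
    detach_index: int | None = None  # frame index of detachment, if any
    group_label: str | None = None


# ---------------------------------------------------------------------------

def sample_cell_population(spec: PopulationSpec) -> list[CellSeed]:
    """Draw a reproducible population of initial cell shapes."""
    rng = np.random.default_rng(spec.seed)

    def truncated_normal(mean, sd, n):
        if sd == 0:
            return np.full(n, float(mean))
        out = np.empty(n)
        remaining = np.arange(n)
        while remaining.size:
            draw = rng.normal(mean, sd, remaining.size)
            ok = draw > 0
            out[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
        return out

    n = spec.n_cells
    areas = truncated_normal(spec.area_mean, spec.area_sd, n)
    perims = truncated_normal(spec.perim_mean, spec.perim_sd, n)
    angles = rng.uniform(spec.angle_low, spec.angle_high, n)
    return [
        CellSeed(cell_id=i, area=float(areas[i]), perimeter=float(perims[i]),
                 angle=float(angles[i]))
        for i in range(n)
    ]


def generate_waveform(
    p0: float,
    p_peak: float,
    duration: float,
    fps: float,
    baseline_frames: int = 5,
    baseline_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LoadingWaveform:
    """Constant-rate pressure ramp p0 -> p_peak over ``duration`` ms.

    A pre-arrival baseline segment of ``baseline_frames`` samples at p0
    (optionally with Gaussian sensor noise) precedes the ramp; the first
    ramp sample is exactly p0 and the last is p_peak.
    """
    if p_peak <= p0:
        raise ValueError("p_peak must exceed p0")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_intervals = int(round(fps * duration / 1e3))
    if n_intervals < 2:
        raise ValueError("too few frames: fps * duration must give >= 2 ramp intervals")
    dt = duration / n_intervals  # ms
    n_total = baseline_frames + n_intervals + 1
    times = (np.arange(n_total) - baseline_frames) * dt
    pressures = np.empty(n_total)
    pressures[:baseline_frames] = p0
    if baseline_noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        pressures[:baseline_frames] += rng.normal(0, baseline_noise_sd, baseline_frames)
    pressures[baseline_frames:] = np.linspace(p0, p_peak, n_intervals + 1)
    return LoadingWaveform(
        times=times,
        pressures=pressures,
        p0=float(p0),
        p_dot=(p_peak - p0) / duration,
        arrival_index=baseline_frames,
        peak_index=n_total - 1,
    )


def couple_params(
    model: eos.StateEquationParams,
    A0_cell: float,
    coupling: SizeCouplingSpec | None,
) -> eos.StateEquationParams:
    """State-equation parameters adjusted for one cell's initial area."""
    if A0_cell <= 0:
        raise ValueError("cell area must be positive")
    if coupling is None:
        return model.with_(A0=A0_cell)
    c = coupling.factor(A0_cell)
    if model.family == "exponential":
        return model.with_(A0=A0_cell, B0=model.B0 * c, Bprime=model.Bprime * c)
    if model.family == "tait":
        return model.with_(A0=A0_cell, alpha3=model.alpha3 / c)
    return model.with_(A0=A0_cell, alpha1=model.alpha1 / c)


def simulate_response(
    cell: CellSeed,
    waveform: LoadingWaveform,
    model: eos.StateEquationParams,
    noise: NoiseSpec | None = None,
    coupling: SizeCouplingSpec | None = None,
    detach_prob: float = 0.0,
    rng: np.random.Generator | None = None,
    detach_mid: float = 1500.0,
    detach_scale: float = 500.0,
) -> DeformationRecord:
    """One experiment: evaluate the state equation at the peak pressure.

    The final area is the model prediction (with size coupling) times a
    multiplicative water-exchange fluctuation.  Detachment is a
    Bernoulli event whose probability is ``detach_prob`` modulated by a
    logistic in the peak pressure; a detached cell's effective peak
    pressure is re-read at the (uniformly drawn) pre-detachment frame.
    """
    rng = rng or np.random.default_rng(0)
    params = couple_params(model, cell.area, coupling)

    p_max = float(waveform.pressures[waveform.peak_index])
    detached = False
    detach_index: int | None = None
    if detach_prob > 0:
        prob = detach_prob * float(expit((p_max - detach_mid) / detach_scale))
        if rng.uniform() < prob:
            # detachment frame after ramp onset; the record keeps the last
            # adhered frame, whose pressure is strictly above baseline
            lo, hi = waveform.arrival_index + 2, waveform.peak_index
            if hi >= lo:
                detached = True
                detach_index = int(rng.integers(lo, hi + 1))
                p_max = float(waveform.pressures[detach_index - 1])

    A_model = float(eos.area_model(p_max, params))
    fluct = noise.draw(rng) if noise is not None else 0.0
    A_final = A_model * (1.0 + fluct)
    return DeformationRecord(
        cell_id=cell.cell_id,
        A_initial=cell.area,
        A_final=A_final,
        zeta=A_final / cell.area,
        p_max=p_max,
        p0=waveform.p0,
        detached=detached,
        detach_index=detach_index,
    )


# ---------------------------------------------------------------------------
# frame rendering

def _cell_polygon(cell: CellSeed, center_um, rng: np.random.Generator,
                  n_vertices: int = 72) -> np.ndarray:
    """Irregular star-convex outline for one cell at its initial area.

    Random radial harmonics (modes 2-6) break the strict perimeter-area
    link of a circle; the polygon is rescaled to the exact target area.
    """
    harmonics = {}
    for k in range(2, 7):
        amp = rng.uniform(0.01, 0.10 / np.sqrt(k))
        harmonics[k] = (amp, rng.uniform(0, 2 * np.pi))
    r0 = np.sqrt(cell.area / np.pi)
    poly = star_polygon(center_um, r0, n_vertices=n_vertices,
                        harmonics=harmonics, rotation=np.deg2rad(cell.angle))
    return scale_to_area(poly, cell.area)


_SUPERSAMPLE = 4  # subpixel rasterisation factor for fractional coverage


def _coverage(poly_rc: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fractional pixel coverage of a polygon by supersampled rasterisation.

    A pixel integrates light over its whole aperture, so edge pixels
    carry intermediate intensities; each pixel is sampled on an s x s
    subgrid (s = 4 -> coverage quantised to 1/16).
    """
    s = _SUPERSAMPLE
    h, w = shape
    big = polygon2mask((h * s, w * s), poly_rc * s + (s - 1) / 2.0)
    return big.reshape(h, s, w, s).mean(axis=(1, 3))


def render_frames(
    cell: CellSeed,
    record: DeformationRecord,
    waveform: LoadingWaveform,
    image_spec: ImageSpec = ImageSpec(),
    rng: np.random.Generator | None = None,
    foreground: float = 2800.0,
    background: float = 600.0,
    noise_sd: float = 40.0,
    blur_sigma: float = 0.3,
):
    """Render one experiment as a frame stack with ground-truth masks.

    Each frame draws the cell's star-convex outline scaled so its area
    interpolates linearly in pressure between the record's initial and
    final states (the state equation anchors the endpoints).  Edge
    pixels carry fractional-coverage intensities (anti-aliased
    rendering); a small optional Gaussian PSF and additive sensor noise
    follow.  Frames at or after a detachment index show background
    only.  Intensities are 12-bit values in 16-bit containers; masks
    (coverage >= 1/2) are 0/255 uint8.

    Returns (frames, masks, polygons) where polygons[i] is the exact
    ground-truth outline (µm) for frame i, or None where no cell is drawn.
    """
    rng = rng or np.random.default_rng(0)
    h, w, ps = image_spec.height, image_spec.width, image_spec.pixel_size
    # subpixel placement jitter: a real cell never sits exactly on the
    # pixel grid, and exact alignment is a degenerate rasterisation case
    jx, jy = rng.uniform(-0.5, 0.5, 2) * ps
    center = (w * ps / 2.0 + jx, h * ps / 2.0 + jy)  # (x, y) µm
    base_poly = _cell_polygon(cell, center, rng)

    p = waveform.pressures
    p_arr, p_peak = p[waveform.arrival_index], p[waveform.peak_index]
    frames, masks, polys = [], [], []
    for i in range(p.size):
        gone = record.detach_index is not None and i >= record.detach_index
        if gone:
            poly = None
        else:
            if i <= waveform.arrival_index:
                area_i = record.A_initial
            else:
                frac = (p[i] - p_arr) / (p_peak - p_arr)
                area_i = record.A_initial + frac * (record.A_final - record.A_initial)
            poly = scale_to_area(base_poly, area_i)
            r_max = np.max(np.hypot(poly[:, 0] - center[0], poly[:, 1] - center[1]))
            if r_max >= min(center[0], center[1]) - ps:
                raise ValueError("cell outline exceeds the canvas")
        if poly is None:
            cov = np.zeros((h, w))
        else:
            cov = _coverage(np.column_stack([poly[:, 1] / ps, poly[:, 0] / ps]), (h, w))
        mask = cov >= 0.5
        img = background + (foreground - background) * cov
        if blur_sigma > 0:
            img = gaussian_filter(img, blur_sigma)
        img += rng.normal(0, noise_sd, size=img.shape)
        np.clip(img, 0, image_spec.max_intensity, out=img)
        frames.append(img.astype(np.uint16))
        masks.append(np.where(mask, 255, 0).astype(np.uint8))
        polys.append(poly)
    return np.stack(frames), np.stack(masks), polys


# ---------------------------------------------------------------------------
# dataset generation

@dataclass(frozen=True)
class DatasetConfig:
    """Full specification of one synthetic study."""

    population: PopulationSpec = PopulationSpec()
    model: eos.StateEquationParams = eos.StateEquationParams(family="tait")
    noise: NoiseSpec = NoiseSpec()
    coupling: SizeCouplingSpec | None = SizeCouplingSpec()
    group_centers: tuple = STUDY_GROUP_CENTERS_KPA
    group_sds: tuple = STUDY_GROUP_SDS_KPA
    group_sizes: tuple = STUDY_GROUP_SIZES
    cv_compliant: bool = True      # cap group SDs at cv_cap * centre
    cv_cap: float = 0.0075
    pressure_span: tuple = PRESSURE_SPAN_KPA
    detach_prob: float = 0.05
    ramp_duration_ms: float = 0.1
    fps: float = 2.0e5
    baseline_frames: int = 5
    seed: int = 0

    def __post_init__(self):
        if len(self.group_centers) != len(self.group_sds) or len(self.group_centers) != len(self.group_sizes):
            raise ValueError("group centers, sds and sizes must have equal length")
        lo, hi = self.pressure_span
        for c in self.group_centers:
            if not lo <= c <= hi:
                raise ValueError(f"group centre {c} kPa outside the sensor range {self.pressure_span}")

    def effective_sds(self) -> np.ndarray:
        sds = np.asarray(self.group_sds, dtype=float)
        if self.cv_compliant:
            sds = np.minimum(sds, self.cv_cap * np.asarray(self.group_centers))
        return sds


def generate_dataset(config: DatasetConfig = DatasetConfig()):
    """Generate a full records table plus a ground-truth provenance dict.

    Peak pressures are truncated-normal draws (+/- 3 sd, clipped to the
    sensor span) around the group centres; each record then runs
    :func:`simulate_response` on its own constant-rate waveform.

    Returns (records, truth): a DataFrame with :data:`RECORD_COLUMNS`
    and a JSON-serialisable dict of every seed and true parameter.
    """
    rng = np.random.default_rng(config.seed)
    pop = dataclasses.replace(config.population,
                              n_cells=int(np.sum(config.group_sizes)),
                              seed=config.seed)
    cells = sample_cell_population(pop)
    sds = config.effective_sds()
    lo, hi = config.pressure_span

    rows = []
    idx = 0
    for g, (centre, sd, size) in enumerate(zip(config.group_centers, sds, config.group_sizes)):
        label = f"Lvl{g + 1}"
        for _ in range(int(size)):
            cell = cells[idx]
            idx += 1
            while True:
                p_peak = rng.normal(centre, sd) if sd > 0 else centre
                if abs(p_peak - centre) <= 3 * sd + 1e-12 and lo <= p_peak <= hi:
                    break
            wf = generate_waveform(config.model.p0, p_peak,
                                   config.ramp_duration_ms, config.fps,
                                   baseline_frames=config.baseline_frames)
            rec = simulate_response(cell, wf, config.model, config.noise,
                                    config.coupling, config.detach_prob, rng)
            rows.append({
                "cell_id": cell.cell_id,
                "group_label": label,
                "p0_kPa": wf.p0,
                "pmax_kPa": rec.p_max,
                "A_initial_um2": rec.A_initial,
                "A_final_um2": rec.A_final,
                "zeta": rec.zeta,
                "perimeter_um": cell.perimeter,
                "angle_deg": cell.angle,
                "detached": rec.detached,
            })

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    truth = {
        "seed": config.seed,
        "model": {
            "family": config.model.family,
            "A0": config.model.A0,
            "p0": config.model.p0,
            "B0": config.model.B0,
            "Bprime": config.model.Bprime,
            "alpha1": config.model.alpha1,
            "kappa": config.model.kappa,
            "alpha3": config.model.alpha3,
            "eps": config.model.eps,
        },
        "noise": {"flow_mode": config.noise.flow_mode, "amplitude": config.noise.amplitude},
        "coupling": None if config.coupling is None else {
            "reference_area": config.coupling.reference_area, "eta": config.coupling.eta,
        },
        "population": dataclasses.asdict(pop),
        "groups": [
            {"label": f"Lvl{g + 1}", "center_kPa": c, "sd_kPa": float(s), "n": int(n)}
            for g, (c, s, n) in enumerate(zip(config.group_centers, sds, config.group_sizes))
        ],
        "pressure_span_kPa": list(config.pressure_span),
        "detach_prob": config.detach_prob,
    }
    return records, truth
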