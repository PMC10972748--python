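"""Seeded synthetic data with exported ground truth.

Generates the four kinds of input the analysis modules consume, each with a
truth table so recovery can be asserted exactly:

* cell populations and rendered multichannel fields (nuclei as disks on a
  uniform background) for segmentation and cell-cycle gating;
* arrayed RNAi screen plates (96-well, 8 control wells each) in the
  three-anchor normalization scheme used for hit calling;
* cycloheximide-chase style exponential decay time courses;
* bio-layer interferometry sensorgrams under the 1:1 Langmuir model.

The image model is deliberately minimal: hard disks, uniform background,
additive Gaussian camera noise.  DNA content is encoded the way DAPI staining
behaves in interphase — mean intensity constant, nuclear *area* scaling with
content — while mitotic nuclei are rendered condensed (smaller, brighter) so
the DAPI-MFI mitosis gate has something to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

PHASES = ("G1", "S", "G2", "M")

#: Default per-phase true channel means (arbitrary fluorescence units).
#: ``dapi`` is the interphase DAPI mean; the generator rescales it per cell so
#: that integrated DAPI is proportional to DNA content (see make_cell_population).
#: ``edu`` is high only in S phase; ``cgas_gfp`` declines from G1 to G2/M
#: (G2 = 0.5 x G1), emulating interphase degradation of nuclear cGAS.
DEFAULT_LEVELS: dict[str, dict[str, float]] = {
    "G1": {"dapi": 200.0, "edu": 30.0, "cgas_gfp": 300.0},
    "S": {"dapi": 200.0, "edu": 600.0, "cgas_gfp": 220.0},
    "G2": {"dapi": 200.0, "edu": 30.0, "cgas_gfp": 150.0},
    "M": {"dapi": 200.0, "edu": 30.0, "cgas_gfp": 150.0},
}

DEFAULT_PHASE_FRACTIONS = {"G1": 0.5, "S": 0.3, "G2": 0.15, "M": 0.05}


@dataclass
class CellTruth:
    """Ground truth for one synthetic nucleus."""

    cell_id: int
    phase: str
    dna_content: float          # genome equivalents, 2.0 (G1) to 4.0 (G2/M)
    centroid_xy: tuple[float, float]  # (x, y) = (col, row), pixels
    radius: float               # pixels
    channel_levels: dict[str, float]  # true in-nucleus mean signal, AU
    cytosol_level: float = 0.0  # true cytosolic signal around the nucleus, AU


@dataclass
class FieldSpec:
    """Rendering parameters for one imaged field."""

    width: int = 1024
    height: int = 1024
    background_level: dict[str, float] | float = 100.0
    noise_sd: dict[str, float] | float = 0.0
    pixel_depth: int = 16
    seed: int = 0
    cytosol_extent: float = 8.0          # cytosol disk radius = nucleus + extent
    cytosol_channels: tuple[str, ...] = ("cgas_gfp",)

    def _per_channel(self, value, channel: str) -> float:
        if isinstance(value, dict):
            return float(value.get(channel, 0.0))
        return float(value)


@dataclass
class ScreenDesign:
    """Layout and noise model of the arrayed siRNA screen.

    The screen mirrors the source assay: a 96-well plate carries 88 library
    wells plus 8 controls — 2 negative-control siRNA wells (anchor 0), 2
    cGAS-targeting siRNA wells (anchor -1) and 4 epoxomicin wells (anchor +1).
    Well values are drawn in anchor (normalized-score) space and mapped to raw
    intensities through the inverse of the piecewise-linear anchor
    normalization, so the planted effect of a gene is its expected score.

    ``well_noise_sd`` is the per-well biological/technical s.d. in anchor
    units.  The default 0.04 corresponds to a Z' factor of ~0.76 against the
    epoxomicin anchor — a high-quality strong-control imaging assay.
    """

    n_genes: int = 972
    sirnas_per_gene: int = 3
    plate_format: int = 96
    controls_per_plate: dict[str, int] = field(
        default_factory=lambda: {"negative": 2, "cgas": 2, "epoxomicin": 4}
    )
    effect_map: dict[str, float] = field(default_factory=dict)  # anchor units
    well_noise_sd: float = 0.04
    # Raw-intensity anchor levels (AU): cgas siRNA, negative control, epoxomicin.
    anchors_mfi: tuple[float, float, float] = (200.0, 500.0, 800.0)
    anchors_integrated: tuple[float, float, float] = (60_000.0, 150_000.0, 240_000.0)
    mean_cells_per_well: float = 1800.0

    def __post_init__(self) -> None:
        if sum(self.controls_per_plate.values()) != 8:
            raise ValueError("controls_per_plate must total 8 wells")
        unknown = set(self.effect_map) - set(self.gene_names())
        if unknown:
            raise ValueError(f"effect requested for genes not in library: {sorted(unknown)[:5]}")

    def gene_names(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def sample_wells_per_plate(self) -> int:
        return self.plate_format - sum(self.controls_per_plate.values())

    @property
    def n_sample_wells(self) -> int:
        return self.n_genes * self.sirnas_per_gene

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_sample_wells / self.sample_wells_per_plate)


@dataclass
class ChaseTruth:
    """Parameters of one exponential-decay chase condition: N(t) = N0 e^(-k t)."""

    condition: str = "control"
    n0: float = 100.0
    rate_k: float = math.log(2) / 4.0   # per hour
    times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)  # hours
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.rate_k < 0:
            raise ValueError("rate_k must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        t = np.asarray(self.times, float)
        if t.size == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be sorted ascending starting at 0")


# ---------------------------------------------------------------------------
# cell populations and fields
# ---------------------------------------------------------------------------

def make_cell_population(
    n: int,
    phase_fractions: dict[str, float] | None = None,
    level_model: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    *,
    field_shape: tuple[int, int] = (1024, 1024),
    base_radius: float = 10.0,
    margin: float = 20.0,
    level_cv: dict[str, float] | None = None,
    cytosol_level: float = 60.0,
    place: bool = True,
) -> list[CellTruth]:
    """Draw a seeded population of nuclei with known phase and signal truth.

    Phase counts are a multinomial draw from ``phase_fractions``.  DNA content
    follows the phase rule (G1 = 2, G2/M = 4, S uniform in between).  Nuclear
    area scales with DNA content at constant DAPI mean in interphase; mitotic
    nuclei have half the G1 area and a 4x DAPI mean, preserving integrated
    DAPI proportional to DNA content.  ``level_cv`` adds per-cell lognormal
    scatter (median-preserving) to the non-DAPI channel levels; the default is
    no scatter so noiseless closure holds downstream.

    With ``place=True`` nuclei get non-overlapping centroids inside the field
    (dart throwing); positions are drawn even when the population is only used
    as a feature table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fractions = dict(phase_fractions or DEFAULT_PHASE_FRACTIONS)
    unknown = set(fractions) - set(PHASES)
    if unknown:
        raise ValueError(f"unknown phase name(s): {sorted(unknown)}")
    probs = np.array([fractions.get(p, 0.0) for p in PHASES], float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("phase fractions must sum to 1")
    levels = level_model or DEFAULT_LEVELS
    cvs = level_cv or {}

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    phases = np.repeat(PHASES, counts)
    rng.shuffle(phases)

    dna = np.empty(n)
    dna[phases == "G1"] = 2.0
    dna[(phases == "G2") | (phases == "M")] = 4.0
    n_s = int(np.sum(phases == "S"))
    dna[phases == "S"] = rng.uniform(2.0, 4.0, n_s)

    # geometry: interphase area ~ dna/2; mitotic area = half the G1 area
    radius = np.where(
        phases == "M",
        base_radius / math.sqrt(2.0),
        base_radius * np.sqrt(dna / 2.0),
    )

    centroids = (
        _place_disks(rng, n, radius, field_shape, margin)
        if place
        else [(0.0, 0.0)] * n
    )

    cells: list[CellTruth] = []
    for i in range(n):
        ph = str(phases[i])
        ch = dict(levels[ph])
        base_dapi = ch.get("dapi", 200.0)
        # integrated DAPI proportional to dna_content by construction:
        # mean = base * (dna/2) * (A_G1 / A)
        area_ratio = (radius[i] / base_radius) ** 2
        ch["dapi"] = base_dapi * (dna[i] / 2.0) / area_ratio
        for name, cv in cvs.items():
            if name in ch and name != "dapi" and cv > 0:
                ch[name] *= float(rng.lognormal(0.0, cv))
        cells.append(
            CellTruth(
                cell_id=i + 1,
                phase=ph,
                dna_content=float(dna[i]),
                centroid_xy=centroids[i],
                radius=float(radius[i]),
                channel_levels=ch,
                cytosol_level=cytosol_level,
            )
        )
    return cells


def _place_disks(rng, n, radii, field_shape, margin):
    """Dart-throw non-overlapping disk centres; error if the field is too full."""
    h, w = field_shape[1], field_shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    placed = 0
    attempts = 0
    max_attempts = 200 * n + 1000
    while placed < n:
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} non-overlapping nuclei in a "
                f"{field_shape[0]}x{field_shape[1]} field"
            )
        attempts += 1
        r = radii[placed]
        x = rng.uniform(margin + r, w - margin - r)
        y = rng.uniform(margin + r, h - margin - r)
        if placed:
            d2 = (xs[:placed] - x) ** 2 + (ys[:placed] - y) ** 2
            if np.any(d2 < (radii[:placed] + r + 2.0) ** 2):
                continue
        xs[placed], ys[placed] = x, y
        placed += 1
    return list(zip(xs, ys))


def truth_table(cells: list[CellTruth]) -> pd.DataFrame:
    """Flatten a population into a ``truth_``-prefixed DataFrame."""
    rows = []
    for c in cells:
        row = {
            "cell_id": c.cell_id,
            "truth_phase": c.phase,
            "truth_dna_content": c.dna_content,
            "truth_x": c.centroid_xy[0],
            "truth_y": c.centroid_xy[1],
            "truth_radius": c.radius,
            "truth_cytosol_level": c.cytosol_level,
        }
        for name, lvl in c.channel_levels.items():
            row[f"truth_{name}_level"] = lvl
        rows.append(row)
    return pd.DataFrame(rows)


def render_field(
    cells: list[CellTruth], spec: FieldSpec
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Render a population as one 16-bit image per channel plus the truth mask.

    Each nucleus is a hard disk at background + its true channel level, so
    background-corrected features recover the planted level; channels listed
    in ``spec.cytosol_channels`` additionally get a larger cytosol disk at
    background + ``cytosol_level`` beneath the nucleus.  Additive Gaussian
    noise (``noise_sd``) is applied last and values are clipped to the pixel
    depth.  Returns ``(channels, label_mask)`` with labels equal to
    ``cell_id``.
    """
    shape = (spec.height, spec.width)
    channel_names: list[str] = sorted(
        {k for c in cells for k in c.channel_levels} or set(DEFAULT_LEVELS["G1"])
    )
    labels = np.zeros(shape, dtype=np.uint16)

    footprints = []
    for c in cells:
        x, y = c.centroid_xy
        if not (c.radius <= x <= spec.width - c.radius and c.radius <= y <= spec.height - c.radius):
            raise ValueError(f"nucleus {c.cell_id} does not fit in the field")
        rr, cc = _disk((y, x), c.radius, shape=shape)
        if np.any(labels[rr, cc] != 0):
            raise ValueError(f"nucleus {c.cell_id} overlaps another nucleus")
        labels[rr, cc] = c.cell_id
        footprints.append((rr, cc))

    rng = np.random.default_rng(spec.seed)
    maxval = 2 ** spec.pixel_depth - 1
    channels: dict[str, np.ndarray] = {}
    for name in channel_names:
        img = np.full(shape, spec._per_channel(spec.background_level, name), dtype=float)
        if name in spec.cytosol_channels:
            for c in cells:
                if c.cytosol_level <= 0:
                    continue
                x, y = c.centroid_xy
                rr, cc = _disk((y, x), c.radius + spec.cytosol_extent, shape=shape)
                bg = spec._per_channel(spec.background_level, name)
                np.maximum.at(img, (rr, cc), bg + c.cytosol_level)
        bg = spec._per_channel(spec.background_level, name)
        for c, (rr, cc) in zip(cells, footprints):
            img[rr, cc] = bg + c.channel_levels.get(name, 0.0)
        sd = spec._per_channel(spec.noise_sd, name)
        if sd > 0:
            img = img + rng.normal(0.0, sd, shape)
        channels[name] = np.clip(np.rint(img), 0, maxval).astype(np.uint16)
    return channels, labels


def measure_population(
    cells: list[CellTruth],
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate per-cell feature extraction directly from truth (no rendering).

    Produces the table the gating stage consumes — integrated DAPI, DAPI MFI,
    EdU MFI and cGAS-GFP MFI per cell — with median-preserving lognormal
    measurement scatter of coefficient ``noise_cv`` on every measured value.
    Useful for large populations where rendering full fields would be wasteful.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for c in cells:
        area = math.pi * c.radius**2
        def meas(v):
            if noise_cv == 0:
                return v
            return v * float(rng.lognormal(0.0, noise_cv))
        dapi_mfi = meas(c.channel_levels["dapi"])
        rows.append(
            {
                "cell_id": c.cell_id,
                "truth_phase": c.phase,
                "truth_dna_content": c.dna_content,
                "dapi_mfi": dapi_mfi,
                "dapi_integrated": dapi_mfi * area,
                "edu_mfi": meas(c.channel_levels.get("edu", 0.0)),
                "cgas_gfp_mfi": meas(c.channel_levels.get("cgas_gfp", 0.0)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# screen plates
# ---------------------------------------------------------------------------

_ROWS = "ABCDEFGH"


def make_plate_layout(design: ScreenDesign) -> pd.DataFrame:
    """Assign genes/siRNAs and control roles to wells across plates.

    Column 1 of every plate carries the 8 control wells (negative, cGAS
    siRNA, epoxomicin top to bottom); the remaining 88 wells take library
    siRNAs in order.  Gene g's three siRNA wells are consecutive.
    """
    control_roles: list[str] = []
    for role in ("negative", "cgas", "epoxomicin"):
        control_roles += [role] * design.controls_per_plate[role]
    genes = design.gene_names()
    pairs = [(g, f"si{j + 1}") for g in genes for j in range(design.sirnas_per_gene)]
    rows = []
    k = 0
    for p in range(design.n_plates):
        plate_id = f"P{p + 1:02d}"
        for col in range(1, 13):
            for r, row in enumerate(_ROWS):
                well = f"{row}{col}"
                if col == 1:
                    rows.append(
                        {"plate_id": plate_id, "well_id": well,
                         "role": control_roles[r], "gene": None, "sirna_id": None}
                    )
                elif k < len(pairs):
                    g, s = pairs[k]
                    rows.append(
                        {"plate_id": plate_id, "well_id": well,
                         "role": "sample", "gene": g, "sirna_id": s}
                    )
                    k += 1
    return pd.DataFrame(rows)


def score_to_raw(score, anchors: tuple[float, float, float]):
    """Inverse of the three-anchor normalization: score -> raw intensity."""
    c_minus, c0, c_plus = anchors
    score = np.asarray(score, float)
    return np.where(score < 0, c0 + score * (c0 - c_minus), c0 + score * (c_plus - c0))


def simulate_screen_plates(
    design: ScreenDesign | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate raw per-well screen measurements with planted truth.

    Every well receives a true anchor-space score (controls at -1/0/+1,
    samples at their gene's planted effect) plus Gaussian well noise of
    ``well_noise_sd``, then is mapped to raw MFI and integrated intensity
    through the inverse normalization.  Truth columns carry the planted
    effect and score so downstream recovery is checkable.
    """
    design = design or ScreenDesign()
    rng = np.random.default_rng(seed)
    layout = make_plate_layout(design)
    base = {"sample": 0.0, "negative": 0.0, "cgas": -1.0, "epoxomicin": 1.0}
    sigma = design.well_noise_sd

    truth_score = layout["role"].map(base).to_numpy(float)
    is_sample = (layout["role"] == "sample").to_numpy()
    effects = layout["gene"].map(lambda g: design.effect_map.get(g, 0.0) if g else 0.0)
    truth_score = truth_score + np.where(is_sample, effects.to_numpy(float), 0.0)

    n = len(layout)
    score_mfi = truth_score + rng.normal(0.0, sigma, n)
    score_int = truth_score + rng.normal(0.0, sigma, n)

    out = layout.copy()
    out["n_cells"] = rng.poisson(design.mean_cells_per_well, n)
    out["raw_mfi"] = score_to_raw(score_mfi, design.anchors_mfi)
    out["raw_integrated"] = score_to_raw(score_int, design.anchors_integrated)
    out["truth_effect"] = np.where(is_sample, effects.to_numpy(float), np.nan)
    out["truth_score"] = truth_score
    return out


# ---------------------------------------------------------------------------
# chase time courses
# ---------------------------------------------------------------------------

def simulate_chase(truth: ChaseTruth, seed: int = 0, n_replicates: int = 1) -> pd.DataFrame:
    """Exponential-decay chase: N(t) = N0 e^(-k t) with multiplicative noise.

    Noise is median-preserving lognormal, exp(N(0, cv)), so log-space decay
    fits are unbiased; with ``noise_cv = 0`` values are exact.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(truth.times, float)
    rows = []
    for rep in range(n_replicates):
        clean = truth.n0 * np.exp(-truth.rate_k * t)
        noisy = clean * (
            np.exp(rng.normal(0.0, truth.noise_cv, t.size)) if truth.noise_cv > 0 else 1.0
        )
        for ti, vi in zip(t, np.atleast_1d(noisy)):
            rows.append(
                {"condition": truth.condition, "replicate": rep + 1,
                 "time_h": ti, "abundance": vi}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BLI sensorgrams
# ---------------------------------------------------------------------------

def simulate_sensorgrams(
    kon: float,
    koff: float,
    concentrations: list[float],
    t_assoc: float = 300.0,
    t_dissoc: float = 600.0,
    rmax: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Simulate 1:1 Langmuir sensorgrams for a concentration series.

    Association: R(t) = Req (1 - e^(-(kon C + koff) t)), Req = rmax C/(C + Kd);
    dissociation: R(t) = R(t_assoc) e^(-koff (t - t_assoc)).  Default timing
    follows the standard 5 min association / 10 min dissociation protocol.
    Columns: time_s, response, conc_M, phase ('assoc'/'dissoc').
    """
    if kon <= 0 or koff <= 0 or rmax <= 0:
        raise ValueError("kon, koff and rmax must be positive")
    if not concentrations:
        raise ValueError("at least one analyte concentration is required")
    rng = np.random.default_rng(seed)
    kd = koff / kon
    t_a = np.arange(0.0, t_assoc + dt / 2, dt)
    t_d = np.arange(dt, t_dissoc + dt / 2, dt)
    frames = []
    for conc in concentrations:
        if conc < 0:
            raise ValueError("concentrations must be non-negative")
        req = rmax * conc / (conc + kd)
        kobs = kon * conc + koff
        r_a = req * (1.0 - np.exp(-kobs * t_a))
        r_split = req * (1.0 - np.exp(-kobs * t_assoc))
        r_d = r_split * np.exp(-koff * t_d)
        df = pd.DataFrame(
            {
                "time_s": np.concatenate([t_a, t_assoc + t_d]),
                "response": np.concatenate([r_a, r_d]),
                "conc_M": conc,
                "phase": ["assoc"] * t_a.size + ["dissoc"] * t_d.size,
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if noise_sd > 0:
        out["response"] += rng.normal(0.0, noise_sd, len(out))
    return out
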