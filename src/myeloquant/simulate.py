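"""Synthetic multiplex images and survival cohorts with known ground truth.

The image simulator renders myeloid cells as disks on a background, one
raster per marker, so that every downstream stage (masking, object
detection, per-cell measurement, gating) can be validated against an
analytic ground truth.  Two populations are drawn:

* ``microglia`` — bright on the microglial marker (P2RY12 or TMEM119),
* ``tam`` — tumor-associated macrophages, dim on the microglial marker.

Both are bright on the pan-myeloid marker Iba1.  CD14/CD163 are modelled
as overlapping log-normal distributions for both populations (a continuum
rather than a clean split), which is what makes those markers unsuitable
for delineating the populations.  Tissue presets mimic the qualitative
composition of epilepsy (almost pure microglia, perivascular CD163+ cells
along a vessel path), meningioma / low-grade tumors (TAM-dominated) and
grade IV glioblastoma (a mixture).

The cohort simulator draws per-patient survival times from an exponential
proportional-hazards model whose hazard depends on the high/low
microglia:TAM-ratio group and on MGMT methylation status, so that the
median-split -> Kaplan-Meier -> Cox chain can be checked for parameter
recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as _disk_coords

from .errors import PlacementError, ValidationError

MICROGLIAL_MARKERS = ("P2RY12", "TMEM119")
CD_MARKERS = ("CD14", "CD163")
TISSUE_TYPES = ("epilepsy", "meningioma", "low_grade", "grade_iv")

__all__ = [
    "MarkerIntensity",
    "ImageSimSpec",
    "GroundTruth",
    "CohortSimSpec",
    "simulate_image",
    "simulate_cohort",
    "tissue_preset",
    "default_intensity_model",
    "write_simulated_image",
    "write_ground_truth",
    "write_cohort",
]


@dataclass(frozen=True)
class MarkerIntensity:
    """Distribution of per-cell foreground mean intensity for one marker.

    ``dist="normal"`` draws N(mean, sd) clipped at zero.  ``dist="lognormal"``
    treats ``mean`` as the median and ``sd`` as the sigma of the underlying
    log — the parameterisation used for the CD14/CD163 continuum.
    """

    mean: float
    sd: float
    dist: str = "normal"

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValidationError(f"intensity mean must be >= 0, got {self.mean}")
        if self.sd < 0:
            raise ValidationError(f"intensity sd must be >= 0, got {self.sd}")
        if self.dist not in ("normal", "lognormal"):
            raise ValidationError(f"unknown intensity distribution {self.dist!r}")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.dist == "normal":
            return np.clip(rng.normal(self.mean, self.sd, size), 0.0, None)
        return self.mean * np.exp(rng.normal(0.0, self.sd, size))


IntensityModel = Mapping[str, Mapping[str, MarkerIntensity]]


def default_intensity_model(
    microglial_marker: str = "P2RY12", cd_marker: str | None = "CD14"
) -> dict[str, dict[str, MarkerIntensity]]:
    """Default per-population intensity model on an arbitrary 16-bit-like scale.

    The microglial marker is strongly bimodal between the populations; the
    CD marker is an overlapping log-normal continuum shifted upward in TAMs.
    """
    model = {
        "microglia": {
            "Iba1": MarkerIntensity(18000.0, 1500.0),
            microglial_marker: MarkerIntensity(14000.0, 1200.0),
        },
        "tam": {
            "Iba1": MarkerIntensity(20000.0, 1800.0),
            microglial_marker: MarkerIntensity(2500.0, 1200.0),
        },
    }
    if cd_marker is not None:
        model["microglia"][cd_marker] = MarkerIntensity(900.0, 0.9, dist="lognormal")
        model["tam"][cd_marker] = MarkerIntensity(2800.0, 0.9, dist="lognormal")
    return model


@dataclass
class ImageSimSpec:
    """Parameters of one simulated multiplex field of view."""

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.5
    n_microglia: int = 100
    n_tam: int = 100
    cell_radius_px_range: tuple[int, int] = (4, 7)
    marker_panel: tuple[str, ...] = ("Iba1", "P2RY12", "CD14")
    intensity_model: IntensityModel = field(default_factory=default_intensity_model)
    background_level: float = 500.0
    noise_sd: float = 200.0
    blur_sigma_px: float = 1.0
    vessel_fraction: float = 0.0
    overlap_budget: float = 0.0
    seed: int = 0
    case_id: str = "sim"
    tissue_type: str = "grade_iv"

    def __post_init__(self) -> None:
        if self.n_microglia < 0 or self.n_tam < 0:
            raise ValidationError("cell counts must be non-negative")
        if self.n_microglia + self.n_tam < 1:
            raise ValidationError("at least one cell is required (empty scene disallowed)")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        if self.blur_sigma_px < 0 or self.noise_sd < 0 or self.background_level < 0:
            raise ValidationError("blur/noise/background must be >= 0")
        if not 0.0 <= self.vessel_fraction <= 1.0:
            raise ValidationError("vessel_fraction must be in [0, 1]")
        if not 0.0 <= self.overlap_budget < 1.0:
            raise ValidationError("overlap_budget must be in [0, 1)")
        lo, hi = self.cell_radius_px_range
        if lo < 1 or hi < lo:
            raise ValidationError("cell_radius_px_range must satisfy 1 <= min <= max")
        panel = tuple(self.marker_panel)
        if len(set(panel)) != len(panel):
            raise ValidationError("marker_panel names must be unique")
        if "Iba1" not in panel:
            raise ValidationError("marker_panel must include Iba1")
        mg = [m for m in panel if m in MICROGLIAL_MARKERS]
        if len(mg) != 1:
            raise ValidationError(
                "marker_panel must include exactly one of " + "/".join(MICROGLIAL_MARKERS)
            )
        cd = [m for m in panel if m in CD_MARKERS]
        if len(cd) > 1:
            raise ValidationError("marker_panel may include at most one of CD14/CD163")
        if self.tissue_type not in TISSUE_TYPES:
            raise ValidationError(f"tissue_type must be one of {TISSUE_TYPES}")
        for pop in ("microglia", "tam"):
            if pop not in self.intensity_model:
                raise ValidationError(f"intensity_model missing population {pop!r}")
            for m in panel:
                if m not in self.intensity_model[pop]:
                    raise ValidationError(f"intensity_model[{pop!r}] missing marker {m!r}")
        # the bimodality the gating relies on: microglia brighter on their marker
        mg_marker = mg[0]
        if not (
            self.intensity_model["microglia"][mg_marker].mean
            > self.intensity_model["tam"][mg_marker].mean
        ):
            raise ValidationError(
                f"microglial-marker mean for microglia must exceed that for TAMs ({mg_marker})"
            )

    @property
    def microglial_marker(self) -> str:
        return next(m for m in self.marker_panel if m in MICROGLIAL_MARKERS)

    @property
    def cd_marker(self) -> str | None:
        return next((m for m in self.marker_panel if m in CD_MARKERS), None)


@dataclass
class GroundTruth:
    """Per-cell ground truth for one simulated image.

    ``cells`` has one row per cell: true_label, x, y (pixel centre), radius_px,
    on_vessel, and one ``true_<marker>`` column per panel marker holding the
    rendered foreground mean.
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        labels = set(self.cells["true_label"].unique())
        if not labels <= {"microglia", "tam"}:
            raise ValidationError(f"unexpected ground-truth labels: {labels}")

    @property
    def n_microglia(self) -> int:
        return int((self.cells["true_label"] == "microglia").sum())

    @property
    def n_tam(self) -> int:
        return int((self.cells["true_label"] == "tam").sum())


def _place_cells(
    spec: ImageSimSpec, rng: np.random.Generator, radii: np.ndarray, on_vessel: np.ndarray
) -> np.ndarray:
    """Rejection-sample non-overlapping centres; vessel cells hug a line path."""
    h, w = spec.height_px, spec.width_px
    centers = np.empty((len(radii), 2))  # (x, y)
    # vessel path: a random straight line through the image centre region
    theta = rng.uniform(0, np.pi)
    cx, cy = rng.uniform(0.3 * w, 0.7 * w), rng.uniform(0.3 * h, 0.7 * h)
    direction = np.array([np.cos(theta), np.sin(theta)])
    half_diag = float(np.hypot(w, h))
    max_attempts = 2000
    for i, (r, vessel) in enumerate(zip(radii, on_vessel)):
        placed = False
        for _ in range(max_attempts):
            if vessel:
                t = rng.uniform(-half_diag / 2, half_diag / 2)
                jitter = rng.normal(0.0, 2.0 + r, 2)
                x, y = np.array([cx, cy]) + t * direction + jitter
                if not (r <= x < w - r and r <= y < h - r):
                    continue
            else:
                x = rng.uniform(r, w - r)
                y = rng.uniform(r, h - r)
            if i:
                d = np.hypot(centers[:i, 0] - x, centers[:i, 1] - y)
                # at budget 0 add a 2-px gap so rendered disks can never be
                # 8-adjacent and connected components stay one-to-one with cells
                gap = 2.0 if spec.overlap_budget == 0 else 0.0
                min_sep = (radii[:i] + r + gap) * (1.0 - spec.overlap_budget)
                if np.any(d < min_sep):
                    continue
            centers[i] = (x, y)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{len(radii)} within overlap budget "
                f"{spec.overlap_budget} after {max_attempts} attempts"
            )
    return centers


def simulate_image(spec: ImageSimSpec):
    """Render one multiplex image and its ground truth.

    Returns ``(MultiplexImage, GroundTruth)``.  Each cell is a disk whose
    per-marker foreground intensity is drawn from the population's intensity
    model, added onto the background, blurred by a Gaussian PSF and corrupted
    by additive Gaussian noise.  Deterministic for a fixed seed.
    """
    from .segmentation import MultiplexImage  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    n = spec.n_microglia + spec.n_tam
    labels = np.array(["microglia"] * spec.n_microglia + ["tam"] * spec.n_tam)
    lo, hi = spec.cell_radius_px_range
    radii = rng.integers(lo, hi + 1, size=n).astype(float)
    on_vessel = np.zeros(n, dtype=bool)
    n_vessel = int(round(spec.vessel_fraction * spec.n_tam))
    if n_vessel:
        on_vessel[spec.n_microglia : spec.n_microglia + n_vessel] = True
    centers = _place_cells(spec, rng, radii, on_vessel)

    fg = {}
    for marker in spec.marker_panel:
        vals = np.empty(n)
        for pop in ("microglia", "tam"):
            sel = labels == pop
            vals[sel] = spec.intensity_model[pop][marker].draw(rng, int(sel.sum()))
        fg[marker] = vals

    shape = (spec.height_px, spec.width_px)
    channels: dict[str, np.ndarray] = {}
    for marker in spec.marker_panel:
        img = np.full(shape, spec.background_level, dtype=np.float64)
        for i in range(n):
            rr, cc = _disk_coords((centers[i, 1], centers[i, 0]), radii[i], shape=shape)
            img[rr, cc] += fg[marker][i]
        if spec.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, spec.blur_sigma_px)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, shape)
        channels[marker] = img

    cells = pd.DataFrame(
        {
            "true_label": labels,
            "x": centers[:, 0],
            "y": centers[:, 1],
            "radius_px": radii,
            "on_vessel": on_vessel,
        }
    )
    for marker in spec.marker_panel:
        cells[f"true_{marker}"] = fg[marker]

    image = MultiplexImage(
        channels=channels,
        pixel_size_um=spec.pixel_size_um,
        case_id=spec.case_id,
        tissue_type=spec.tissue_type,
    )
    return image, GroundTruth(cells)


def tissue_preset(
    tissue_type: str,
    n_cells: int = 200,
    seed: int = 0,
    case_id: str | None = None,
    **overrides,
) -> ImageSimSpec:
    """Build an ImageSimSpec mimicking the myeloid composition of one tissue type.

    epilepsy    — almost pure microglia; the few CD-positive cells sit along a
                  vessel path (perivascular macrophages); CD expression near
                  background otherwise.
    meningioma  — TAM-dominated (non-brain origin, few resident microglia).
    low_grade   — TAM-dominated.
    grade_iv    — a variable mixture of both populations.
    """
    if tissue_type not in TISSUE_TYPES:
        raise ValidationError(f"tissue_type must be one of {TISSUE_TYPES}")
    fractions = {"epilepsy": 0.98, "meningioma": 0.10, "low_grade": 0.15, "grade_iv": 0.40}
    n_mg = int(round(fractions[tissue_type] * n_cells))
    n_tam = n_cells - n_mg
    kwargs: dict = dict(
        n_microglia=n_mg,
        n_tam=n_tam,
        tissue_type=tissue_type,
        seed=seed,
        case_id=case_id or f"{tissue_type}_{seed}",
    )
    if tissue_type == "epilepsy":
        marker = overrides.get("marker_panel", ("Iba1", "P2RY12", "CD14"))
        mg_marker = next(m for m in marker if m in MICROGLIAL_MARKERS)
        cd = next((m for m in marker if m in CD_MARKERS), None)
        model = default_intensity_model(mg_marker, cd)
        if cd is not None:
            # quasi-steady-state control: CD expression near background in
            # parenchymal microglia; vessel-associated cells carry the high tail
            model["microglia"][cd] = MarkerIntensity(500.0, 0.5, dist="lognormal")
            model["tam"][cd] = MarkerIntensity(4000.0, 0.5, dist="lognormal")
        kwargs.update(intensity_model=model, vessel_fraction=1.0, marker_panel=tuple(marker))
    kwargs.update(overrides)
    return ImageSimSpec(**kwargs)


@dataclass
class CohortSimSpec:
    """Parameters of a simulated survival cohort.

    Survival times follow an exponential proportional-hazards model: the
    baseline hazard (events/month) is scaled by ``exp(log_hr_ratio_high)``
    for patients above the realized median microglia:TAM ratio and by
    ``exp(log_hr_mgmt)`` for MGMT-methylated patients.  Censoring is an
    independent exponential clock.
    """

    n_patients: int = 100
    baseline_hazard: float = 0.05
    log_hr_ratio_high: float = -1.0
    log_hr_mgmt: float = -1.0
    censoring_rate: float = 0.0
    ratio_lognorm_mu: float = 0.0
    ratio_lognorm_sigma: float = 1.0
    p_mgmt: float = 0.45
    p_idh1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValidationError("censoring_rate must be >= 0")
        if self.ratio_lognorm_sigma < 0:
            raise ValidationError("ratio_lognorm_sigma must be >= 0")
        for p in (self.p_mgmt, self.p_idh1):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a patient cohort; returns one row per patient.

    Columns: case_id, time_months, event, ratio, ratio_group_true (the
    generating high/low indicator), mgmt_methylated, idh1_mutant.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ratio = np.exp(rng.normal(spec.ratio_lognorm_mu, spec.ratio_lognorm_sigma, n))
    mgmt = rng.random(n) < spec.p_mgmt
    idh1 = rng.random(n) < spec.p_idh1
    high = ratio > np.median(ratio)
    hazard = spec.baseline_hazard * np.exp(
        spec.log_hr_ratio_high * high + spec.log_hr_mgmt * mgmt
    )
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censoring_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "case_id": [f"pt{i:04d}" for i in range(n)],
            "time_months": time,
            "event": event,
            "ratio": ratio,
            "ratio_group_true": np.where(high, "high", "low"),
            "mgmt_methylated": mgmt.astype(int),
            "idh1_mutant": idh1.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# serialization


def write_simulated_image(image, path: str | Path) -> Path:
    """Write a multi-channel TIFF plus sidecar JSON; returns the TIFF path."""
    from .io import write_multiplex

    return write_multiplex(image, path)


def write_ground_truth(truth: GroundTruth, spec: ImageSimSpec, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(out / f"{spec.case_id}_truth.csv", index=False)
    echo = asdict(spec)
    echo["intensity_model"] = {
        pop: {m: asdict(mi) for m, mi in markers.items()}
        for pop, markers in spec.intensity_model.items()
    }
    (out / f"{spec.case_id}_spec.json").write_text(json.dumps(echo, indent=2))


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)
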