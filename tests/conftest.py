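import numpy as np
import pandas as pd
import pytest

import myeloquant as mq


@pytest.fixture()
def noiseless_spec():
    """Small zero-noise, zero-blur scene where ground truth is exact."""
    return mq.ImageSimSpec(
        width_px=512,
        height_px=512,
        n_microglia=25,
        n_tam=15,
        noise_sd=0.0,
        blur_sigma_px=0.0,
        background_level=0.0,
        seed=7,
        case_id="clean",
    )


@pytest.fixture()
def noiseless_scene(noiseless_spec):
    return mq.simulate_image(noiseless_spec)


@pytest.fixture()
def noiseless_table(noiseless_scene):
    image, truth = noiseless_scene
    masks = [mq.make_channel_mask(image, m, "fixed", 1.0) for m in image.markers]
    labeled = mq.label_objects(mq.combine_masks(masks), min_area_px=5)
    return mq.measure_cells(labeled, image), truth


def midpoint_scheme(spec: "mq.ImageSimSpec") -> "mq.GatingScheme":
    """Split gate at the midpoint of the two populations' microglial-marker means.

    The Iba1 master gate sits halfway between background and the dimmer
    population's Iba1 mean, so noise-driven objects land in debris.
    """
    m = spec.microglial_marker
    mid = 0.5 * (
        spec.intensity_model["microglia"][m].mean + spec.intensity_model["tam"][m].mean
    )
    iba1_lo = min(spec.intensity_model[p]["Iba1"].mean for p in ("microglia", "tam"))
    master = spec.background_level + 0.5 * (iba1_lo - spec.background_level)
    return mq.GatingScheme.from_thresholds(
        master_iba1_min=max(master, 1.0), split_threshold=mid, split_marker=m
    )


def synthetic_cell_table(
    p2ry12: np.ndarray,
    iba1: float = 18000.0,
    case_id: str = "synthetic",
    tissue_type: str = "grade_iv",
    area_mm2: float = 1.0,
) -> "mq.CellTable":
    """CellTable built directly from per-cell intensities (no image rendering)."""
    n = len(p2ry12)
    return mq.CellTable(
        pd.DataFrame(
            {
                "case_id": case_id,
                "cell_id": np.arange(1, n + 1),
                "tissue_type": tissue_type,
                "x": np.zeros(n),
                "y": np.zeros(n),
                "area_px": np.full(n, 80),
                "area_um2": np.full(n, 20.0),
                "tissue_area_mm2": area_mm2,
                "mean_Iba1": np.full(n, float(iba1)),
                "mean_P2RY12": np.asarray(p2ry12, dtype=float),
            }
        )
    )
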