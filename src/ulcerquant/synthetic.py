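"""Seeded synthetic fixtures: lesion images, well plates, rater panels.

No photograph from the original ulcer studies is publicly deposited, so
every input the pipeline consumes is emulated here with ground truth
attached:

* gastric-like images — pink tissue background with Gaussian pixel noise,
  either elongated high-red stripes (ethanol-type phenotype) or dark
  low-value spots (stress/WIRE-type phenotype), an optional white specular
  patch, and the exact lesion mask used to paint them;
* a blood-dilution well plate rendered from a known standard line, so the
  calibration fit can be round-tripped through rendering + measurement;
* multi-rater score panels built from true ulcer indices plus per-method
  Gaussian rater noise.

All generators are pure functions of their spec + seed.  Randomness comes
from ``numpy.random.default_rng`` (PCG64), whose algorithm identity keeps
fixtures bit-stable across sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .calibration import CalibrationCurve, DilutionSeries
from .imaging import RGBImage

__all__ = [
    "LesionSpec",
    "PanelSpec",
    "GenerationError",
    "make_gastric_image",
    "make_well_plate",
    "measure_wells",
    "make_rater_panel",
    "materialize_fixture_dir",
]

DEFAULT_SIZE = (512, 512)
DEFAULT_BACKGROUND = (205, 145, 150)  # tissue pink
SPECULAR_RGB = (252, 252, 252)
WIRE_SPOT_RGB = (60, 45, 50)
STRIPE_ASPECT = 6.0  # semi-major : semi-minor of ethanol stripes


class GenerationError(RuntimeError):
    """Raised when a fixture spec cannot be realised (e.g. area target)."""


@dataclass(frozen=True)
class LesionSpec:
    """Specification of one synthetic gastric image.

    ``area_fraction_target`` is the fraction of the image the ground-truth
    lesion mask should cover (met within 10% for targets in [0.01, 0.3]).
    ``lesion_red`` sets the red channel of ethanol-type stripes; the
    stress-type dark spots use a fixed dark triple instead.
    """

    phenotype: Literal["ethanol_stripe", "wire_spot"] = "ethanol_stripe"
    n_lesions: int = 3
    lesion_red: int = 220
    background_rgb: tuple[int, int, int] = DEFAULT_BACKGROUND
    area_fraction_target: float = 0.05
    noise_sd: float = 2.0
    seed: int = 0
    size: tuple[int, int] = DEFAULT_SIZE
    specular: bool = False

    def lesion_rgb(self) -> tuple[int, int, int]:
        if self.phenotype == "wire_spot":
            return WIRE_SPOT_RGB
        return (self.lesion_red, 40, 55)


@dataclass(frozen=True)
class PanelSpec:
    """Specification of paired rater panels (manual-rubric vs image-analysis).

    Each cell is the subject's true UI plus zero-mean Gaussian rater noise
    with a method-specific SD, floored at 0.
    """

    true_ui: tuple[float, ...]
    rater_noise_sd_cco: float = 15.0
    rater_noise_sd_ia: float = 3.0
    n_raters: int = 8
    seed: int = 0


def _place_ellipses(
    rng: np.random.Generator,
    shape: tuple[int, int],
    target_px: int,
    n_lesions: int,
    aspect: float,
) -> np.ndarray:
    """Paint random ellipses until the mask union is near the target area.

    The first draws split the target evenly over ``n_lesions`` ellipses;
    overlap is allowed, so further draws sized to the remaining deficit
    top the union up (``n_lesions`` is a minimum lesion count).  Each
    ellipse is placed fully inside the frame using its rotation-aware
    bounding extents.
    """
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    max_semi = 0.45 * min(H, W)
    per_lesion = target_px / n_lesions

    def try_add(area: float) -> bool:
        b = math.sqrt(area / (math.pi * aspect))
        a = min(aspect * b, max_semi)
        b = max(area / (math.pi * a), 1.0)
        for _ in range(200):
            rot = rng.uniform(0, math.pi)
            er = math.hypot(a * math.cos(rot), b * math.sin(rot)) + 2
            ec = math.hypot(a * math.sin(rot), b * math.cos(rot)) + 2
            if 2 * er >= H or 2 * ec >= W:
                continue
            r0 = rng.uniform(er, H - er)
            c0 = rng.uniform(ec, W - ec)
            rr, cc = ellipse(r0, c0, a, b, shape=shape, rotation=rot)
            if rr.size == 0:
                continue
            mask[rr, cc] = True
            return True
        return False

    for _ in range(n_lesions * 60):
        deficit = target_px - int(mask.sum())
        if deficit <= 0.02 * target_px:
            break
        if not try_add(min(per_lesion, deficit)):
            raise GenerationError(
                f"could not place lesion area in a {H}x{W} image"
            )
    if abs(int(mask.sum()) - target_px) > 0.10 * max(target_px, 1):
        raise GenerationError("lesion area target unreachable within 10%")
    return mask


def make_gastric_image(spec: LesionSpec) -> tuple[RGBImage, np.ndarray]:
    """Render a synthetic gastric image and its ground-truth lesion mask.

    The background is uniform tissue pink plus per-pixel Gaussian noise;
    lesion pixels are painted with the phenotype color before the noise is
    added, so mask and image are consistent by construction.  Identical
    specs (same seed) produce bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    img = np.empty((H, W, 3), dtype=float)
    img[:] = spec.background_rgb

    target_px = int(round(spec.area_fraction_target * H * W))
    if target_px > 0:
        aspect = STRIPE_ASPECT if spec.phenotype == "ethanol_stripe" else 1.0
        mask = _place_ellipses(rng, (H, W), target_px, spec.n_lesions, aspect)
        img[mask] = spec.lesion_rgb()
    else:
        mask = np.zeros((H, W), dtype=bool)

    if spec.specular:
        rr, cc = disk((int(H * 0.15), int(W * 0.8)), min(H, W) * 0.06, shape=(H, W))
        img[rr, cc] = SPECULAR_RGB
        mask[rr, cc] = False

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return RGBImage(img), mask


def make_well_plate(
    curve: CalibrationCurve,
    series: DilutionSeries,
    noise_sd: float = 0.0,
    seed: int = 0,
    cell: int = 100,
) -> tuple[RGBImage, list[dict], pd.DataFrame]:
    """Render a blood-dilution plate from a known standard line.

    Each well is a disk whose mean red value is 255 * (slope * x +
    intercept + noise) clipped to [0, 255]; ``noise_sd`` is on the
    response (fraction) scale.  Returns the image, circular well ROIs
    (cx, cy, radius, concentration), and the noiseless response table.
    """
    rng = np.random.default_rng(seed)
    concs = list(series)
    ncols = 3
    nrows = math.ceil(len(concs) / ncols)
    H, W = nrows * cell, ncols * cell
    img = np.empty((H, W, 3), dtype=float)
    img[:] = (230, 230, 232)  # plate plastic

    rois = []
    rows = []
    radius = cell * 0.36
    for i, x in enumerate(concs):
        r, c = divmod(i, ncols)
        cy, cx = r * cell + cell // 2, c * cell + cell // 2
        y = curve.response_at(x)
        red = 255.0 * (y + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
        red = min(max(red, 0.0), 255.0)
        rr, cc = disk((cy, cx), radius, shape=(H, W))
        img[rr, cc, 0] = red
        img[rr, cc, 1] = red * 0.22
        img[rr, cc, 2] = red * 0.28
        rois.append({"cx": cx, "cy": cy, "radius": radius, "concentration": x})
        rows.append({"concentration": x, "response": y})
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return RGBImage(img), rois, pd.DataFrame(rows)


def measure_wells(image: RGBImage, rois: list[dict]) -> np.ndarray:
    """Mean red response (red/255) inside each well ROI."""
    responses = []
    for roi in rois:
        rr, cc = disk(
            (roi["cy"], roi["cx"]), roi["radius"], shape=image.pixels.shape[:2]
        )
        responses.append(image.pixels[rr, cc, 0].astype(float).mean() / 255.0)
    return np.asarray(responses)


def make_rater_panel(spec: PanelSpec):
    """Paired score panels for the manual-rubric and image-analysis methods.

    Returns (cco_panel, ia_panel) as RaterPanel objects; each cell is
    true_ui + N(0, method SD), floored at 0.
    """
    from .agreement import RaterPanel

    rng = np.random.default_rng(spec.seed)
    true = np.asarray(spec.true_ui, dtype=float)[:, None]
    shape = (true.shape[0], spec.n_raters)
    cco = np.maximum(true + rng.normal(0.0, spec.rater_noise_sd_cco, shape), 0.0)
    ia = np.maximum(true + rng.normal(0.0, spec.rater_noise_sd_ia, shape), 0.0)
    return RaterPanel(cco), RaterPanel(ia)


def materialize_fixture_dir(
    outdir: str | Path,
    seed: int = 0,
    n_control: int = 3,
    n_treated: int = 3,
    treated_area: float = 0.08,
    control_area: float = 0.01,
) -> Path:
    """Write a complete fixture set: images + masks + CSV tables.

    Produces control and lesioned gastric images with their ground-truth
    masks, a rendered blood-dilution plate with its standard table, and a
    paired rater-panel CSV — everything the command-line pipeline needs.
    """
    from .calibration import dilution_series
    from .imaging import save_image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(n_control + n_treated + 2)]

    manifest = []
    for i in range(n_control):
        spec = LesionSpec(
            area_fraction_target=control_area, seed=child_seeds[i] % 2**31
        )
        img, mask = make_gastric_image(spec)
        name = f"control_{i}.png"
        save_image(img, outdir / "images" / name)
        _save_mask(mask, outdir / "masks" / name)
        manifest.append({"image": name, "group": "control"})
    for i in range(n_treated):
        spec = LesionSpec(
            area_fraction_target=treated_area,
            seed=child_seeds[n_control + i] % 2**31,
        )
        img, mask = make_gastric_image(spec)
        name = f"treated_{i}.png"
        save_image(img, outdir / "images" / name)
        _save_mask(mask, outdir / "masks" / name)
        manifest.append({"image": name, "group": "treated"})
    pd.DataFrame(manifest).to_csv(outdir / "manifest.csv", index=False)

    curve = CalibrationCurve(slope=0.4432, intercept=0.05, r_squared=1.0, n_points=6)
    plate, rois, table = make_well_plate(
        curve, dilution_series(), seed=child_seeds[-2] % 2**31
    )
    save_image(plate, outdir / "well_plate.png")
    table.to_csv(outdir / "standard.csv", index=False)

    panel_spec = PanelSpec(
        true_ui=(100.0, 250.0, 400.0, 180.0, 320.0), seed=child_seeds[-1] % 2**31
    )
    cco, ia = make_rater_panel(panel_spec)
    _write_panel_csv(outdir / "panels.csv", cco, ia)
    return outdir


def _save_mask(mask: np.ndarray, path: Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, mask.astype(np.uint8) * 255)


def _write_panel_csv(path: Path, cco, ia) -> None:
    rows = []
    for method, panel in (("cco", cco), ("ia", ia)):
        for s in range(panel.n_subjects):
            for r in range(panel.n_raters):
                rows.append(
                    {
                        "subject_id": s,
                        "rater_id": r,
                        "method": method,
                        "score": panel.scores[s, r],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
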