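"""DAB immunostain quantification by optical-density colour deconvolution.

Brightfield immunohistochemistry obeys the Beer-Lambert law: the optical
density of each RGB channel is a linear mixture of per-stain densities,
``OD_c = sum_s concentration_s * basis[s, c]``, where each stain's unit OD
vector (Haematoxylin, Eosin, DAB) forms a row of the stain basis.  Unmixing
inverts this 3x3 system per pixel (Ruifrok-Johnston colour deconvolution).

Quantification mirrors the standard digitized-slide workflow: a tissue mask
is the union of thresholded Eosin and DAB maps (whitespace excluded), DAB
pixels above an OD threshold inside the tissue define the stained area, and
two statistics summarise each slide:

* ``percent_surface_area`` = 100 * DAB area / tissue area,
* ``density`` = mean DAB optical density over all tissue pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_triangle

__all__ = [
    "StainBasis",
    "IHCQuant",
    "HED_BASIS",
    "unmix",
    "mix",
    "tissue_mask",
    "quantify",
    "ratio_table",
    "default_od_threshold",
]

I0 = 255.0          # incident (white) transmitted-light level, 8-bit convention
OD_EPS = 1.0 / 255  # avoids log(0) on fully absorbed pixels


@dataclass(frozen=True)
class StainBasis:
    """Unit optical-density vectors for three stains (rows) x RGB (columns)."""

    vectors: np.ndarray
    names: tuple[str, str, str] = ("haematoxylin", "eosin", "dab")

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.shape != (3, 3):
            raise ValueError("stain basis must be 3 stains x 3 channels")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        v = v / norms[:, None]
        if abs(np.linalg.det(v)) < 1e-6:
            raise ValueError("stain vectors must be linearly independent")
        object.__setattr__(self, "vectors", v)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)


# Published Ruifrok-Johnston constants for Haematoxylin / Eosin / DAB.
# The study optimised its own vectors; these are the standard defaults and
# are overridable wherever a StainBasis is accepted.
HED_BASIS = StainBasis(
    vectors=np.array(
        [
            [0.650, 0.704, 0.286],
            [0.072, 0.990, 0.105],
            [0.268, 0.570, 0.776],
        ]
    )
)


@dataclass(frozen=True)
class IHCQuant:
    """Per-image DAB quantification summary."""

    dab_area: int
    tissue_area: int
    percent_surface_area: float
    density: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_surface_area <= 100.0:
            raise ValueError("percent_surface_area outside [0, 100]")


def _rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=np.float64)
    return -np.log10((rgb + OD_EPS) / I0)


def unmix(rgb: np.ndarray, basis: StainBasis = HED_BASIS) -> dict[str, np.ndarray]:
    """Separate an 8-bit RGB image into per-stain concentration (OD) maps.

    Negative concentrations (noise projected outside the stain simplex) are
    clipped to zero.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    od = _rgb_to_od(rgb)
    conc = od @ basis.inverse  # per pixel: OD vector through the basis inverse
    conc = np.clip(conc, 0.0, None)
    return {name: conc[..., i] for i, name in enumerate(basis.names)}


def mix(concentrations: dict[str, np.ndarray] | np.ndarray,
        basis: StainBasis = HED_BASIS) -> np.ndarray:
    """Synthesize the 8-bit RGB image transmitted by given stain densities.

    Per channel: ``transmitted = I0 * 10**(-sum_s c_s * basis[s, c])``,
    rounded to the 8-bit grid.  Zero concentration everywhere gives a white
    image.
    """
    if isinstance(concentrations, dict):
        maps = np.stack([np.asarray(concentrations[n], dtype=np.float64)
                         for n in basis.names], axis=-1)
    else:
        maps = np.asarray(concentrations, dtype=np.float64)
    if (maps < 0).any():
        raise ValueError("stain concentrations must be non-negative")
    od = maps @ basis.vectors
    rgb = I0 * np.power(10.0, -od)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def tissue_mask(eosin: np.ndarray, dab: np.ndarray,
                eosin_threshold: float, dab_threshold: float) -> np.ndarray:
    """Tissue = union of thresholded Eosin and DAB OD maps."""
    eosin = np.asarray(eosin)
    dab = np.asarray(dab)
    if eosin.shape != dab.shape:
        raise ValueError("eosin and DAB maps must share a shape")
    return (eosin > eosin_threshold) | (dab > dab_threshold)


def quantify(dab: np.ndarray, dab_threshold: float, tissue: np.ndarray) -> IHCQuant:
    """DAB area, percent tissue surface area and whole-tissue density."""
    dab = np.asarray(dab)
    tissue = np.asarray(tissue, dtype=bool)
    if dab.shape != tissue.shape:
        raise ValueError("DAB map and tissue mask must share a shape")
    tissue_area = int(tissue.sum())
    if tissue_area == 0:
        raise ValueError("tissue mask is empty; quantification undefined")
    dab_area = int(((dab > dab_threshold) & tissue).sum())
    return IHCQuant(
        dab_area=dab_area,
        tissue_area=tissue_area,
        percent_surface_area=100.0 * dab_area / tissue_area,
        density=float(dab[tissue].mean()),
    )


def default_od_threshold(od_map: np.ndarray) -> float:
    """Triangle-method threshold on an OD map's histogram.

    The study's fixed thresholds are unpublished; the triangle method is a
    standard unimodal-background choice and is overridable everywhere.
    """
    return float(threshold_triangle(np.asarray(od_map, dtype=np.float64)))


def ratio_table(quants: pd.DataFrame) -> pd.DataFrame:
    """Per-subject pairwise ratios of densities and percent surface areas.

    ``quants`` is long-format with columns ``subject, target, percent_surface_area,
    density`` where target is one of LOX / LOXL1 / LOXL2.  Returns one row per
    subject with columns like ``density_LOX_over_LOXL1``.  Ratios whose
    denominator is zero are set to NaN and flagged in the ``flags`` column.
    """
    required = {"subject", "target", "percent_surface_area", "density"}
    missing = required - set(quants.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    wide = quants.pivot(index="subject", columns="target",
                        values=["percent_surface_area", "density"])
    targets = sorted(quants["target"].unique())  # LOX before LOXL1 before LOXL2
    rows = []
    for subject, row in wide.iterrows():
        out: dict[str, object] = {"subject": subject}
        flags = []
        for metric, col in (("density", "density"),
                            ("percent_area", "percent_surface_area")):
            for i, a in enumerate(targets):
                for b in targets[i + 1:]:
                    num, den = row[(col, a)], row[(col, b)]
                    key = f"{metric}_{a}_over_{b}"
                    if den == 0 or pd.isna(den) or pd.isna(num):
                        out[key] = np.nan
                        flags.append(key)
                    else:
                        out[key] = num / den
        out["flags"] = ";".join(flags)
        rows.append(out)
    return pd.DataFrame(rows)
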