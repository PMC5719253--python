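"""Ground-truth-labelled synthetic inputs for every analysis stage.

The study's tissue images and force curves are not published, so each stage
is exercised on synthetic data whose generating parameters are known exactly:

* **SHG stacks** -- fibril segments rendered as hard cylinders with a linear
  one-voxel anti-aliased edge.  Each segment carries a maturity m in [0, 1]
  that splits its emitted signal between the forward channel (fraction m,
  mature/organized collagen) and the backward channel (fraction 1-m,
  immature/disorganized collagen); total emission is independent of m.
* **IHC tiles** -- Beer-Lambert transmitted light through Haematoxylin /
  Eosin / DAB concentration maps, 8-bit quantized, white background.
* **AFM force curves** -- Hertz sphere-contact response over a linear
  baseline drift, with additive Gaussian noise.
* **Cohort tables** -- multivariate subject data with a planted latent-factor
  loading structure and per-group mean shifts.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .afm import ForceCurve, hertz_force
from .ihc import HED_BASIS, StainBasis, mix
from .shg import SHGStack

__all__ = [
    "FibrilSegment",
    "SHGGroundTruth",
    "IHCGroundTruth",
    "CurveGroundTruth",
    "CohortGroundTruth",
    "gen_shg_stack",
    "gen_ihc_image",
    "gen_force_curve",
    "gen_cohort",
    "random_segments",
    "random_concentration_maps",
    "default_cohort_truth",
    "write_truth_yaml",
]


# ---------------------------------------------------------------------------
# SHG

@dataclass(frozen=True)
class FibrilSegment:
    """Cylinder from start to end voxel with radius (voxels) and maturity m."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float
    maturity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.maturity <= 1.0:
            raise ValueError("maturity must be in [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if np.allclose(self.start, self.end):
            raise ValueError("degenerate zero-length segment")


@dataclass(frozen=True)
class SHGGroundTruth:
    segments: tuple[FibrilSegment, ...]
    forward_gain: float = 2000.0   # a.u. per unit fibril occupancy
    backward_gain: float = 2000.0
    background_level: float = 50.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.forward_gain <= 0 or self.backward_gain <= 0:
            raise ValueError("gains must be positive")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background must be non-negative")


def _segment_occupancy(seg: FibrilSegment, shape: tuple[int, int, int]) -> np.ndarray:
    """Per-voxel occupancy in [0,1]: 1 inside the cylinder, linear falloff
    to 0 over one voxel beyond the radius (anti-aliased hard edge)."""
    a = np.asarray(seg.start, dtype=np.float64)
    b = np.asarray(seg.end, dtype=np.float64)
    ab = b - a
    ab2 = float(ab @ ab)
    yy, xx, zz = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij",
    )
    pts = np.stack([yy, xx, zz], axis=-1).astype(np.float64)
    ap = pts - a
    t = np.clip((ap @ ab) / ab2, 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist = np.linalg.norm(pts - closest, axis=-1)
    return np.clip(seg.radius + 1.0 - dist, 0.0, 1.0)


def gen_shg_stack(truth: SHGGroundTruth, shape: tuple[int, int, int]) -> SHGStack:
    """Render forward/backward channels from fibril segments.

    forward voxel = background + sum_seg occupancy * forward_gain * m + noise;
    backward analogous with (1 - m).  Channels are clipped to the 16-bit
    range; deterministic under the truth's seed.
    """
    if any(s <= 0 for s in shape):
        raise ValueError("stack shape must be positive in all dimensions")
    fwd = np.full(shape, float(truth.background_level))
    bwd = np.full(shape, float(truth.background_level))
    for seg in truth.segments:
        occ = _segment_occupancy(seg, shape)
        fwd += occ * truth.forward_gain * seg.maturity
        bwd += occ * truth.backward_gain * (1.0 - seg.maturity)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        fwd += rng.normal(0.0, truth.noise_sd, shape)
        bwd += rng.normal(0.0, truth.noise_sd, shape)
    fwd = np.clip(fwd, 0.0, 65535.0)
    bwd = np.clip(bwd, 0.0, 65535.0)
    return SHGStack(forward=fwd, backward=bwd, label=f"synthetic-seed{truth.seed}")


def random_segments(n: int, shape: tuple[int, int, int], maturity: float,
                    seed: int, radius_range: tuple[float, float] = (1.0, 2.5),
                    min_length: float = 4.0) -> tuple[FibrilSegment, ...]:
    """Draw n random fibril segments of fixed maturity inside a stack volume."""
    rng = np.random.default_rng(seed)
    segments = []
    extent = np.asarray(shape, dtype=np.float64)
    while len(segments) < n:
        a = rng.uniform(0, extent)
        b = rng.uniform(0, extent)
        if np.linalg.norm(b - a) < min_length:
            continue
        segments.append(FibrilSegment(
            start=tuple(a), end=tuple(b),
            radius=float(rng.uniform(*radius_range)),
            maturity=maturity,
        ))
    return tuple(segments)


# ---------------------------------------------------------------------------
# IHC

@dataclass(frozen=True)
class IHCGroundTruth:
    """Per-stain concentration maps (OD units) plus the mixing basis."""

    concentration_maps: dict
    stain_basis: StainBasis = HED_BASIS
    seed: int = 0

    def __post_init__(self) -> None:
        shapes = {np.asarray(m).shape for m in self.concentration_maps.values()}
        if len(shapes) != 1:
            raise ValueError("concentration maps must share one shape")
        for name, m in self.concentration_maps.items():
            if (np.asarray(m) < 0).any():
                raise ValueError(f"negative concentrations in {name!r}")


def gen_ihc_image(truth: IHCGroundTruth) -> np.ndarray:
    """8-bit RGB brightfield tile transmitted through the stain maps."""
    return mix(truth.concentration_maps, truth.stain_basis)


# Default per-stain concentration ceiling.  At 0.2 OD on all three stains the
# most absorbing channel stays above ~90/255 transmitted counts, so the
# round-trip OD error after 8-bit quantization is bounded well under 2/255
# even through the basis inverse (see docs/methods.md for the bound).
DEFAULT_MAX_CONCENTRATION = 0.2


def random_concentration_maps(shape: tuple[int, int], seed: int,
                              max_concentration: float = DEFAULT_MAX_CONCENTRATION,
                              smoothness: float = 4.0) -> dict:
    """Smooth random non-negative stain maps (Gaussian-filtered noise)."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    maps = {}
    for name in ("haematoxylin", "eosin", "dab"):
        raw = gaussian_filter(rng.standard_normal(shape), smoothness)
        raw -= raw.min()
        if raw.max() > 0:
            raw /= raw.max()
        maps[name] = raw * max_concentration
    return maps


# ---------------------------------------------------------------------------
# AFM

@dataclass(frozen=True)
class CurveGroundTruth:
    """Generating parameters of a Hertz indentation curve.

    Defaults mirror the acquisition: 2.5-um-radius spherical probe, Poisson
    ratio 0.4, 10-um ramp.
    """

    E_true: float                  # kPa
    R: float = 2.5                 # um
    nu: float = 0.4
    contact_point: float = 2.0     # um
    baseline_slope: float = 0.0    # nN/um
    noise_sd: float = 0.0          # nN, additive
    n_points: int = 500
    ramp: float = 10.0             # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_true < 0:
            raise ValueError("modulus must be non-negative")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")
        if self.R <= 0 or self.ramp <= 0:
            raise ValueError("radius and ramp must be positive")
        if self.n_points < 50:
            raise ValueError("need at least 50 samples")


def gen_force_curve(truth: CurveGroundTruth) -> ForceCurve:
    """Synthesize an approach curve: baseline drift + Hertz contact + noise."""
    z = np.linspace(0.0, truth.ramp, truth.n_points)
    force = truth.baseline_slope * z
    delta = np.clip(z - truth.contact_point, 0.0, None)
    force = force + hertz_force(delta, truth.E_true, truth.R, truth.nu)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        force = force + rng.normal(0.0, truth.noise_sd, truth.n_points)
    return ForceCurve(
        z=z, force=force, probe_radius=truth.R, poisson_nu=truth.nu,
        label=f"synthetic-E{truth.E_true}-seed{truth.seed}",
    )


# ---------------------------------------------------------------------------
# Cohort

@dataclass(frozen=True)
class CohortGroundTruth:
    """Planted factor structure: X_subject = shift[group] + L f + e."""

    loading_matrix: np.ndarray            # variables x factors
    uniqueness: np.ndarray                # per-variable residual variance
    group_shift: dict                     # group label -> offset vector
    n_per_group: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        L = np.asarray(self.loading_matrix, dtype=np.float64)
        u = np.asarray(self.uniqueness, dtype=np.float64)
        if np.any(u <= 0):
            raise ValueError("uniqueness variances must be positive")
        if np.linalg.matrix_rank(L) < L.shape[1]:
            raise ValueError("loading matrix must have full column rank")
        if len(u) != L.shape[0]:
            raise ValueError("uniqueness length must match loading rows")
        object.__setattr__(self, "loading_matrix", L)
        object.__setattr__(self, "uniqueness", u)


def default_cohort_truth(n_per_group: int = 100, seed: int = 0,
                         group_shift: dict | None = None) -> CohortGroundTruth:
    """Two-factor structure: 4 variables, loadings [[.8,0],[.7,0],[0,.8],[0,.7]],
    uniqueness 0.3 -- two distinct relationship groups, fully synthetic."""
    L = np.array([[0.8, 0.0], [0.7, 0.0], [0.0, 0.8], [0.0, 0.7]])
    if group_shift is None:
        group_shift = {"non-IPF": np.zeros(4), "IPF": np.zeros(4)}
    return CohortGroundTruth(
        loading_matrix=L,
        uniqueness=np.full(4, 0.3),
        group_shift=group_shift,
        n_per_group=n_per_group,
        seed=seed,
    )


def gen_cohort(truth: CohortGroundTruth, variables: list[str] | None = None) -> pd.DataFrame:
    """Simulate a subjects x variables cohort table with group labels."""
    L = truth.loading_matrix
    p, k = L.shape
    if variables is None:
        variables = [f"var_{i + 1}" for i in range(p)]
    if len(variables) != p:
        raise ValueError(f"need {p} variable names, got {len(variables)}")
    rng = np.random.default_rng(truth.seed)
    rows = []
    sid = 0
    for group, shift in truth.group_shift.items():
        shift = np.asarray(shift, dtype=np.float64)
        if shift.shape != (p,):
            raise ValueError(f"group {group!r} shift must have length {p}")
        for _ in range(truth.n_per_group):
            f = rng.standard_normal(k)
            e = rng.normal(0.0, np.sqrt(truth.uniqueness))
            x = shift + L @ f + e
            rows.append({"subject": f"S{sid:04d}", "group": group,
                         **dict(zip(variables, x))})
            sid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground-truth sidecars

def write_truth_yaml(truth, path: str | Path) -> None:
    """Serialize any ground-truth record as a YAML sidecar."""
    def _clean(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if hasattr(obj, "__dataclass_fields__"):
            return {f: _clean(getattr(obj, f)) for f in obj.__dataclass_fields__}
        return obj

    Path(path).write_text(yaml.safe_dump(_clean(truth), sort_keys=False))
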