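"""Young's modulus from AFM micro-indentation via the Hertz sphere model.

A sphere-tipped cantilever indenting an elastic half-space follows

    F(delta) = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

with indentation depth ``delta = z - z0`` past the contact point ``z0``,
probe radius ``R`` and Poisson ratio ``nu``.  Units are fixed throughout:
E in kPa, lengths in um, force in nN (1 kPa * um^2 = 1 nN, the single unit
bridge in this module).

Fitting estimates (baseline intercept, baseline slope, Hertz coefficient)
jointly by linear least squares for each candidate contact point, selects the
contact point minimising the mean squared residual over a coarse grid of
sample positions, then refines it by bounded scalar minimisation.  The fitted
window is restricted to delta <= max_indentation_fraction of the post-contact
range to limit substrate (bottom-effect) stiffening on thin sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "ForceCurve",
    "HertzFitResult",
    "HertzFitConfig",
    "SampleStiffness",
    "hertz_force",
    "fit_curve",
    "parse_curves",
    "write_curve",
    "aggregate",
    "kruskal_dunn",
]

# 1 kPa * um^2 = 1e3 Pa * 1e-12 m^2 = 1e-9 N = 1 nN
KPA_UM2_TO_NN = 1.0


@dataclass
class ForceCurve:
    """One approach force-indentation record.

    ``z`` in um (strictly increasing piezo extension), ``force`` in nN.
    ``spring_constant`` (pN/nm) is metadata used only when converting
    deflection records to force.
    """

    z: np.ndarray
    force: np.ndarray
    probe_radius: float = 2.5     # um
    poisson_nu: float = 0.4
    spring_constant: float | None = None  # pN/nm
    label: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        self.force = np.asarray(self.force, dtype=np.float64)
        if self.z.shape != self.force.shape or self.z.ndim != 1:
            raise ValueError("z and force must be matching 1-D arrays")
        if not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")
        if self.probe_radius <= 0:
            raise ValueError("probe radius must be positive")
        if not 0.0 <= self.poisson_nu < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")


@dataclass(frozen=True)
class HertzFitResult:
    E: float                     # kPa
    contact_point: float         # um
    baseline_slope: float        # nN/um
    baseline_intercept: float    # nN
    rss: float                   # nN^2
    n_fit_points: int
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class HertzFitConfig:
    """Fit options.

    max_indentation_fraction limits the fitted indentation depth to this
    fraction of the post-contact z range, mitigating bottom-effect stiffening
    on thin cryosections; min_post_contact is the smallest admissible number
    of post-contact samples for a candidate contact point.
    """

    max_indentation_fraction: float = 0.5
    min_post_contact: int = 20
    min_pre_contact: int = 2
    coarse_step: int = 1
    nu_override: float | None = None


def hertz_force(delta: np.ndarray | float, E: float, R: float, nu: float) -> np.ndarray | float:
    """Hertz sphere-contact force (nN) at indentation depth delta (um)."""
    delta = np.asarray(delta, dtype=np.float64)
    if np.any(delta < 0):
        raise ValueError("indentation depth must be non-negative")
    out = (4.0 / 3.0) * (E / (1.0 - nu**2)) * np.sqrt(R) * delta**1.5 * KPA_UM2_TO_NN
    return float(out) if out.ndim == 0 else out


def _design(z: np.ndarray, z0: float) -> np.ndarray:
    delta = np.clip(z - z0, 0.0, None)
    return np.column_stack([np.ones_like(z), z, delta**1.5])


def _fit_window(z: np.ndarray, z0: float, frac: float) -> np.ndarray:
    """Boolean mask: all pre-contact points plus post-contact up to frac of range."""
    z_max = z[-1]
    cutoff = z0 + frac * (z_max - z0)
    return z <= cutoff


def _objective(z: np.ndarray, f: np.ndarray, z0: float, frac: float) -> tuple[float, np.ndarray, int]:
    mask = _fit_window(z, z0, frac)
    zz, ff = z[mask], f[mask]
    X = _design(zz, z0)
    coef, _, _, _ = np.linalg.lstsq(X, ff, rcond=None)
    if coef[2] < 0:  # modulus is physically non-negative: refit without Hertz term
        coef01, _, _, _ = np.linalg.lstsq(X[:, :2], ff, rcond=None)
        coef = np.array([coef01[0], coef01[1], 0.0])
    resid = ff - X @ coef
    rss = float(resid @ resid)
    n = len(zz)
    return rss / max(n - 3, 1), coef, n


def fit_curve(curve: ForceCurve, config: HertzFitConfig | None = None) -> HertzFitResult:
    """Joint least-squares estimate of (E, contact point, baseline).

    The contact point is profiled out: for each candidate z0 the remaining
    parameters are linear and solved exactly; the candidate minimising the
    mean squared residual wins and is refined continuously between its grid
    neighbours.  Never returns a negative modulus; irrecoverable fits return
    ``converged=False`` with a diagnostic message rather than a silent zero.
    """
    cfg = config or HertzFitConfig()
    z, f = curve.z, curve.force
    n = len(z)
    lo = cfg.min_pre_contact
    hi = n - cfg.min_post_contact
    if hi <= lo:
        return HertzFitResult(
            E=float("nan"), contact_point=float("nan"), baseline_slope=float("nan"),
            baseline_intercept=float("nan"), rss=float("nan"), n_fit_points=0,
            converged=False,
            message=f"curve too short: need >= {cfg.min_pre_contact + cfg.min_post_contact} samples",
        )
    frac = cfg.max_indentation_fraction
    candidates = range(lo, hi, cfg.coarse_step)
    best_idx, best_obj = None, np.inf
    for i in candidates:
        obj, _, _ = _objective(z, f, z[i], frac)
        if obj < best_obj:
            best_obj, best_idx = obj, i

    if best_idx is None:
        return HertzFitResult(
            E=float("nan"), contact_point=float("nan"), baseline_slope=float("nan"),
            baseline_intercept=float("nan"), rss=float("nan"), n_fit_points=0,
            converged=False, message="no admissible contact point",
        )

    z_lo = z[max(best_idx - cfg.coarse_step, 0)]
    z_hi = z[min(best_idx + cfg.coarse_step, n - 1)]
    res = minimize_scalar(
        lambda z0: _objective(z, f, z0, frac)[0],
        bounds=(z_lo, z_hi), method="bounded",
        options={"xatol": 1e-9 * max(z[-1] - z[0], 1.0)},
    )
    z0 = float(res.x) if res.success else float(z[best_idx])
    obj, coef, n_fit = _objective(z, f, z0, frac)

    nu = cfg.nu_override if cfg.nu_override is not None else curve.poisson_nu
    hertz_coef = coef[2]
    E = 3.0 * hertz_coef * (1.0 - nu**2) / (4.0 * np.sqrt(curve.probe_radius)) / KPA_UM2_TO_NN
    return HertzFitResult(
        E=float(max(E, 0.0)),
        contact_point=z0,
        baseline_slope=float(coef[1]),
        baseline_intercept=float(coef[0]),
        rss=float(obj * max(n_fit - 3, 1)),
        n_fit_points=int(n_fit),
        converged=True,
    )


# ---------------------------------------------------------------------------
# I/O

def write_curve(curve: ForceCurve, path: str | Path) -> None:
    """CSV with columns z_um, force_nN plus a YAML sidecar for metadata."""
    path = Path(path)
    pd.DataFrame({"z_um": curve.z, "force_nN": curve.force}).to_csv(
        path, index=False, float_format="%.17g")  # round-trip exact for float64
    meta = {
        "probe_radius_um": float(curve.probe_radius),
        "poisson_nu": float(curve.poisson_nu),
        "spring_constant_pN_nm": None if curve.spring_constant is None else float(curve.spring_constant),
        "label": curve.label,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def parse_curves(path: str | Path, probe_radius: float = 2.5,
                 poisson_nu: float = 0.4,
                 spring_constant: float | None = None) -> list[ForceCurve]:
    """Parse force curves from CSV/TSV.

    Accepted layouts: columns ``z_um, force_nN`` (one curve), the same plus a
    ``curve_id`` column (long format, one curve per id), or ``z_um,
    deflection_nm`` with a spring constant k (pN/nm) from the argument or a
    YAML sidecar, in which case force_nN = k * deflection_nm * 1e-3.
    Malformed curves are skipped with a warning stating the reason.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        probe_radius = meta.get("probe_radius_um", probe_radius)
        poisson_nu = meta.get("poisson_nu", poisson_nu)
        spring_constant = meta.get("spring_constant_pN_nm", spring_constant)

    if "z_um" not in df.columns:
        raise ValueError(f"{path.name}: missing required column z_um")
    if "force_nN" not in df.columns:
        if "deflection_nm" in df.columns:
            if spring_constant is None:
                raise ValueError(f"{path.name}: deflection data needs a spring constant (pN/nm)")
            # pN/nm * nm = pN; 1e-3 nN per pN
            df = df.assign(force_nN=df["deflection_nm"] * spring_constant * 1e-3)
        else:
            raise ValueError(f"{path.name}: need force_nN or deflection_nm column")

    groups = df.groupby("curve_id") if "curve_id" in df.columns else [(path.stem, df)]
    curves = []
    for label, sub in groups:
        try:
            curves.append(ForceCurve(
                z=sub["z_um"].to_numpy(), force=sub["force_nN"].to_numpy(),
                probe_radius=probe_radius, poisson_nu=poisson_nu,
                spring_constant=spring_constant, label=str(label),
            ))
        except ValueError as exc:
            warnings.warn(f"curve {label!r} rejected: {exc}", stacklevel=2)
    return curves


# ---------------------------------------------------------------------------
# Aggregation and group comparison

@dataclass(frozen=True)
class SampleStiffness:
    """Per-group stiffness summaries; failed fits are counted, never dropped silently."""

    summary: pd.DataFrame  # group, n, n_failed, median, q1, q3


def aggregate(results: pd.DataFrame, by: str | list[str] = "group") -> SampleStiffness:
    """Median/IQR of fitted moduli per group.

    ``results`` needs columns ``E`` and ``converged`` plus the grouping keys.
    """
    for col in ("E", "converged"):
        if col not in results.columns:
            raise ValueError(f"missing column {col!r}")
    rows = []
    for keys, sub in results.groupby(by):
        ok = sub[sub["converged"].astype(bool)]
        if len(sub) == 0:
            raise ValueError(f"empty group {keys!r}")
        rec = {"group": keys} if isinstance(by, str) else dict(zip(by, keys))
        rec.update(
            n=len(sub),
            n_failed=int(len(sub) - len(ok)),
            median=float(ok["E"].median()) if len(ok) else float("nan"),
            q1=float(ok["E"].quantile(0.25)) if len(ok) else float("nan"),
            q3=float(ok["E"].quantile(0.75)) if len(ok) else float("nan"),
        )
        rows.append(rec)
    return SampleStiffness(summary=pd.DataFrame(rows))


def kruskal_dunn(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis omnibus test with Dunn's pairwise post-hoc comparison.

    Dunn's z statistics use the pooled rank variance with tie correction;
    pairwise p values are Bonferroni-adjusted over all comparisons (the
    classical family-wise scheme).  Degenerate input where every value is
    identical returns p = 1 rather than failing.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for k, v in data.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has fewer than 3 values")
    pooled = np.concatenate([data[k] for k in names])
    if np.ptp(pooled) == 0:  # all values identical: no evidence of any difference
        pairs = [
            {"group_a": a, "group_b": b, "z": 0.0, "p_raw": 1.0, "p_adjusted": 1.0}
            for i, a in enumerate(names) for b in names[i + 1:]
        ]
        return {"H": 0.0, "p": 1.0, "pairwise": pd.DataFrame(pairs)}

    H, p = stats.kruskal(*[data[k] for k in names])

    ranks = stats.rankdata(pooled)
    N = len(pooled)
    offsets = np.cumsum([0] + [len(data[k]) for k in names])
    mean_ranks = {
        k: ranks[offsets[i]:offsets[i + 1]].mean() for i, k in enumerate(names)
    }
    # tie correction: sum over tie groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))

    pairs = []
    n_comparisons = len(names) * (len(names) - 1) // 2
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(var_term * (1.0 / len(data[a]) + 1.0 / len(data[b])))
            zval = (mean_ranks[a] - mean_ranks[b]) / se
            p_raw = 2.0 * stats.norm.sf(abs(zval))
            pairs.append({
                "group_a": a, "group_b": b, "z": float(zval),
                "p_raw": float(p_raw),
                "p_adjusted": float(min(p_raw * n_comparisons, 1.0)),
            })
    return {"H": float(H), "p": float(p), "pairwise": pd.DataFrame(pairs)}
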