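"""Scaling-law and descriptor-correlation fits.

The tertiary-structure analysis fits the power law R_g ∝ MW^v on log-log
axes; the robust variant minimises the mean absolute residual
("least-average-residual", LAR) via iteratively reweighted least squares,
with a percentile-bootstrap 95% CI on the exponent.  Linear descriptor
correlations (OLS slope/intercept/R²), binodal interpolation (minimum PEG
concentration for phase formation at a given phosphate level), the
relative molar-fraction correction and the ET(30) polarity analysis
(quadratic wavelength calibration, linear-region slope) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


# ----------------------------------------------------------------------
# result objects

@dataclass
class ScalingFit:
    """Result of the log-log power-law fit R_g = prefactor * MW^v."""

    exponent_v: float
    prefactor: float
    ci95: tuple[float, float]
    method: str
    n_points: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo <= self.exponent_v <= hi:
            raise ValueError("exponent must lie inside its CI")

    def predict(self, mw: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(mw, dtype=float) ** self.exponent_v

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"Power-law fit Rg = c * MW^v   [{self.method.upper()}, "
            f"{self.n_points} points]\n"
            f"  exponent v : {self.exponent_v:.4f}  (95% CI {lo:.4f} .. {hi:.4f})\n"
            f"  prefactor c: {self.prefactor:.4f} Å\n"
        )


@dataclass
class CorrelationFit:
    """OLS line fit with the squared Pearson correlation."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def summary(self) -> str:
        return (
            f"Linear fit y = {self.slope:.4g} x + {self.intercept:.4g}   "
            f"(R² = {self.r_squared:.4f})\n"
        )


# ----------------------------------------------------------------------
# power-law fitting

def _lar_line(x: np.ndarray, y: np.ndarray, n_iter: int = 50, damping: float = 1e-8):
    """L1 (least-average-residual) straight line via IRLS."""
    # start from OLS
    A = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    for _ in range(n_iter):
        r = y - A @ beta
        w = 1.0 / np.maximum(np.abs(r), damping)
        Aw = A * w[:, None]
        beta_new, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)
        if np.allclose(beta_new, beta, rtol=0, atol=1e-14):
            beta = beta_new
            break
        beta = beta_new
    return beta  # (slope, intercept)


def _ols_line(x: np.ndarray, y: np.ndarray):
    A = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def fit_scaling(
    points,
    method: str = "lar",
    n_boot: int = 1000,
    seed: int = 0,
) -> ScalingFit:
    """Fit R_g = c * MW^v on log-log axes.

    Parameters
    ----------
    points
        Sequence of (mw, rg) pairs, all strictly positive; at least 3.
    method
        "lar" (robust L1 via IRLS) or "ols".
    n_boot, seed
        Percentile bootstrap over the points for the 95% CI on v.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 (mw, rg) pairs")
    if np.any(pts <= 0):
        raise ValueError("mw and rg must be strictly positive for a log-log fit")
    if method not in ("lar", "ols"):
        raise ValueError(f"unknown method {method!r}")
    fitter = _lar_line if method == "lar" else _ols_line

    lx = np.log(pts[:, 0])
    ly = np.log(pts[:, 1])
    slope, intercept = fitter(lx, ly)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    i = 0
    while i < n_boot:
        idx = rng.integers(0, len(pts), size=len(pts))
        if np.ptp(lx[idx]) < 1e-12:
            continue  # degenerate resample: one distinct abscissa
        boot[i] = fitter(lx[idx], ly[idx])[0]
        i += 1
    lo, hi = np.percentile(boot, [2.5, 97.5])
    # the percentile CI need not contain the point estimate on tiny or
    # degenerate samples; widen minimally so the invariant holds
    lo = min(lo, slope)
    hi = max(hi, slope)
    return ScalingFit(
        exponent_v=float(slope),
        prefactor=float(np.exp(intercept)),
        ci95=(float(lo), float(hi)),
        method=method,
        n_points=len(pts),
    )


def linear_fit(x, y) -> CorrelationFit:
    """Ordinary least squares with R² = squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    return CorrelationFit(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


# ----------------------------------------------------------------------
# binodal and polarity datasets

@dataclass
class BinodalDataset:
    """Phase-transition (cloud) points per PEG MW: (PO4 %w/w, PEG %w/w)."""

    curves: dict[float, np.ndarray]  # peg_mw -> (k, 2) array [po4_pct, peg_pct]

    def __post_init__(self) -> None:
        for mw, pts in self.curves.items():
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
                raise ValueError(f"binodal for MW {mw} needs >= 2 (po4, peg) points")
            if np.any((pts < 0) | (pts > 100)):
                raise ValueError(f"binodal for MW {mw}: concentrations must be %w/w in [0, 100]")
            self.curves[mw] = pts[np.argsort(pts[:, 0])]

    @classmethod
    def from_csv(cls, path: str | Path) -> "BinodalDataset":
        """Read a CSV with columns peg_mw, po4_pct, peg_pct."""
        df = _read_csv(path, ["peg_mw", "po4_pct", "peg_pct"])
        curves = {
            float(mw): g[["po4_pct", "peg_pct"]].to_numpy()
            for mw, g in df.groupby("peg_mw")
        }
        return cls(curves)


@dataclass
class PolarityDataset:
    """ET(30) polarity readings per PEG MW: (molar fraction, kcal/mol)."""

    series: dict[float, np.ndarray]  # peg_mw -> (k, 2) array [molar_fraction, et30]
    mw_ref: float = 200.0

    def __post_init__(self) -> None:
        if self.mw_ref <= 0:
            raise ValueError("mw_ref must be positive")
        for mw, pts in self.series.items():
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError(f"polarity series for MW {mw} must be (k, 2)")
            if np.any((pts[:, 0] < 0) | (pts[:, 0] > 1)):
                raise ValueError(f"polarity series for MW {mw}: molar fractions must be in [0, 1]")
            self.series[mw] = pts[np.argsort(pts[:, 0])]

    @classmethod
    def from_csv(cls, path: str | Path, mw_ref: float = 200.0) -> "PolarityDataset":
        """Read a CSV with columns peg_mw, molar_fraction, et30."""
        df = _read_csv(path, ["peg_mw", "molar_fraction", "et30"])
        series = {
            float(mw): g[["molar_fraction", "et30"]].to_numpy()
            for mw, g in df.groupby("peg_mw")
        }
        return cls(series, mw_ref=mw_ref)


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"data table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def min_peg_for_phase(binodal: BinodalDataset, peg_mw: float, po4_level: float) -> float:
    """Minimum PEG %w/w for two-phase formation at a given PO4 %w/w.

    Piecewise-linear interpolation of the binodal curve; querying outside
    the measured PO4 range raises rather than extrapolating.
    """
    try:
        pts = binodal.curves[peg_mw]
    except KeyError:
        raise KeyError(f"no binodal curve for PEG MW {peg_mw}") from None
    po4 = pts[:, 0]
    if not po4[0] <= po4_level <= po4[-1]:
        raise ValueError(
            f"PO4 level {po4_level} outside the measured range "
            f"[{po4[0]}, {po4[-1]}] — refusing to extrapolate"
        )
    return float(np.interp(po4_level, po4, pts[:, 1]))


def relative_molar_fraction(dataset: PolarityDataset) -> dict[float, np.ndarray]:
    """Scale each PEG's molar fractions to the reference MW (default 200).

    Fractions of a PEG of molecular weight MW are multiplied by
    round(MW / mw_ref), so one molecule of a k-fold heavier PEG counts as
    k reference molecules.
    """
    out = {}
    for mw, pts in dataset.series.items():
        factor = round(mw / dataset.mw_ref)
        scaled = pts.copy()
        scaled[:, 0] = scaled[:, 0] * factor
        out[mw] = scaled
    return out


def et30_slope(
    points,
    min_points: int = 4,
    min_r_squared: float = 0.98,
) -> CorrelationFit:
    """Slope of the linear low-fraction region of an ET(30) series.

    Points are sorted by molar fraction; the longest prefix of at least
    ``min_points`` points whose OLS fit reaches ``min_r_squared`` is
    selected and its fit returned.  ET(30) decreasing with fraction gives
    a negative slope.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < min_points:
        raise ValueError(f"need at least {min_points} (fraction, et30) points")
    pts = pts[np.argsort(pts[:, 0])]
    best: CorrelationFit | None = None
    for k in range(min_points, len(pts) + 1):
        fit = linear_fit(pts[:k, 0], pts[:k, 1])
        if fit.r_squared >= min_r_squared:
            best = fit
    if best is None:
        raise ValueError(
            f"no prefix of >= {min_points} points reaches R² >= {min_r_squared}; "
            "the series has no linear region under the configured rule"
        )
    return best


@dataclass
class ET30Calibration:
    """Quadratic map from absorbance-maximum wavelength (nm) to ET(30)."""

    coefficients: np.ndarray  # highest degree first, np.polyval order

    def __call__(self, wavelength_nm) -> np.ndarray | float:
        out = np.polyval(self.coefficients, wavelength_nm)
        return float(out) if np.isscalar(wavelength_nm) else out


def et30_calibration(points) -> ET30Calibration:
    """Least-squares 2nd-degree polynomial through (wavelength, ET30) pairs."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("calibration needs at least 3 (wavelength, et30) points")
    if len(np.unique(pts[:, 0])) < 3:
        raise ValueError("calibration needs at least 3 distinct wavelengths")
    coeffs = np.polyfit(pts[:, 0], pts[:, 1], deg=2)
    return ET30Calibration(coefficients=coeffs)
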