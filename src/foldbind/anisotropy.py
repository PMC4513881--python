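"""Fluorescence anisotropy binding isotherms.

A fluorescein-labeled nucleic acid (default 50 nM) is titrated with
protein; the anisotropy r rises as complex forms.  The isotherm is the
single-site hyperbola

    r = r0 + a·[P] / (b + [P])

with ``r0`` the anisotropy of the free nucleic acid, ``a`` the amplitude
of the change on binding and ``b`` the apparent dissociation constant.
By default ``[P]`` is the added (total) protein concentration — valid
when b is at least comparable to the label concentration — and an exact
mode that solves the 1:1 depletion quadratic is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .equilibria import _bound_two_state

__all__ = [
    "AnisotropyTitration",
    "BindingFit",
    "SingleSiteBindingModel",
    "fit_single_site",
    "normalize",
    "compare_affinities",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a binding fit cannot produce a meaningful estimate."""


@dataclass
class AnisotropyTitration:
    """One titration: added-protein concentrations vs anisotropy.

    Parameters
    ----------
    ligand_conc : array-like
        Added protein concentrations, nM, strictly increasing, first point
        at or near zero.
    r : array-like
        Anisotropy readings (dimensionless).
    r_err : array-like, optional
        Standard errors of r (replicate-based).
    label_conc : float
        Labeled nucleic acid concentration, nM (default 50).
    label : str
        Free-text identifier (construct / ligand).
    """

    ligand_conc: np.ndarray
    r: np.ndarray
    r_err: np.ndarray | None = None
    label_conc: float = 50.0
    label: str = ""

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.r_err is not None:
            self.r_err = np.asarray(self.r_err, dtype=float)
            if self.r_err.shape != self.r.shape:
                raise ValueError("r_err length does not match r")
        if self.ligand_conc.shape != self.r.shape:
            raise ValueError("ligand_conc and r lengths differ")
        if np.any(self.ligand_conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.ligand_conc) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("anisotropy values must be finite")

    def __len__(self) -> int:
        return len(self.r)


def _hyperbola(p: np.ndarray, r0: float, a: float, b: float) -> np.ndarray:
    return r0 + a * p / (b + p)


def _depletion_curve(
    p: np.ndarray, r0: float, a: float, b: float, label_conc: float
) -> np.ndarray:
    # Exact 1:1 model: the signal tracks the bound fraction of the label,
    # with [P] depleted by complex formation.
    bound = np.array([_bound_two_state(pi, label_conc, b) for pi in p])
    return r0 + a * bound / label_conc


@dataclass
class BindingFit:
    """Result of a single-site anisotropy fit.

    Attributes
    ----------
    r0, a, b : float
        Baseline anisotropy, amplitude and apparent Kd (nM).
    r0_err, a_err, b_err : float
        Asymptotic standard errors (nan when the covariance is
        unavailable).
    residuals : ndarray
        Data minus model at the measured points.
    """

    r0: float
    a: float
    b: float
    r0_err: float
    a_err: float
    b_err: float
    residuals: np.ndarray
    titration: AnisotropyTitration = field(repr=False)
    mode: str = "total"
    weighted: bool = False
    lmfit_result: lmfit.minimizer.MinimizerResult | None = field(
        default=None, repr=False, compare=False
    )

    def predict(self, conc: np.ndarray) -> np.ndarray:
        """Model anisotropy at the given added-protein concentrations (nM)."""
        conc = np.asarray(conc, dtype=float)
        if self.mode == "free":
            return _depletion_curve(conc, self.r0, self.a, self.b, self.titration.label_conc)
        return _hyperbola(conc, self.r0, self.a, self.b)

    def plot(self, ax=None, normalized: bool = False):
        """Draw the isotherm and fitted curve; see plotting.plot_isotherm."""
        from .plotting import plot_isotherm

        return plot_isotherm(self, ax=ax, normalized=normalized)

    def summary(self) -> str:
        lines = [
            "Single-site anisotropy fit"
            + (f" [{self.titration.label}]" if self.titration.label else ""),
            f"  mode: {self.mode} protein, "
            + ("weighted" if self.weighted else "unweighted") + " least squares",
            f"  r0 = {self.r0:.5f} ± {self.r0_err:.5f}",
            f"  a  = {self.a:.5f} ± {self.a_err:.5f}",
            f"  b  = {self.b:.1f} ± {self.b_err:.1f} nM (apparent Kd)",
            f"  n = {len(self.residuals)}, RMS residual = "
            f"{float(np.sqrt(np.mean(self.residuals ** 2))):.2e}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "r0": self.r0,
            "a": self.a,
            "b_nM": self.b,
            "r0_err": self.r0_err,
            "a_err": self.a_err,
            "b_err_nM": self.b_err,
            "mode": self.mode,
            "weighted": self.weighted,
            "n_points": int(len(self.residuals)),
            "rms_residual": float(np.sqrt(np.mean(self.residuals**2))),
        }


class SingleSiteBindingModel:
    """Single-site hyperbolic model for an anisotropy titration.

    Parameters
    ----------
    titration : AnisotropyTitration
    mode : {"total", "free"}
        "total" fits the hyperbola against added protein; "free" solves the
        1:1 depletion quadratic so that b is the true Kd even when the label
        concentration is not negligible.
    weighted : bool
        Weight residuals by 1/r_err (requires r_err).
    """

    def __init__(
        self,
        titration: AnisotropyTitration,
        mode: str = "total",
        weighted: bool = False,
    ) -> None:
        if mode not in ("total", "free"):
            raise ValueError(f"mode must be 'total' or 'free', got {mode!r}")
        if weighted and titration.r_err is None:
            raise ValueError("weighted fit requested but titration has no r_err")
        if len(titration) < 4:
            raise FitError("need at least 4 titration points for a 3-parameter fit")
        self.titration = titration
        self.mode = mode
        self.weighted = weighted

    def _check_design(self) -> None:
        t = self.titration
        if t.ligand_conc[0] > 0.05 * t.ligand_conc[-1]:
            warnings.warn(
                "no near-zero protein point: baseline r0 is poorly determined",
                stacklevel=3,
            )

    def fit(self) -> BindingFit:
        """Least-squares fit of (r0, a, b); raises FitError on degeneracy."""
        t = self.titration
        self._check_design()
        span = float(np.ptp(t.r))
        if span < 1e-12:
            raise FitError("degenerate titration: anisotropy is flat, no binding signal")

        params = lmfit.Parameters()
        params.add("r0", value=float(t.r[0]))
        params.add("a", value=float(t.r[-1] - t.r[0]))
        b0 = float(np.median(t.ligand_conc[t.ligand_conc > 0]))
        params.add("b", value=b0, min=1e-6)

        weights = None
        if self.weighted:
            err = np.where(t.r_err > 0, t.r_err, np.nan)
            err = np.where(np.isfinite(err), err, np.nanmax(err))
            weights = 1.0 / err

        def resid(p):
            if self.mode == "free":
                model = _depletion_curve(
                    t.ligand_conc, p["r0"].value, p["a"].value, p["b"].value, t.label_conc
                )
            else:
                model = _hyperbola(t.ligand_conc, p["r0"].value, p["a"].value, p["b"].value)
            res = model - t.r
            return res * weights if weights is not None else res

        result = lmfit.minimize(resid, params, method="leastsq")
        if not result.success:
            raise FitError(f"single-site fit did not converge: {result.message}")

        p = result.params
        half_sat = p["b"].value
        if half_sat > 2.0 * t.ligand_conc[-1]:
            warnings.warn(
                "fitted Kd lies beyond the titrated range; estimate is an "
                "extrapolation",
                stacklevel=2,
            )

        def err_of(name: str) -> float:
            se = p[name].stderr
            return float(se) if se is not None else float("nan")

        residuals = t.r - (
            _depletion_curve(t.ligand_conc, p["r0"].value, p["a"].value, p["b"].value, t.label_conc)
            if self.mode == "free"
            else _hyperbola(t.ligand_conc, p["r0"].value, p["a"].value, p["b"].value)
        )
        return BindingFit(
            r0=float(p["r0"].value),
            a=float(p["a"].value),
            b=float(p["b"].value),
            r0_err=err_of("r0"),
            a_err=err_of("a"),
            b_err=err_of("b"),
            residuals=residuals,
            titration=t,
            mode=self.mode,
            weighted=self.weighted,
            lmfit_result=result,
        )


def fit_single_site(
    t: AnisotropyTitration, mode: str = "total", weighted: bool = False
) -> BindingFit:
    """Fit the single-site hyperbola r = r0 + a·[P]/(b+[P]) to a titration."""
    return SingleSiteBindingModel(t, mode=mode, weighted=weighted).fit()


def normalize(t: AnisotropyTitration, f: BindingFit) -> np.ndarray:
    """Normalized isotherm (r − r0)/a; 0 at baseline, 0.5 at [P] = b, → 1."""
    if f.a == 0:
        raise ValueError("cannot normalize with zero amplitude")
    return (t.r - f.r0) / f.a


def compare_affinities(fits: dict[str, BindingFit]):
    """Pairwise apparent-Kd ratios with propagated relative errors.

    Returns a DataFrame with one row per ordered pair (i, j), the ratio
    b_i/b_j and its standard error from first-order propagation of the
    relative errors of both fits.
    """
    import pandas as pd

    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = []
    names = list(fits)
    for i in names:
        for j in names:
            if i == j:
                continue
            fi, fj = fits[i], fits[j]
            ratio = fi.b / fj.b
            rel = np.sqrt(
                (fi.b_err / fi.b) ** 2 + (fj.b_err / fj.b) ** 2
            )
            rows.append(
                {
                    "numerator": i,
                    "denominator": j,
                    "kd_ratio": ratio,
                    "ratio_err": ratio * rel,
                }
            )
    return pd.DataFrame(rows)
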