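"""NMR titration observables for a coupled folding-and-binding system.

Two exchange regimes coexist in the titration of an unfolded RNA-binding
domain with its substrate:

* the free unfolded protein (F_U) and the bound unfolded encounter
  complex (B_U) interconvert fast on the chemical-shift timescale, so
  the "unfolded" amide peaks move as a population-weighted average of
  the two environments;
* the bound folded form (B_F) is in slow exchange with the unfolded
  pool, so a second, dispersed set of peaks appears whose volumes report
  the B_F population directly.

This module computes chemical shift perturbations (CSPs), predicts the
fast-exchange shift trajectory of the unfolded pool under the
three-state model, fits the average-CSP series to recover the
microscopic encounter Kd, estimates the folding constant K2 from
slow-exchange peak volumes, and provides secondary-chemical-shift and
heteronuclear-NOE summaries of the free-state ensemble.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import lmfit
import numpy as np
import pandas as pd

from .equilibria import SpeciesState, ThreeStateModel, microscopic_kd, solve_species

__all__ = [
    "ShiftTable",
    "TitrationPoint",
    "ShiftTrajectory",
    "RandomCoilTable",
    "csp",
    "predict_unfolded_shift",
    "average_csp_series",
    "ShiftTitrationModel",
    "ShiftTitrationFit",
    "fit_microscopic_kd",
    "estimate_k2_from_volumes",
    "predict_intensity_evolution",
    "secondary_shifts",
    "hetnoe_region_summary",
]

logger = logging.getLogger(__name__)

# Physically plausible backbone shift windows (ppm); values outside are
# flagged, not rejected — unusual shifts exist.
_PLAUSIBLE = {"dh": (5.0, 12.0), "dn": (100.0, 135.0), "ca": (40.0, 70.0), "co": (165.0, 185.0)}


@dataclass
class ShiftTable:
    """Per-residue backbone shifts (and optional volumes / hetNOE).

    ``data`` columns: ``residue`` (int), ``aa`` (one-letter), ``dh``,
    ``dn`` (amide 1H/15N, ppm); optional ``ca``, ``co`` (ppm),
    ``volume`` (a.u.), ``hetnoe``.
    """

    data: pd.DataFrame
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        required = {"residue", "aa", "dh", "dn"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"shift table missing columns: {sorted(missing)}")
        if df["residue"].duplicated().any():
            dupes = df.loc[df["residue"].duplicated(), "residue"].tolist()
            raise ValueError(f"duplicate residue numbers: {dupes}")
        self.data = df.sort_values("residue").reset_index(drop=True)
        for col, (lo, hi) in _PLAUSIBLE.items():
            if col in df.columns:
                vals = df[col].dropna()
                bad = vals[(vals < lo) | (vals > hi)]
                if len(bad):
                    msg = f"{len(bad)} {col} shifts outside [{lo}, {hi}] ppm"
                    self.flags.append(msg)
                    logger.warning(msg)

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TitrationPoint:
    """One NMR titration point.

    ``equivalents`` is added RNA relative to the initial protein amount;
    totals are dilution-corrected concentrations in µM.  ``folded_volume``
    is the mean peak volume of the slow-exchange folded-form signals.
    """

    equivalents: float
    p_total: float
    r_total: float
    shifts: ShiftTable
    folded_volume: float | None = None


@dataclass
class ShiftTrajectory:
    """Ordered titration points sharing (mostly) the same residue set."""

    points: list[TitrationPoint]

    def __post_init__(self) -> None:
        eqs = [pt.equivalents for pt in self.points]
        if any(b <= a for a, b in zip(eqs, eqs[1:])):
            raise ValueError(f"equivalents must be strictly increasing, got {eqs}")
        sets = [set(pt.shifts.residues) for pt in self.points]
        common = set.intersection(*sets) if sets else set()
        union = set.union(*sets) if sets else set()
        if union - common:
            logger.warning(
                "%d residues missing at some titration points", len(union - common)
            )
        self._common_residues = np.array(sorted(common))

    @property
    def equivalents(self) -> np.ndarray:
        return np.array([pt.equivalents for pt in self.points])

    @property
    def totals(self) -> np.ndarray:
        """(n_points, 2) array of dilution-corrected (p_total, r_total), µM."""
        return np.array([[pt.p_total, pt.r_total] for pt in self.points])

    def __len__(self) -> int:
        return len(self.points)


class RandomCoilTable:
    """Random-coil CA/C' reference shifts per amino-acid type.

    The bundled default is the GGXGG peptide set of Wishart et al. (1995).
    Any 20-row table with columns ``aa``, ``ca``, ``co`` can be supplied
    instead.
    """

    AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

    def __init__(self, table: pd.DataFrame) -> None:
        missing = self.AMINO_ACIDS - set(table["aa"])
        if missing:
            raise ValueError(f"random-coil table lacks residue types: {sorted(missing)}")
        self.table = table.set_index("aa")

    @classmethod
    def bundled(cls) -> "RandomCoilTable":
        ref = resources.files("foldbind.data") / "random_coil_wishart1995.csv"
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, comment="#")
        return cls(df)

    def ca(self, aa: str) -> float:
        return float(self.table.loc[aa, "ca"])

    def co(self, aa: str) -> float:
        return float(self.table.loc[aa, "co"])


def csp(dh, dn):
    """Combined amide chemical shift perturbation sqrt((ΔδN/6)² + ΔδH²).

    The 15N term is scaled by 1/6 to put both nuclei on a comparable ppm
    scale.  Symmetric in the sign of either input; accepts arrays.
    """
    dh = np.asarray(dh, dtype=float)
    dn = np.asarray(dn, dtype=float)
    out = np.sqrt((dn / 6.0) ** 2 + dh**2)
    return float(out) if out.ndim == 0 else out


def predict_unfolded_shift(state: SpeciesState, d_free: float, d_bound: float) -> float:
    """Fast-exchange shift of an unfolded-pool peak.

    Population-weighted average of the free (F_U) and encounter-complex
    (B_U) environments; always lies between the two limiting shifts.
    """
    pool = state.f_u + state.b_u
    if pool <= 0:
        raise ValueError("unfolded pool is empty; fast-exchange shift undefined")
    return (state.f_u * d_free + state.b_u * d_bound) / pool


def average_csp_series(
    traj: ShiftTrajectory, reference_point: int = 0
) -> np.ndarray:
    """Mean CSP over residues vs the reference point, per titration point.

    Residues absent at a point are excluded from that point's mean (and
    logged); residues absent at the reference make the series undefined
    for them everywhere.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 titration points")
    ref = traj.points[reference_point].shifts.data.set_index("residue")
    out = np.empty(len(traj))
    for i, pt in enumerate(traj.points):
        cur = pt.shifts.data.set_index("residue")
        shared = ref.index.intersection(cur.index)
        if len(shared) == 0:
            raise ValueError(f"no residues shared with the reference at point {i}")
        if len(shared) < len(ref):
            logger.info(
                "point %d: %d residues missing from mean CSP", i, len(ref) - len(shared)
            )
        dh = cur.loc[shared, "dh"].to_numpy() - ref.loc[shared, "dh"].to_numpy()
        dn = cur.loc[shared, "dn"].to_numpy() - ref.loc[shared, "dn"].to_numpy()
        out[i] = float(np.mean(csp(dh, dn)))
    return out


@dataclass
class ShiftTitrationFit:
    """Result of fitting the average-CSP trajectory.

    ``kd1`` is the microscopic encounter Kd (µM), ``amplitude`` the
    saturating mean CSP (ppm).  ``kd1_ci`` is a ±1.96σ asymptotic
    interval (equal bounds in constrained mode, where kd1 is fixed).
    """

    kd1: float
    amplitude: float
    kd1_err: float
    amplitude_err: float
    kd1_ci: tuple[float, float]
    mode: str
    k2: float
    residuals: np.ndarray
    converged: bool
    noise_floor: float = 0.0
    lmfit_result: lmfit.minimizer.MinimizerResult | None = field(
        default=None, repr=False, compare=False
    )

    def summary(self) -> str:
        lines = [
            "Three-state shift-trajectory fit",
            f"  mode: {self.mode} (k2 = {self.k2:g})",
            f"  kd1 = {self.kd1:.4g} µM"
            + (
                f" ± {self.kd1_err:.2g} (95% CI {self.kd1_ci[0]:.3g}–{self.kd1_ci[1]:.3g})"
                if self.mode == "unconstrained"
                else " (fixed by kd_app·(1+k2))"
            ),
            f"  amplitude = {self.amplitude:.4g} ± {self.amplitude_err:.2g} ppm",
            f"  RMS residual = {float(np.sqrt(np.mean(self.residuals ** 2))):.3g} ppm",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kd1_uM": self.kd1,
            "kd1_err_uM": self.kd1_err,
            "kd1_ci_uM": list(self.kd1_ci),
            "amplitude_ppm": self.amplitude,
            "amplitude_err_ppm": self.amplitude_err,
            "mode": self.mode,
            "k2": self.k2,
            "converged": self.converged,
        }


class ShiftTitrationModel:
    """Fit the average unfolded-form CSP series under the three-state model.

    The observed mean CSP at titration point i is modeled as

        A · b_u(i) / (f_u(i) + b_u(i))

    the saturating amplitude times the bound fraction of the fast-exchange
    unfolded pool, with species concentrations from the mass-balance
    solver at that point's dilution-corrected totals.

    Parameters
    ----------
    traj : ShiftTrajectory
    kd_app : float
        Externally measured macroscopic Kd (µM), e.g. from anisotropy.
    k2 : float
        Externally estimated folding constant (e.g. from slow-exchange
        peak volumes); held fixed during the fit.
    """

    def __init__(self, traj: ShiftTrajectory, kd_app: float, k2: float) -> None:
        if len(traj) < 4:
            raise ValueError("need at least 4 titration points to fit")
        self.traj = traj
        self.kd_app = float(kd_app)
        self.k2 = float(k2)
        self._y = average_csp_series(traj)
        self._totals = traj.totals

    def _bound_fraction(self, kd1: float) -> np.ndarray:
        model = ThreeStateModel(kd1=kd1, k2=self.k2)
        out = np.empty(len(self._totals))
        for i, (p, r) in enumerate(self._totals):
            out[i] = solve_species(p, r, model).unfolded_bound_fraction
        return out

    def fit(self, mode: str = "unconstrained", noise_floor: bool = True) -> ShiftTitrationFit:
        """Fit amplitude (and kd1 when unconstrained) by least squares.

        ``constrained`` fixes kd1 = kd_app·(1+k2) and fits the amplitude
        alone (a linear problem); ``unconstrained`` floats kd1 as well,
        initialized at the constrained value.

        The mean-CSP series is a mean of magnitudes, so measurement noise
        adds a positive floor at every non-reference point (the reference
        is compared with itself and sits at exactly zero).  With
        ``noise_floor=True`` (unconstrained mode) the model becomes
        sqrt((A·frac)² + floor²) away from the reference, with the floor a
        third fitted parameter; on noiseless data the floor collapses to
        zero and the fit is exact, on noisy data it removes the upward
        bias in kd1 that the rectified noise would otherwise cause.
        """
        if mode not in ("constrained", "unconstrained"):
            raise ValueError(f"mode must be 'constrained' or 'unconstrained', got {mode!r}")
        kd1_0 = microscopic_kd(self.kd_app, self.k2)
        y = self._y

        frac0 = self._bound_fraction(kd1_0)
        titrated = self._totals[:, 1] > 0
        if titrated.any() and np.all(frac0[titrated] > 0.95):
            warnings.warn(
                "all titration points are near saturation; kd1 is poorly "
                "constrained by this design",
                stacklevel=2,
            )

        if mode == "constrained":
            denom = float(frac0 @ frac0)
            if denom == 0:
                raise RuntimeError("design matrix is zero; no binding signal to fit")
            amp = float(frac0 @ y) / denom
            resid = y - amp * frac0
            dof = max(len(y) - 1, 1)
            amp_err = float(np.sqrt((resid @ resid) / dof / denom))
            return ShiftTitrationFit(
                kd1=kd1_0,
                amplitude=amp,
                kd1_err=0.0,
                amplitude_err=amp_err,
                kd1_ci=(kd1_0, kd1_0),
                mode=mode,
                k2=self.k2,
                residuals=resid,
                converged=True,
            )

        params = lmfit.Parameters()
        params.add("kd1", value=kd1_0, min=1e-9)
        params.add("amplitude", value=float(np.max(y)) or 1.0)
        ymax = float(np.max(y))
        params.add(
            "floor",
            value=0.01 * ymax if ymax > 0 else 1e-6,
            min=0.0,
            vary=noise_floor,
        )
        # the reference point is compared with itself: no noise floor there
        mask = np.ones_like(y)
        mask[0] = 0.0

        def resid_fn(p):
            frac = self._bound_fraction(p["kd1"].value)
            signal = p["amplitude"].value * frac
            return np.sqrt(signal**2 + (p["floor"].value * mask) ** 2) - y

        result = lmfit.minimize(resid_fn, params, method="leastsq")
        if not result.success:
            raise RuntimeError(f"shift-trajectory fit did not converge: {result.message}")
        kd1 = float(result.params["kd1"].value)
        amp = float(result.params["amplitude"].value)
        floor = float(result.params["floor"].value)
        kd1_err = result.params["kd1"].stderr
        amp_err = result.params["amplitude"].stderr
        kd1_err = float(kd1_err) if kd1_err is not None else float("nan")
        amp_err = float(amp_err) if amp_err is not None else float("nan")
        ci = (kd1 - 1.96 * kd1_err, kd1 + 1.96 * kd1_err) if np.isfinite(kd1_err) else (
            float("nan"),
            float("nan"),
        )
        fitted = np.sqrt((amp * self._bound_fraction(kd1)) ** 2 + (floor * mask) ** 2)
        return ShiftTitrationFit(
            kd1=kd1,
            amplitude=amp,
            kd1_err=kd1_err,
            amplitude_err=amp_err,
            kd1_ci=ci,
            mode=mode,
            k2=self.k2,
            residuals=y - fitted,
            converged=bool(result.success),
            noise_floor=floor,
            lmfit_result=result,
        )


def fit_microscopic_kd(
    traj: ShiftTrajectory, kd_app: float, k2: float, mode: str = "unconstrained"
) -> ShiftTitrationFit:
    """Recover the microscopic encounter Kd from the average-CSP series."""
    return ShiftTitrationModel(traj, kd_app=kd_app, k2=k2).fit(mode=mode)


def estimate_k2_from_volumes(
    vol_unfolded: float, vol_folded: float, state: SpeciesState | None = None
) -> float:
    """Folding constant K2 from slow-exchange peak volumes.

    The naive estimate vol_folded/vol_unfolded equates the unfolded-peak
    volume with [B_U]; in reality that peak also carries the free protein
    (fast exchange), so with a species state the free-unfolded
    contribution is divided out:

        k2 = (vol_folded / vol_unfolded) · (1 + f_u/b_u)

    which is exact when volumes are proportional to populations.
    """
    if vol_unfolded <= 0 or vol_folded <= 0:
        raise ValueError("peak volumes must be positive")
    naive = vol_folded / vol_unfolded
    if state is None:
        return naive
    if state.b_u <= 0:
        raise ValueError("species state has no bound-unfolded population")
    return naive * (1.0 + state.f_u / state.b_u)


def predict_intensity_evolution(
    points, model: ThreeStateModel, normalization: str = "max"
):
    """Normalized intensity series of the unfolded and folded peak sets.

    The unfolded series is proportional to f_u + b_u (one fast-exchange
    pool), the folded series to b_f; each is normalized to its own
    maximum over the series (or to the first/last nonzero point with
    ``normalization="first"``).

    Parameters
    ----------
    points : sequence of (p_total, r_total) in µM.

    Returns
    -------
    (unfolded, folded) : two ndarrays.
    """
    if normalization not in ("max", "first"):
        raise ValueError("normalization must be 'max' or 'first'")
    states = [solve_species(p, r, model) for p, r in points]
    unfolded = np.array([s.f_u + s.b_u for s in states])
    folded = np.array([s.b_f for s in states])

    def _norm(x):
        if normalization == "max":
            ref = x.max()
        else:
            nz = x[x > 0]
            ref = nz[0] if len(nz) else 0.0
        return x / ref if ref > 0 else x

    return _norm(unfolded), _norm(folded)


def secondary_shifts(
    table: ShiftTable, rc: RandomCoilTable, combine: str = "sum"
) -> pd.DataFrame:
    """Combined CA/C' secondary chemical shifts per residue.

    Δδ = observed − random coil for each nucleus; positive combined
    values indicate helical propensity, negative extended/strand.
    ``combine`` is "sum" (default) or "mean".  Residues lacking CA or C'
    are skipped and logged.
    """
    if combine not in ("sum", "mean"):
        raise ValueError("combine must be 'sum' or 'mean'")
    df = table.data
    if "ca" not in df.columns or "co" not in df.columns:
        raise ValueError("shift table has no CA/C' columns")
    rows = []
    skipped = 0
    for _, row in df.iterrows():
        if pd.isna(row.get("ca")) or pd.isna(row.get("co")):
            skipped += 1
            continue
        d_ca = row["ca"] - rc.ca(row["aa"])
        d_co = row["co"] - rc.co(row["aa"])
        combined = d_ca + d_co if combine == "sum" else 0.5 * (d_ca + d_co)
        rows.append(
            {
                "residue": int(row["residue"]),
                "aa": row["aa"],
                "d_ca": d_ca,
                "d_co": d_co,
                "combined": combined,
            }
        )
    if skipped:
        logger.info("secondary_shifts: skipped %d residues lacking CA or C'", skipped)
    return pd.DataFrame(rows)


def hetnoe_region_summary(
    table: ShiftTable, regions: list[tuple[int, int]], rigidity_threshold: float = 0.5
) -> pd.DataFrame:
    """Mean/sd of the 1H-15N heteronuclear NOE per residue region.

    Regions are inclusive (start, end) residue-number ranges.  Regions
    whose mean exceeds ``rigidity_threshold`` are flagged rigid; empty
    regions are flagged, not fatal.
    """
    df = table.data
    if "hetnoe" not in df.columns:
        raise ValueError("shift table has no hetNOE column")
    rows = []
    for start, end in regions:
        sel = df[(df["residue"] >= start) & (df["residue"] <= end)]["hetnoe"].dropna()
        if len(sel) == 0:
            logger.warning("hetNOE region %d-%d is empty", start, end)
            rows.append(
                {
                    "start": start,
                    "end": end,
                    "n": 0,
                    "mean": float("nan"),
                    "sd": float("nan"),
                    "rigid": False,
                    "empty": True,
                }
            )
            continue
        mean = float(sel.mean())
        sd = float(sel.std(ddof=0))
        rows.append(
            {
                "start": start,
                "end": end,
                "n": int(len(sel)),
                "mean": mean,
                "sd": sd,
                "rigid": mean > rigidity_threshold,
                "empty": False,
            }
        )
    return pd.DataFrame(rows)
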