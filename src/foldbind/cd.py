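"""MCR-ALS decomposition of circular dichroism titration spectra.

A CD titration matrix D (titration points × wavelengths) of a mixture
that obeys Beer–Lambert additivity is bilinear, D = C·S, with C the
non-negative concentration profiles and S the signed pure-component
spectra.  Multivariate curve resolution by alternating least squares
(MCR-ALS) recovers C and S up to permutation and scale by alternating
the two conditional least-squares problems under constraints.  Here the
only default constraint is non-negativity of C: CD spectra are signed
(the unfolded-protein minimum near 200 nm is negative), so S is left
free.  For a protein titrated with RNA there is no common closure — RNA
accumulates while total protein stays fixed — but an optional closure
over a subset of components (the two protein forms) is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

__all__ = [
    "SpectraMatrix",
    "DecompositionResult",
    "MCRALS",
    "estimate_rank",
    "mcr_als",
    "match_components",
]

logger = logging.getLogger(__name__)


@dataclass
class SpectraMatrix:
    """CD titration matrix: rows = titration points, columns = wavelengths."""

    wavelengths: np.ndarray
    D: np.ndarray
    equivalents: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.D = np.atleast_2d(np.asarray(self.D, dtype=float))
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.D.shape[1] != len(self.wavelengths):
            raise ValueError(
                f"D has {self.D.shape[1]} columns but {len(self.wavelengths)} wavelengths"
            )
        if np.all(np.isnan(self.D), axis=0).any():
            raise ValueError("spectra matrix has all-NaN wavelength columns")
        if self.equivalents is not None:
            self.equivalents = np.asarray(self.equivalents, dtype=float)
            if len(self.equivalents) != self.D.shape[0]:
                raise ValueError("equivalents length does not match number of spectra")

    @property
    def n_points(self) -> int:
        return self.D.shape[0]


def estimate_rank(
    m: SpectraMatrix,
    noise_level: float | None = None,
    sv_factor: float = 5.0,
    rel_tol: float = 1e-6,
) -> int:
    """Number of spectroscopically significant components by SVD.

    Counts singular values above a noise threshold.  When the
    per-element noise standard deviation ``noise_level`` is supplied
    (e.g. from blank scans or replicate spectra), the threshold is 1.5×
    the largest singular value a pure-noise matrix of this shape would
    show, ``noise_level·(√n + √m)``.  Without it the floor is estimated
    blindly as ``sv_factor`` times the median of the smaller half of the
    singular-value spectrum — deliberately conservative for matrices
    with few spectra.  In both cases the threshold is at least
    ``rel_tol`` times the largest singular value.  Deterministic for a
    given matrix.
    """
    if m.n_points < 3:
        raise ValueError("need at least 3 titration points to estimate rank")
    s = np.linalg.svd(m.D, compute_uv=False)
    k = len(s)
    if noise_level is not None:
        n, w = m.D.shape
        floor = 1.5 * noise_level * (np.sqrt(n) + np.sqrt(w))
    else:
        tail = s[k - max(2, (k + 1) // 2):]
        floor = sv_factor * float(np.median(tail))
    threshold = max(floor, rel_tol * s[0])
    rank = int(np.sum(s > threshold))
    if rank >= k:
        warnings.warn(
            f"all {k} singular values exceed the noise threshold; rank capped "
            "at the number of spectra — acquire more titration points",
            stacklevel=2,
        )
    return rank


@dataclass
class DecompositionResult:
    """MCR-ALS output.

    ``C``: points × components, non-negative, each column scaled to unit
    maximum; ``S``: components × wavelengths, signed, carrying the scale.
    ``lof`` is the final lack of fit in percent,
    100·sqrt(Σ(D−CS)²/ΣD²).
    """

    C: np.ndarray
    S: np.ndarray
    wavelengths: np.ndarray
    lof: float
    lof_history: np.ndarray
    n_iter: int
    converged: bool
    labels: list[str] | None = field(default=None)

    def reconstruct(self) -> np.ndarray:
        return self.C @ self.S

    def plot(self, axes=None):
        """Draw profiles and spectra; see plotting.plot_decomposition."""
        from .plotting import plot_decomposition

        return plot_decomposition(self, axes=axes)

    @property
    def n_components(self) -> int:
        return self.C.shape[1]

    def summary(self) -> str:
        lines = [
            f"MCR-ALS decomposition: {self.n_components} components, "
            f"{self.n_iter} iterations, converged={self.converged}",
            f"  lack of fit: {self.lof:.4g} %",
        ]
        if self.labels:
            lines.append("  labels: " + ", ".join(self.labels))
        return "\n".join(lines)


def _purest_rows(D: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k most mutually dissimilar rows (greedy projection)."""
    norms = np.linalg.norm(D, axis=1)
    chosen = [int(np.argmax(norms))]
    basis = D[chosen[0]][None, :] / max(norms[chosen[0]], 1e-300)
    for _ in range(1, k):
        # residual of each row after projection onto the chosen span
        q, _ = np.linalg.qr(basis.T)
        resid = D - (D @ q) @ q.T
        rnorm = np.linalg.norm(resid, axis=1)
        rnorm[chosen] = -1.0
        nxt = int(np.argmax(rnorm))
        chosen.append(nxt)
        basis = np.vstack([basis, D[nxt] / max(np.linalg.norm(D[nxt]), 1e-300)])
    return np.array(chosen)


class MCRALS:
    """Alternating-least-squares bilinear decomposition of a spectra matrix.

    Parameters
    ----------
    m : SpectraMatrix
    n_components : int
        Requested rank (1 ≤ k ≤ min(points, wavelengths)).
    init : {"purest", "svd"}
        Initial spectra: the most mutually dissimilar measured rows
        (SIMPLISMA-flavored, default) or truncated-SVD loadings.
    nonneg_c : bool
        Non-negativity on concentration profiles (default True).
    closure : sequence of int, optional
        Component indices whose concentrations are rescaled to a constant
        sum at every point (e.g. the two protein forms when total protein
        is fixed).  The rescaling is a projection, not a least-squares
        step, so strict lack-of-fit monotonicity is guaranteed only
        without closure.
    closure_total : float, optional
        The conserved total for the closure set, in the units of the
        profiles (meaningful when a fixed reference spectrum anchors the
        scale); defaults to the median of the unconstrained totals.
    known_profiles : dict of {int: ndarray}, optional
        Equality constraints on concentration profiles, for components
        whose concentration the experimenter controls (the accumulating
        titrant).  Fixed profiles keep their physical units and are
        excluded from the unit-maximum renormalization.
    known_spectra : dict of {int: ndarray}, optional
        Equality constraints on component spectra: each entry fixes that
        component's spectrum to a measured reference (e.g. the free
        protein measured before the titration, or the free titrant
        measured separately) and only the remaining spectra are updated.
        This is the standard remedy for rotational ambiguity in titration
        MCR; profiles of fixed components keep the physical units implied
        by their reference and are excluded from the unit-maximum
        renormalization.
    tol : float
        Convergence: relative change of lack of fit (default 1e-8).
    max_iter : int
        Iteration cap (default 500).
    seed : int
        Seed for the reseeding perturbation on a rank-deficient start.
    """

    def __init__(
        self,
        m: SpectraMatrix,
        n_components: int,
        init: str = "purest",
        nonneg_c: bool = True,
        closure: list[int] | None = None,
        closure_total: float | None = None,
        known_spectra: dict[int, np.ndarray] | None = None,
        known_profiles: dict[int, np.ndarray] | None = None,
        tol: float = 1e-8,
        max_iter: int = 500,
        seed: int = 0,
    ) -> None:
        kmax = min(m.D.shape)
        if not 1 <= n_components <= kmax:
            raise ValueError(f"n_components must be in [1, {kmax}], got {n_components}")
        if init not in ("purest", "svd"):
            raise ValueError("init must be 'purest' or 'svd'")
        if known_spectra:
            for idx, sp in known_spectra.items():
                if not 0 <= idx < n_components:
                    raise ValueError(f"known_spectra index {idx} out of range")
                if len(np.asarray(sp)) != len(m.wavelengths):
                    raise ValueError(
                        f"known spectrum {idx} has {len(np.asarray(sp))} points, "
                        f"expected {len(m.wavelengths)}"
                    )
        if known_profiles:
            for idx, cp in known_profiles.items():
                if not 0 <= idx < n_components:
                    raise ValueError(f"known_profiles index {idx} out of range")
                if len(np.asarray(cp)) != m.n_points:
                    raise ValueError(
                        f"known profile {idx} has {len(np.asarray(cp))} points, "
                        f"expected {m.n_points}"
                    )
        self.m = m
        self.k = n_components
        self.init = init
        self.nonneg_c = nonneg_c
        self.closure = closure
        self.closure_total = closure_total
        self.known_spectra = {
            int(i): np.asarray(sp, dtype=float) for i, sp in (known_spectra or {}).items()
        }
        self.known_profiles = {
            int(i): np.asarray(cp, dtype=float) for i, cp in (known_profiles or {}).items()
        }
        self.tol = tol
        self.max_iter = max_iter
        self.seed = seed

    def _init_spectra(self) -> np.ndarray:
        D = self.m.D
        if self.init == "purest":
            return D[_purest_rows(D, self.k)].copy()
        _, _, vt = np.linalg.svd(D, full_matrices=False)
        return vt[: self.k].copy()

    def _solve_c(self, S: np.ndarray) -> np.ndarray:
        D = self.m.D
        fixed = sorted(self.known_profiles)
        free = [j for j in range(self.k) if j not in self.known_profiles]
        C = np.zeros((D.shape[0], self.k))
        for idx in fixed:
            C[:, idx] = self.known_profiles[idx]
        R = D - C[:, fixed] @ S[fixed] if fixed else D
        if not free:
            pass
        elif self.nonneg_c:
            for i in range(D.shape[0]):
                C[i, free], _ = nnls(S[free].T, R[i])
        else:
            C[:, free] = np.linalg.lstsq(S[free].T, R.T, rcond=None)[0].T
        if self.closure is not None:
            idx = list(self.closure)
            sub = C[:, idx]
            total = sub.sum(axis=1)
            if self.closure_total is not None:
                target = float(self.closure_total)
            else:
                target = float(np.median(total[total > 0])) if np.any(total > 0) else 0.0
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(total > 0, target / total, 1.0)
            C[:, idx] = sub * scale[:, None]
        return C

    def _lof(self, C: np.ndarray, S: np.ndarray) -> float:
        resid = self.m.D - C @ S
        return 100.0 * np.sqrt(np.sum(resid**2) / np.sum(self.m.D**2))

    def _update_spectra(self, C: np.ndarray, S: np.ndarray) -> np.ndarray:
        fixed = sorted(self.known_spectra)
        free = [j for j in range(self.k) if j not in self.known_spectra]
        if not free:
            return S
        if not fixed:
            return np.linalg.lstsq(C, self.m.D, rcond=None)[0]
        R = self.m.D - C[:, fixed] @ S[fixed]
        S = S.copy()
        S[free] = np.linalg.lstsq(C[:, free], R, rcond=None)[0]
        return S

    def fit(self) -> DecompositionResult:
        """Run ALS to convergence; non-convergence yields converged=False."""
        S = self._init_spectra()
        for idx, sp in self.known_spectra.items():
            S[idx] = sp
        if self.known_spectra:
            # start the free spectra orthogonal to the fixed ones, so the
            # first C-step does not misattribute known contributions
            fixed = sorted(self.known_spectra)
            free = [j for j in range(self.k) if j not in self.known_spectra]
            if free:
                q, _ = np.linalg.qr(S[fixed].T)
                S[free] = S[free] - (S[free] @ q) @ q.T
        for attempt in range(2):
            if np.linalg.matrix_rank(S) == self.k:
                break
            if attempt == 1:
                raise RuntimeError("rank-deficient initialization after reseeding")
            logger.warning("rank-deficient initial spectra; reseeding with perturbation")
            rng = np.random.default_rng(self.seed)
            free = [j for j in range(self.k) if j not in self.known_spectra]
            S[free] = S[free] + rng.normal(
                scale=1e-6 * max(np.abs(S).max(), 1.0), size=S[free].shape
            )

        history = []
        prev = None
        converged = False
        C = self._solve_c(S)
        for it in range(1, self.max_iter + 1):
            S = self._update_spectra(C, S)
            C = self._solve_c(S)
            lof = self._lof(C, S)
            history.append(lof)
            # 1e-8 % lack of fit is reconstruction to ~1e-10 relative:
            # further ALS sweeps only churn machine noise
            if lof < 1e-8 or (
                prev is not None and prev - lof <= self.tol * max(prev, 1e-300)
            ):
                converged = True
                break
            prev = lof
        if not converged:
            warnings.warn(
                f"MCR-ALS did not converge in {self.max_iter} iterations "
                f"(lack of fit {history[-1]:.3g} %)",
                stacklevel=2,
            )
        # Resolve the intensity ambiguity: unit-maximum concentration
        # profiles, scale absorbed into the spectra.  Components with a
        # fixed reference spectrum keep their physical scale.
        scale = C.max(axis=0)
        scale[scale == 0] = 1.0
        keep = set(self.known_spectra) | set(self.known_profiles) | set(self.closure or [])
        for idx in keep:
            scale[idx] = 1.0
        C = C / scale
        S = S * scale[:, None]
        return DecompositionResult(
            C=C,
            S=S,
            wavelengths=self.m.wavelengths,
            lof=history[-1] if history else float("nan"),
            lof_history=np.array(history),
            n_iter=len(history),
            converged=converged,
        )


def mcr_als(
    m: SpectraMatrix,
    n_components: int,
    init: str = "purest",
    nonneg_c: bool = True,
    closure: list[int] | None = None,
    closure_total: float | None = None,
    known_spectra: dict[int, np.ndarray] | None = None,
    known_profiles: dict[int, np.ndarray] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> DecompositionResult:
    """Decompose a spectra matrix into concentration profiles and spectra."""
    return MCRALS(
        m,
        n_components,
        init=init,
        nonneg_c=nonneg_c,
        closure=closure,
        closure_total=closure_total,
        known_spectra=known_spectra,
        known_profiles=known_profiles,
        tol=tol,
        max_iter=max_iter,
        seed=seed,
    ).fit()


def match_components(
    res: DecompositionResult,
    refs: dict[str, tuple[np.ndarray, np.ndarray]],
    threshold: float = 0.8,
):
    """Label components by best Pearson correlation to reference spectra.

    ``refs`` maps label -> (wavelengths, spectrum); references are
    linearly resampled onto the decomposition grid.  Assignment is
    one-to-one (Hungarian on −correlation); a component whose best match
    correlates below ``threshold`` stays unassigned.

    Returns a list of (label or None, correlation) per component and
    stores labels on the result.
    """
    import pandas as pd

    if not refs:
        raise ValueError("reference library is empty")
    wl = res.wavelengths
    labels = list(refs)
    R = np.empty((res.n_components, len(labels)))
    for j, lab in enumerate(labels):
        rwl, rsp = refs[lab]
        rwl = np.asarray(rwl, dtype=float)
        rsp = np.asarray(rsp, dtype=float)
        if wl[0] > rwl[-1] or wl[-1] < rwl[0]:
            raise ValueError(f"reference {lab!r} does not overlap the wavelength grid")
        resampled = np.interp(wl, rwl, rsp)
        for i in range(res.n_components):
            R[i, j] = np.corrcoef(res.S[i], resampled)[0, 1]
    rows, cols = linear_sum_assignment(-R)
    assignment: list[tuple[str | None, float]] = [(None, float("nan"))] * res.n_components
    for i, j in zip(rows, cols):
        corr = float(R[i, j])
        assignment[i] = (labels[j] if corr >= threshold else None, corr)
    res.labels = [lab if lab is not None else "unassigned" for lab, _ in assignment]
    return pd.DataFrame(
        {
            "component": np.arange(res.n_components),
            "label": [lab for lab, _ in assignment],
            "correlation": [c for _, c in assignment],
        }
    )
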