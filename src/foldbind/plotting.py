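"""Diagnostic figures for the fitted models.

Each function takes a fit/result object, draws onto a matplotlib Axes
(created on demand) and returns it; nothing is written to disk here.
"""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_isotherm(fit, ax=None, normalized: bool = False):
    """Anisotropy titration points with the fitted single-site curve.

    With ``normalized=True`` the curve is shown as (r − r0)/a, so the
    half-saturation point sits at 0.5.
    """
    ax = _axes(ax)
    t = fit.titration
    conc = t.ligand_conc
    grid = np.concatenate([[0.0], np.geomspace(max(conc[conc > 0].min(), 1e-3) / 3,
                                               conc.max() * 1.5, 200)])
    y_data, y_model = t.r, fit.predict(grid)
    if normalized:
        y_data = (y_data - fit.r0) / fit.a
        y_model = (y_model - fit.r0) / fit.a
    if t.r_err is not None and not normalized:
        ax.errorbar(conc, y_data, yerr=t.r_err, fmt="o", ms=4, label="data")
    else:
        ax.plot(conc, y_data, "o", ms=4, label="data")
    ax.plot(grid, y_model, "-", label=f"fit: b = {fit.b:.0f} nM")
    ax.set_xlabel("added protein (nM)")
    ax.set_ylabel("normalized anisotropy" if normalized else "anisotropy")
    ax.legend()
    return ax


def plot_csp_fit(model, fit, ax=None):
    """Average unfolded-form CSP series with the three-state fitted curve.

    Parameters
    ----------
    model : ShiftTitrationModel
    fit : ShiftTitrationFit
    """
    ax = _axes(ax)
    eqs = model.traj.equivalents
    ax.plot(eqs, model._y, "o", label="mean CSP")
    frac = model._bound_fraction(fit.kd1)
    curve = fit.amplitude * frac
    if fit.noise_floor > 0:
        mask = np.ones_like(curve)
        mask[0] = 0.0
        curve = np.sqrt(curve**2 + (fit.noise_floor * mask) ** 2)
    ax.plot(eqs, curve, "-", label=f"fit: kd1 = {fit.kd1:.2g} µM")
    ax.set_xlabel("RNA equivalents")
    ax.set_ylabel("mean CSP (ppm)")
    ax.legend()
    return ax


def plot_decomposition(res, axes=None):
    """Concentration profiles (left) and component spectra (right)."""
    if axes is None:
        import matplotlib.pyplot as plt

        _, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ax_c, ax_s = axes
    labels = res.labels or [f"component {i}" for i in range(res.n_components)]
    for i in range(res.n_components):
        ax_c.plot(res.C[:, i], "o-", label=labels[i])
        ax_s.plot(res.wavelengths, res.S[i], "-", label=labels[i])
    ax_c.set_xlabel("titration point")
    ax_c.set_ylabel("relative concentration")
    ax_s.set_xlabel("wavelength (nm)")
    ax_s.set_ylabel("ellipticity (a.u.)")
    ax_s.axhline(0.0, color="k", lw=0.5)
    ax_c.legend(fontsize=8)
    return axes
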