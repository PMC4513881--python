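"""Synthetic titration data with known ground truth.

Each generator emulates one of the experiments analyzed by the package
— anisotropy isotherms, NMR shift titrations under the three-state
coupled binding-and-folding model, CD titration matrices, and
free-state shift/NOE tables — and returns the data together with the
generating parameters, so every downstream fit has a machine-checkable
recovery target.  All randomness is controlled by a single integer
seed.

Default scenario parameters mirror the study design the analyses
assume: a 50 nM labeled nucleic acid titrated with protein
(anisotropy); a 200 µM protein sample titrated with a 400 µM RNA stock
in 0.25-equivalent steps with dilution (NMR); an 8 µM protein CD
titration in 0.25-equivalent RNA steps over 200–300 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anisotropy import AnisotropyTitration
from .cd import SpectraMatrix
from .equilibria import ThreeStateModel, solve_species
from .nmr import ShiftTable, ShiftTrajectory, TitrationPoint

__all__ = [
    "AnisotropyScenario",
    "NMRScenario",
    "CDScenario",
    "DisorderScenario",
    "gen_anisotropy",
    "gen_nmr_trajectory",
    "gen_cd_titration",
    "gen_shift_tables",
    "protein_basis_spectrum_unfolded",
    "protein_basis_spectrum_folded",
    "rna_basis_spectrum",
]

# default construct: an 80-residue dsRBD numbered 1732-1811 in the full protein
_DEFAULT_FIRST_RESIDUE = 1732
_DEFAULT_N_RESIDUES = 80
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# anisotropy
# ---------------------------------------------------------------------------


@dataclass
class AnisotropyScenario:
    """Ground truth for a synthetic anisotropy titration.

    ``kd_nM`` is the apparent dissociation constant b of the hyperbola;
    the default grid is 12 points: zero plus log-spaced concentrations
    up to 10·b, which brackets half-saturation.  ``noise_sigma`` is the
    additive Gaussian standard deviation on r, matching the role of the
    standard error of triplicate measurements (default 0.003 anisotropy
    units).
    """

    kd_nM: float = 300.0
    r0: float = 0.05
    a: float = 0.10
    label_conc: float = 50.0
    n_points: int = 12
    conc_max_nM: float | None = None
    noise_sigma: float = 0.003
    label: str = "synthetic"

    def grid(self) -> np.ndarray:
        top = self.conc_max_nM if self.conc_max_nM is not None else 10.0 * self.kd_nM
        pos = np.geomspace(top / 200.0, top, self.n_points - 1)
        return np.concatenate([[0.0], pos])


def gen_anisotropy(
    cfg: AnisotropyScenario | None = None, seed: int | np.random.Generator = 0
) -> tuple[AnisotropyTitration, dict]:
    """Hyperbolic isotherm r = r0 + a·[P]/(b+[P]) plus Gaussian noise."""
    cfg = cfg or AnisotropyScenario()
    rng = _rng(seed)
    conc = cfg.grid()
    clean = cfg.r0 + cfg.a * conc / (cfg.kd_nM + conc)
    r = clean + rng.normal(scale=cfg.noise_sigma, size=conc.shape) if cfg.noise_sigma > 0 else clean
    t = AnisotropyTitration(
        ligand_conc=conc,
        r=r,
        r_err=np.full_like(conc, cfg.noise_sigma) if cfg.noise_sigma > 0 else None,
        label_conc=cfg.label_conc,
        label=cfg.label,
    )
    truth = {"r0": cfg.r0, "a": cfg.a, "b_nM": cfg.kd_nM, "noise_sigma": cfg.noise_sigma}
    return t, truth


# ---------------------------------------------------------------------------
# NMR titration
# ---------------------------------------------------------------------------


@dataclass
class NMRScenario:
    """Ground truth for a synthetic NMR shift titration.

    A ``p0`` µM protein sample of volume ``v0`` µL is titrated with a
    ``stock`` µM RNA stock; each scheduled point states cumulative added
    equivalents relative to the initial protein amount, and totals are
    dilution-corrected.  Per-residue bound-state shift offsets Δδ are
    drawn once from a log-normal magnitude distribution with random
    signs, multiplied by ``region_weight`` inside ``regions`` (the
    binding-interface segments: N-terminal half of helix 2 and strands
    2–3 in the folded topology).  ``shift_noise_frac`` scales the
    per-point shift noise to that fraction of the largest ground-truth
    CSP (σ_H = frac·maxCSP; σ_N = 6·σ_H).
    """

    p0: float = 200.0
    stock: float = 400.0
    v0: float = 300.0
    schedule: tuple[float, ...] = tuple(np.arange(0.0, 2.01, 0.25))
    kd1: float = 2.0
    k2: float = 5.0
    n_residues: int = _DEFAULT_N_RESIDUES
    first_residue: int = _DEFAULT_FIRST_RESIDUE
    # interface segments in construct numbering (strands 2-3, helix-2 N-term)
    regions: tuple[tuple[int, int], ...] = ((1762, 1775), (1786, 1796))
    region_weight: float = 3.0
    delta_h_scale: float = 0.03
    delta_h_sigma: float = 0.6
    shift_noise_frac: float = 0.05
    volume_noise_frac: float = 0.02
    dilution: bool = True

    def __post_init__(self) -> None:
        sched = np.asarray(self.schedule, dtype=float)
        if sched[0] != 0.0:
            raise ValueError("schedule must start at 0 equivalents (reference point)")
        if np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing")

    def totals(self) -> np.ndarray:
        """Dilution-corrected (p_total, r_total) per scheduled point, µM."""
        sched = np.asarray(self.schedule, dtype=float)
        n_prot = self.p0 * self.v0  # pmol-scale amount, units cancel
        out = np.empty((len(sched), 2))
        for i, eq in enumerate(sched):
            n_rna = eq * n_prot
            if self.dilution:
                v = self.v0 + n_rna / self.stock
            else:
                v = self.v0
            out[i] = (n_prot / v, n_rna / v)
        return out


def gen_nmr_trajectory(
    cfg: NMRScenario | None = None, seed: int | np.random.Generator = 0
) -> tuple[ShiftTrajectory, dict]:
    """Synthetic shift trajectory under the three-state model.

    Unfolded-pool peaks move in fast exchange between the free and
    encounter-complex environments; their volumes track f_u + b_u and the
    folded-form volume tracks b_f.  Returns the trajectory and a ground
    truth dict with the model constants, per-residue Δδ and the exact
    saturating mean CSP (``amplitude``).
    """
    cfg = cfg or NMRScenario()
    rng = _rng(seed)
    model = ThreeStateModel(kd1=cfg.kd1, k2=cfg.k2)
    residues = np.arange(cfg.first_residue, cfg.first_residue + cfg.n_residues)
    aa = rng.choice(_AA, size=cfg.n_residues)

    # free-state shifts: narrow dispersion typical of a disordered chain
    dh_free = rng.normal(8.2, 0.15, cfg.n_residues)
    dn_free = rng.normal(119.0, 3.0, cfg.n_residues)

    weights = np.ones(cfg.n_residues)
    for start, end in cfg.regions:
        weights[(residues >= start) & (residues <= end)] = cfg.region_weight
    mag_h = rng.lognormal(np.log(cfg.delta_h_scale), cfg.delta_h_sigma, cfg.n_residues)
    mag_n = rng.lognormal(np.log(6.0 * cfg.delta_h_scale), cfg.delta_h_sigma, cfg.n_residues)
    sign_h = rng.choice([-1.0, 1.0], cfg.n_residues)
    sign_n = rng.choice([-1.0, 1.0], cfg.n_residues)
    delta_h = weights * mag_h * sign_h
    delta_n = weights * mag_n * sign_n

    max_csp = float(np.max(np.sqrt((delta_n / 6.0) ** 2 + delta_h**2)))
    amplitude = float(np.mean(np.sqrt((delta_n / 6.0) ** 2 + delta_h**2)))
    sigma_h = cfg.shift_noise_frac * max_csp
    sigma_n = 6.0 * sigma_h

    totals = cfg.totals()
    points = []
    for eq, (p_tot, r_tot) in zip(cfg.schedule, totals):
        state = solve_species(p_tot, r_tot, model)
        frac = state.unfolded_bound_fraction
        dh = dh_free + frac * delta_h
        dn = dn_free + frac * delta_n
        if sigma_h > 0:
            dh = dh + rng.normal(scale=sigma_h, size=dh.shape)
            dn = dn + rng.normal(scale=sigma_n, size=dn.shape)
        vol_unfolded = state.f_u + state.b_u
        vol_folded = state.b_f
        vols = np.full(cfg.n_residues, vol_unfolded)
        if cfg.volume_noise_frac > 0 and vol_unfolded > 0:
            vols = vols * (
                1.0 + rng.normal(scale=cfg.volume_noise_frac, size=cfg.n_residues)
            )
            if vol_folded > 0:
                vol_folded = vol_folded * (1.0 + rng.normal(scale=cfg.volume_noise_frac))
        table = ShiftTable(
            pd.DataFrame(
                {
                    "residue": residues,
                    "aa": aa,
                    "dh": dh,
                    "dn": dn,
                    "volume": vols,
                }
            )
        )
        points.append(
            TitrationPoint(
                equivalents=float(eq),
                p_total=float(p_tot),
                r_total=float(r_tot),
                shifts=table,
                folded_volume=float(vol_folded) if vol_folded > 0 else None,
            )
        )
    traj = ShiftTrajectory(points)
    truth = {
        "kd1_uM": cfg.kd1,
        "k2": cfg.k2,
        "kd_app_uM": model.kd_app,
        "amplitude_ppm": amplitude,
        "max_csp_ppm": max_csp,
        "delta_h": delta_h,
        "delta_n": delta_n,
        "residues": residues,
        "sigma_h": sigma_h,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# CD titration
# ---------------------------------------------------------------------------


def protein_basis_spectrum_unfolded(wl: np.ndarray) -> np.ndarray:
    """Disordered-chain basis: single negative band centered at 200 nm."""
    return -22.0 * np.exp(-0.5 * ((wl - 200.0) / 7.0) ** 2)


def protein_basis_spectrum_folded(wl: np.ndarray) -> np.ndarray:
    """Folded α/β domain basis: negative double band near 208 and 222 nm plus
    the positive π→π* exciton band below 200 nm (its tail enters the grid)."""
    return (
        -12.0 * np.exp(-0.5 * ((wl - 208.0) / 6.0) ** 2)
        - 11.0 * np.exp(-0.5 * ((wl - 222.0) / 7.0) ** 2)
        + 14.0 * np.exp(-0.5 * ((wl - 193.0) / 6.0) ** 2)
    )


def rna_basis_spectrum(wl: np.ndarray) -> np.ndarray:
    """A-form duplex RNA basis: negative band at 210 nm, positive at 265 nm."""
    return -14.0 * np.exp(-0.5 * ((wl - 210.0) / 6.0) ** 2) + 10.0 * np.exp(
        -0.5 * ((wl - 265.0) / 12.0) ** 2
    )


@dataclass
class CDScenario:
    """Ground truth for a synthetic CD titration.

    An 8 µM protein sample is titrated with RNA in 0.25-equivalent
    steps; the measured matrix is the bilinear mixture of three signed
    basis spectra — unfolded protein, folded protein and RNA — weighted
    by the three-state populations (unfolded = f_u + b_u, folded = b_f)
    and total RNA.  ``noise_sigma_frac`` is relative to the largest
    absolute ellipticity in the noiseless matrix.
    """

    p0: float = 8.0
    schedule: tuple[float, ...] = tuple(np.arange(0.0, 2.01, 0.25))
    kd_app: float = 0.3
    k2: float = 5.0
    wl_start: float = 200.0
    wl_stop: float = 300.0
    wl_step: float = 1.0
    noise_sigma_frac: float = 0.0

    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_start, self.wl_stop + 0.5 * self.wl_step, self.wl_step)


def gen_cd_titration(
    cfg: CDScenario | None = None, seed: int | np.random.Generator = 0
) -> tuple[SpectraMatrix, dict]:
    """Bilinear CD titration matrix D = C·S (+ noise) with known C and S."""
    cfg = cfg or CDScenario()
    rng = _rng(seed)
    wl = cfg.wavelengths()
    S = np.vstack(
        [
            protein_basis_spectrum_unfolded(wl),
            rna_basis_spectrum(wl),
            protein_basis_spectrum_folded(wl),
        ]
    )
    model = ThreeStateModel(kd1=cfg.kd_app * (1.0 + cfg.k2), k2=cfg.k2)
    sched = np.asarray(cfg.schedule, dtype=float)
    C = np.empty((len(sched), 3))
    for i, eq in enumerate(sched):
        state = solve_species(cfg.p0, eq * cfg.p0, model)
        C[i] = (state.f_u + state.b_u, state.r_total, state.b_f)
    D = C @ S
    if cfg.noise_sigma_frac > 0:
        sigma = cfg.noise_sigma_frac * np.abs(D).max()
        D = D + rng.normal(scale=sigma, size=D.shape)
    m = SpectraMatrix(wavelengths=wl, D=D, equivalents=sched)
    truth = {
        "C": C,
        "S": S,
        "labels": ["unfolded_protein", "rna", "folded_protein"],
        "kd_app_uM": cfg.kd_app,
        "k2": cfg.k2,
    }
    return m, truth


# ---------------------------------------------------------------------------
# free-state disorder summaries
# ---------------------------------------------------------------------------


@dataclass
class DisorderScenario:
    """Ground truth for free-state CA/C'/hetNOE tables.

    The default emulates a chain whose C-terminal half transiently
    populates secondary structure (positive combined CA+C' offsets, a
    higher hetNOE plateau) while the N-terminal half is fully flexible.
    Offsets are in ppm per nucleus; ``helical_regions`` use construct
    numbering.
    """

    n_residues: int = _DEFAULT_N_RESIDUES
    first_residue: int = _DEFAULT_FIRST_RESIDUE
    helical_regions: tuple[tuple[int, int], ...] = ((1786, 1800),)
    strand_regions: tuple[tuple[int, int], ...] = ((1762, 1775),)
    helix_offset_ca: float = 1.5
    helix_offset_co: float = 1.0
    strand_offset_ca: float = -0.8
    strand_offset_co: float = -0.6
    shift_noise: float = 0.1
    noe_n_half: float = 0.1
    noe_c_half: float = 0.4
    noe_noise: float = 0.05


def gen_shift_tables(
    cfg: DisorderScenario | None = None, seed: int | np.random.Generator = 0
) -> tuple[ShiftTable, dict]:
    """CA/C' shifts around random-coil values plus a regional hetNOE profile."""
    from .nmr import RandomCoilTable

    cfg = cfg or DisorderScenario()
    rng = _rng(seed)
    rc = RandomCoilTable.bundled()
    residues = np.arange(cfg.first_residue, cfg.first_residue + cfg.n_residues)
    aa = rng.choice(_AA, size=cfg.n_residues)
    ca = np.array([rc.ca(a) for a in aa], dtype=float)
    co = np.array([rc.co(a) for a in aa], dtype=float)

    offsets_ca = np.zeros(cfg.n_residues)
    offsets_co = np.zeros(cfg.n_residues)
    for start, end in cfg.helical_regions:
        sel = (residues >= start) & (residues <= end)
        offsets_ca[sel] += cfg.helix_offset_ca
        offsets_co[sel] += cfg.helix_offset_co
    for start, end in cfg.strand_regions:
        sel = (residues >= start) & (residues <= end)
        offsets_ca[sel] += cfg.strand_offset_ca
        offsets_co[sel] += cfg.strand_offset_co
    ca = ca + offsets_ca
    co = co + offsets_co
    if cfg.shift_noise > 0:
        ca = ca + rng.normal(scale=cfg.shift_noise, size=cfg.n_residues)
        co = co + rng.normal(scale=cfg.shift_noise, size=cfg.n_residues)

    midpoint = cfg.first_residue + cfg.n_residues // 2
    noe = np.where(residues < midpoint, cfg.noe_n_half, cfg.noe_c_half).astype(float)
    if cfg.noe_noise > 0:
        noe = noe + rng.normal(scale=cfg.noe_noise, size=cfg.n_residues)

    table = ShiftTable(
        pd.DataFrame(
            {
                "residue": residues,
                "aa": aa,
                "dh": rng.normal(8.2, 0.15, cfg.n_residues),
                "dn": rng.normal(119.0, 3.0, cfg.n_residues),
                "ca": ca,
                "co": co,
                "hetnoe": noe,
            }
        )
    )
    truth = {
        "offsets_ca": offsets_ca,
        "offsets_co": offsets_co,
        "midpoint": midpoint,
        "noe_n_half": cfg.noe_n_half,
        "noe_c_half": cfg.noe_c_half,
    }
    return table, truth
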