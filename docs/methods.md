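# Methods

## The three-state model

All analyses share one mechanistic model: a disordered protein domain P
binds a structured RNA R in two coupled steps,

    F_U + R  ⇌  B_U·R   (encounter; Kd1 = [F_U][R]/[B_U], µM)
    B_U·R    ⇌  B_F·R   (on-RNA folding; K2 = [B_F]/[B_U], dimensionless)

with 1:1 stoichiometry and thermodynamic (not kinetic) treatment
throughout. Exchange kinetics enter only as regime assumptions: F_U ⇌ B_U
is fast on the NMR chemical-shift timescale (one population-averaged peak
set), B_U ⇌ B_F is slow (separate peak sets whose volumes report
populations). These regimes are inputs to the analysis, not inferred from
the data.

Because B_U and B_F are indistinguishable to any total-bound readout, the
scheme collapses exactly to a two-state system with

    Kd,app = Kd1 / (1 + K2).

The species solver exploits this: total bound B solves the usual 1:1
quadratic B² − (p+r+Kd,app)B + pr = 0, taken in the multiplication form
B = 2pr/(s + √(s²−4pr)) to avoid cancellation when Kd,app ≪ totals, and
the bound pool splits as b_f = K2·b_u. Unit convention: µM internally,
with converters for nM/µM/mM/M; temperature defaults to 298 K and
ΔG = −RT·ln K uses R = 8.314×10⁻³ kJ/(mol·K).

An independent bracketing root solve on the one-dimensional mass balance
in free RNA serves as the oracle in the test suite; the two routes agree
to 1e-8 relative over 1000 random parameter draws.

## Anisotropy isotherms

The observable is the anisotropy of a labeled nucleic acid (default
50 nM) as protein is added, fitted to r = r0 + a·[P]/(b+[P]) by
Levenberg–Marquardt least squares (lmfit), unweighted by default with
1/σ² weighting available. `[P]` is taken as the *added* protein
concentration by default — adequate when b is comparable to or larger
than the label concentration — and a `mode="free"` variant solves the 1:1
depletion quadratic so that b is the true Kd even for tight binders; the
unit test demonstrates the bias the hyperbolic approximation incurs when
depletion matters. Degenerate (flat) titrations raise instead of
returning a spurious b; designs without a near-zero point or whose fitted
b lies beyond the titrated range warn.

Synthetic replicates use additive Gaussian noise with σ = 0.003
anisotropy units — the scale of a standard error from triplicate
20-second integrations — on a grid of zero plus 11 log-spaced points up
to 10·b. At this design the median fitted b over 100 replicates is
unbiased well within the uncertainties typical of the assay across the
67–860 nM range.

## NMR shift trajectory and the microscopic Kd

At each titration point i the unfolded-form peaks sit at the
population-weighted average of the free and encounter-complex
environments, so the mean CSP over residues (CSP = √((ΔδN/6)² + ΔδH²))
relative to the zero-RNA reference follows

    y_i = A · b_u(i)/(f_u(i) + b_u(i)),

the saturating amplitude A times the bound fraction of the fast-exchange
pool, with species from the solver at each point's dilution-corrected
totals (initial volume, stock concentration and cumulative added volume;
fixed-totals simulation is available but dilution is the default, since
titrations add aliquots from a stock). K2 and Kd,app come from their own
experiments (slow-exchange volumes; anisotropy) and are held fixed.

Two fit modes: `constrained` fixes Kd1 = Kd,app·(1+K2) and fits A alone
(a linear problem); `unconstrained` floats Kd1 too, initialized at the
constrained value. Both are provided because either reading of a
"fitted curve considering" an externally measured macroscopic constant
is defensible; they agree exactly when the data were generated at the
constrained value.

One estimator detail matters: y_i is a mean of *magnitudes*, so i.i.d.
shift noise adds a positive floor at every non-reference point while the
reference (compared with itself) sits at exactly zero. Fitting A·frac
alone then biases Kd1 upward (about +20% at 5% shift noise). The
unconstrained fit therefore includes a third nuisance parameter, a noise
floor c, with model √((A·frac_i)² + c²) away from the reference — the
expected-magnitude shape for a signal in quadrature with noise. On
noiseless data c collapses to zero and the fit is exact to <1%; at 5%
noise the median recovered Kd1 over 100 replicates is within a few
percent of truth.

The slow-exchange estimator of K2 is vol_folded/vol_unfolded, optionally
corrected for the fact that the "unfolded" peak also carries the free
protein: K2 = (v_f/v_u)·(1 + f_u/b_u), exact when volumes are
proportional to populations. Unfolded-peak volumes are modeled as
proportional to f_u + b_u with a single proportionality constant — no
differential line-broadening correction, since broadening of the
encounter complex is a qualitative observation; a per-species scale can
be emulated through the generator's volume noise if needed.

Secondary chemical shifts are Δδ(CA) + Δδ(C′) versus a bundled
random-coil table (Wishart et al. 1995, GGXGG peptides; any table with
the same columns can be substituted — the combination rule is "sum" by
default with "mean" selectable). Positive combined values indicate
helical propensity, negative extended. HetNOE summaries report mean/sd/n
per user-supplied residue range with a configurable rigidity threshold
(default 0.5); region boundaries are deliberately user-supplied, since
"N-terminal half"/"C-terminal half" are not sharply defined.

## CD titrations and MCR-ALS

A titration of additive chromophores gives a bilinear matrix D = C·S
(points × wavelengths). The decomposition alternates two constrained
least-squares problems: given S solve for C row-wise under
non-negativity (NNLS), given C solve for S unconstrained — CD spectra
are signed, so constraining S would be wrong physics. Iteration stops
when the relative change in lack of fit (100·√(Σ(D−CS)²/ΣD²)) falls
below 1e-8, when the lack of fit itself falls below 1e-8% (exact
reconstruction), or at 500 iterations (then `converged=False` with a
warning). Initial spectra are the most mutually dissimilar measured rows
(greedy residual projection, SIMPLISMA-flavored), with truncated-SVD
initialization as an alternative; a rank-deficient start is perturbed
once, then errors. Each unconstrained concentration profile is scaled to
unit maximum with the scale absorbed into its spectrum.

Bilinear decompositions are unique only up to rotation, and with
non-negativity on C alone the ALS fixed point is generally *not* the
generating solution — it drifts toward a sparse vertex of the feasible
cone (profile correlations ~0.92 on this titration's geometry). The
remedy implemented is the standard one for titration MCR: equality
constraints carrying what the experiment actually knows. `known_spectra`
fixes a component's spectrum to a measured reference — the free-protein
spectrum *is* the first titration point, and the free-titrant spectrum
is measurable separately; `known_profiles` fixes a concentration profile
the experimenter controls — the accumulating titrant. With these, ground
truth profiles are recovered exactly on noiseless data and to r > 0.99
at 1% noise. An optional closure constraint (components summing to a
constant, e.g. the two protein forms) is also available; it is a
projection rather than a least-squares step, so the strict monotone
decrease of the lack of fit is guaranteed only without it. Component
identification (Pearson correlation against a reference library,
one-to-one Hungarian assignment, unassigned below 0.8) is best done on
the *unconstrained* run, where all component shapes are free; the
constrained run then supplies the quantitative profiles.

Rank estimation counts singular values above a noise threshold. With a
supplied per-element noise σ (blank or replicate scans) the threshold is
1.5·σ(√n+√m), 1.5 times the edge of the pure-noise singular-value
distribution. Blind, the floor is 5× the median of the smaller half of
the singular spectrum — deliberately conservative for matrices with few
rows, where the trailing singular values are a poor noise sample; the
blind rule can miss a weak third component that the noise-informed rule
resolves.

## Synthetic data: what it emulates, what it does not

The generators reproduce the statistical structure each analysis
assumes, with all randomness under one integer seed and ground truth
returned alongside every dataset.

- **Anisotropy**: exact hyperbola plus Gaussian noise (σ = 0.003 a.u.);
  truth (r0=0.05, a=0.10, b per scenario).
- **NMR titration**: 200 µM protein, 400 µM RNA stock, 0.25-equivalent
  steps to 2.0 equivalents, dilution-corrected; 80 residues with
  bound-state shift offsets drawn once from a log-normal magnitude
  distribution (median ΔδH 0.03 ppm, ΔδN six times larger, random
  signs), multiplied ×3 inside the binding-interface segments (the
  strand-2/3 and helix-2 regions of the folded topology) — matching the
  qualitative heterogeneity of real CSP profiles without inventing
  per-residue values. Shift noise defaults to 5% of the largest true
  CSP (σN = 6·σH); volumes get 2% multiplicative noise.
- **CD**: 8 µM protein, 0.25-equivalent steps to 2.0 equivalents,
  200–300 nm at 1 nm; three parametric Gaussian basis spectra — a
  single negative disordered-coil band at 200 nm; a folded α/β band
  pair at 208/222 nm plus the positive π→π* exciton band at 193 nm
  whose tail enters the grid; an A-form RNA pair (−210 nm, +265 nm).
  Profiles are the three-state populations (unfolded = f_u+b_u,
  folded = b_f) and total RNA. The schedule extends past equivalence
  deliberately: before saturation the three profiles are nearly affine
  in added RNA (the matrix is numerically rank-2), and only
  post-equivalence points make the third component detectable at 1%
  noise. Noise is Gaussian, σ expressed as a fraction of max|D|.
- **Free-state disorder tables**: random-coil CA/C′ baselines plus
  regional offsets (helical +1.5/+1.0 ppm, strand −0.8/−0.6 ppm in the
  C-terminal half) and a two-level hetNOE profile (0.1 N-half, 0.4
  C-half).

Not emulated: lineshapes and differential broadening, peak overlap and
assignment errors, baseline drift in CD, ionic-strength effects, multi-
site binding on long RNAs. Passing recovery tests therefore validate the
estimators under the stated statistical model — they bound estimator
bias and variance, not robustness to these unmodeled systematics.

## Problem sizes and numerical choices

Replicate studies use 100 seeded replicates (anisotropy and NMR recovery),
1000 random draws for the species-solver oracle checks, 80-residue
proteins, 9-point titrations and 101-wavelength spectra — sizes chosen so
the full suite and the acceptance script each run in seconds on one core
while keeping Monte-Carlo error in a median far below the tolerances
tested. Ties and degeneracies: zero totals short-circuit the quadratic;
tiny negative concentrations from rounding clamp to zero; the anisotropy
fit rejects flat data (span < 1e-12) rather than returning an unbounded b;
empty hetNOE regions flag rather than raise.

## Known limitations

- The three-state treatment is thermodynamic; it cannot address exchange
  rates, and the fast/slow regime assignment must hold for the fit to be
  meaningful.
- The unconstrained shift-trajectory fit estimates Kd1 only as well as
  the titration design constrains it: designs saturating the unfolded
  pool at every point are flagged but cannot be rescued.
- MCR-ALS without equality constraints remains rotationally ambiguous;
  reported profiles from unconstrained runs are qualitative.
- The random-coil reference choice shifts secondary-shift baselines by
  up to a few tenths of a ppm; conclusions about weak propensities
  should be checked against more than one table.
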