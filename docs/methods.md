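# Methods

This note records the models barrelkit fits, the conventions and defaults it
adopts where the underlying experiments leave a choice open, what the
synthetic-data generators do and do not emulate, and the package's known
limitations.

## Units and constants

Concentrations in molar (mM accepted at I/O with a declared column name),
temperatures stored in kelvin (°C converted on read), voltages in mV,
conductances in nS, coordinates in Å. Folding free energies use
R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹; gating energies use F = 96 485 C/mol and are
reported in kJ/mol (nFV₀ = n·96485·|V₀|/10⁶ with V₀ in mV). Conversions are
always explicit in the code; nothing rescales silently.

## Equilibrium denaturation (linear extrapolation method)

Model: folded fraction f_F(D) = 1/(1+exp(−(ΔG⁰−m·D)/RT)) between two
sloping linear baselines. Six parameters are floated by default (ΔG⁰ or C_m,
m, two baseline intercepts, two slopes); baseline slopes can be frozen at
their initial estimates. The fit allows either sign of transition amplitude
— whether the folded state is the brighter one is not assumed.

Choices that were genuinely open:

* **Fixed vs floated baselines** — floated is the default; the alternative
  is available because sparse baselines can otherwise leak error into m.
* **Parametrization** — (ΔG⁰, m) and (C_m, m) are both supported and give
  identical predicted curves; C_m is always reported as ΔG⁰/m.
* **Initialisation** — baselines from the outer 15% of points by D; the
  transition midpoint from where the baseline-normalized signal crosses ½
  (a local-derivative maximum was tried first and discarded: at dense
  sampling the derivative of noisy data peaks anywhere); m from the
  apparent 10–90% transition width via m ≈ ln(81)·RT/width.
* **Optimizer** — Levenberg-Marquardt followed by a trust-region polish
  with a 3-point Jacobian, so both parametrizations land on the same
  optimum to ~10⁻¹⁰ rather than ~10⁻⁶ (forward-difference gradients stop
  earlier than the reparametrization-identity check tolerates).
* **Degenerate inputs** — a constant or transition-free signal raises a fit
  failure (the fitted transition amplitude is compared against 3× the RMS
  residual); m collapsing onto its positivity bound flags non-convergence.
* **Aggregation at low denaturant** on long incubation is handled only by
  an optional point-exclusion mask, never modelled.

Hysteresis between arms is reported as signed folding-minus-unfolding
differences (ΔC_m, ΔΔG⁰, Δm) and flagged when |ΔC_m| > 0.1 M (configurable).
Temperature defaults to 298.15 K.

## Thermal melts

Model: f_U(T) = 1/(1+exp(ΔG(T)/RT)) with ΔG(T) = ΔH_app·(1−T/T_m) and
ΔC_p = 0, between sloping linear baselines in T. These barrels aggregate on
thermal unfolding, so the transition is irreversible and both T_m and
ΔH_app are *apparent*; ΔH_app doubles as a transition-width (cooperativity)
readout — larger ΔH_app, narrower transition, earlier-defined onset. The
two-parameter transition is the minimal defensible model; estimating ΔC_p
from an irreversible melt would be decoration.

T_m-start is defined as the temperature where f_U first reaches 5%
(threshold configurable in (0, 0.5]; 0.5 returns T_m by definition), solved
by bisection to 10⁻³ K. The 5% convention is exactly that — a convention —
and is recorded in every fit result.

## Kinetics and chevrons

Anisotropy traces are normalised to folded fraction with the measured
folded/unfolded anisotropy endpoints; noisy values outside [0,1] are kept
(clipping would bias rate fits). Exponential fits use
offset + Σ Aᵢ·exp(−kᵢ·t) with the time origin at the first retained point
and amplitudes extrapolated back to t = 0, which makes the fitted rates
exactly independent of how much dead time was discarded. Phases are
reported fast→slow; two-phase fits with rate ratio < 2 and traces shorter
than ~3/k warn. An optional F-test (α = 0.01) compares single vs double
exponentials; the default is user-specified phase count because real
datasets here switch regime with denaturant.

Chevron arms are fit unweighted in ln-rate space, folding and unfolding
separately, over configurable linear-zone windows (defaults 0.8–1.68 M and
1.72–3.0 M — the acquisition ranges typical of manual-mix refolding and
stopped-flow unfolding in this system). Rollover is handled only by the
optional quadratic term m_U1-kin·D² on the unfolding arm; the term sits
outside the RT scaling, so its units are M⁻². No automated rollover
exclusion is attempted.

ΔG⁰_kin is computed verbatim as −RT·ln(k_f^H₂O/k_u^H₂O). For a protein
whose folding is faster than its unfolding this is *negative*; the sign
convention travels with the fit result rather than being silently flipped.
The rate-selection rule used to build a chevron from multi-phase fits
(dominant amplitude, fastest, slowest) is explicit and retained in the
dataset's provenance.

## Voltage gating

G_max is the mean conductance inside a ±10 mV reference window where the
channels sit open; each branch's G/G_max series is fit to

    G/G_max(V) = g_min + (1−g_min)/(1+exp(nF(|V|−V₀)/RT))

with a residual closed-state fraction g_min — VDAC channels never close
completely, so forcing g_min = 0 would bias n. Branches are fit
independently (gating is asymmetric in sign). The fit operates on G/G_max
directly; at zero noise a logit-transform fit gives identical parameters.

Insertion-step classification uses a two-component 1-D Gaussian mixture
with deterministic 25%/75%-quantile initial means and symmetric initial
weights/variances, so repeated runs classify identically and match the
exhaustive minimum-within-class-variance partition on separable data.

## Fluorescence probes

Inner-filter correction is the standard F·10^((A_ex+A_em)/2). Stern-Volmer
fits are ordinary least squares of F₀/F (or τ₀/τ) vs [Q] with a free
intercept (expected 1; deviations are diagnostic, not hidden). TCSPC decays
are tail-fit from the count peak + 0.2 ns (no IRF deconvolution) with
residuals weighted 1/√max(counts,1), the Gaussian approximation to Poisson
statistics. ⟨τ⟩ defaults to amplitude weighting Σαᵢτᵢ/Σαᵢ;
intensity weighting Σαᵢτᵢ²/Σαᵢτᵢ is one switch away, because conventions
differ between labs and the two disagree for multi-component decays.

## Hydropathy

Three embedded 20-residue scales: Kyte-Doolittle hydropathy, the
Wimley-White water→POPC-interface transfer free energies (charged side
chains for D/E/K/R, neutral His), and the Zhao-London transmembrane
tendency. Window means (default window 9) are assigned to the window
*centre* in 1-based residue coordinates, so profile positions line up with
residue numbers of interest (e.g. interfacial tryptophans at 75/86/160/221
in VDAC-2). Min-max normalisation is the default for overlaying the three
scales on one axis. Checksum tests pin each table against transcription
drift.

## Trajectory metrics

Kabsch superposition is computed by SVD with the determinant correction
(always a proper rotation); collinear selections are rejected rather than
silently resolved. R_g is mass-weighted by default using standard atomic
masses guessed from atom names. RMSF is taken about the time-mean position
after optional per-frame superposition onto the first frame; the residue
value is the mean over its atoms and exports as B = (8π²/3)·RMSF².

Vicinity counting is per-*molecule* (any-atom criterion, closed ≤ cutoff
boundary, default 5 Å, heavy atoms only by default): a detergent or water
molecule with one atom in range counts once. The minimum-image convention
is applied for orthorhombic boxes only. Selections (residue ranges,
atom-name sets, molecule classes, exclusions such as a mobile N-terminal
helix) are expressed through `SelectionSpec`, not hard-coded.

Supported interchange is PDB (topology + first frame) and a multi-frame XYZ
dialect whose comment line carries the box edges; engine-native trajectory
formats are out of scope. Molecule classes come from residue names via a
configurable map (DDM→detergent, HOH/SOL/TIP3→water, NA/CL→ion, else
protein).

## Synthetic data

Each generator forward-simulates exactly the model its stage fits, so
generate(noise = 0) → fit recovers truth to solver tolerance; that identity
is the core of the test suite. Noise is magnitude × a unit Gaussian draw
fixed by the seed (Poisson for photon decays), so at constant seed the
realized noise — and therefore every fitted standard error — scales
monotonically with the magnitude.

Defaults sit in the regimes of a β-barrel refolded in DDM micelles:
C_m within the 1.5–2.5 M GdnHCl transition zone, anisotropy folding rates
~5×10⁻³ s⁻¹ with the first 25 s discarded (manual-mixing dead time),
chevron slopes ±1.5 kcal·mol⁻¹·M⁻¹, gating parameters n ≈ 2–3 and
V₀ ≈ 20–29 mV with g_min = 0.4, insertion populations at 2.43/3.98 nS with
6/12 events, K_SV = 5 M⁻¹, lifetimes averaging ~2.8 ns. Two sampling
choices deserve a note:

* **Melt sampling** is a 0.2 K data pitch (456 points over 4–95 °C), the
  data density of a continuous CD T-scan; at a 1 K pitch ΔH_app is
  intrinsically determined only to ~4% at 2% noise, too coarse for the
  recovery the fits are tested against.
* **Titration design** places half the 24 points uniformly across the
  range and half within one 10–90% width of C_m — the way an m-value
  titration is actually planned; uniform spacing starves the transition of
  points at high m and the baselines at low C_m.

The toy micelle system is a geometric construction, not a simulation: a
24-residue one-atom-per-residue cage, an 80-molecule three-atom detergent
belt around its mid-plane, water slabs above and below, and ions in the
outer shell, in a 110.4 Å cubic box with 0.15 Å per-frame jitter. One
detergent molecule is pinned beside the buried probe residue and one water
beside the surface probe, so the buried position has detergent but no water
within 5 Å in every frame and the surface position the inverse — the
qualitative buried/exposed solvation contrast, by construction. It
exercises the counting, superposition and selection machinery; it says
nothing about real detergent packing, diffusion, or protein flexibility,
and passing its tests validates the *kernels*, not any MD result.

## Known limitations

* Two-state models throughout: no three-state equilibrium fits, no explicit
  kinetic intermediates (rollover is absorbed, not interpreted).
* Irreversible melts mean all thermal parameters are apparent; ΔC_p is not
  estimated.
* No IRF deconvolution in lifetime fitting; sub-200 ps components are
  outside scope.
* No modified (accessible-fraction) Stern-Volmer analysis.
* Trajectory support is post-analysis only — no engine formats, no SASA,
  no hydrogen-bond networks; minimum-image is orthorhombic-only.
* The simulators emulate measurement structure and noise scale, not
  instrument artifacts (photobleaching, drift) beyond what a mask or
  baseline can absorb.
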