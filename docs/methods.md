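# Methods

This note documents the models, the fitting and uncertainty procedures,
the synthetic-data study conditions, numerical choices, and known
limitations of `acifit`.

## C3 model (FvCB with TPU)

Net assimilation at chloroplast CO2 mole fraction Cc (µmol mol⁻¹) is

    An = (1 − Γ*/Cc) · min(Wc, Wj, Wp) − RL

with carboxylation rates

    Wc = Vcmax · Cc / (Cc + Kc·(1 + O/Ko))          Rubisco
    Wj = J · Cc / (4·Cc + Γ*·cj)                    RuBP regeneration
    Wp = 3·Tp · Cc / (Cc − Γ*·cp)                   TPU

All CO2/O2 quantities are mole fractions (µmol mol⁻¹; Ko and O in
mmol mol⁻¹); no partial-pressure layer is used. The glycolate-export
coefficients are assembled in one function (`tpu_coefficients`):

    cj = 8·(1 + 2·αG + αS + αT)
    cp = 1 + 3·αold + 3·αG + 6·αS + 8·αT

so that all-zero exports give the classic (cj, cp) = (8, 1) and the
single-parameter formulation gives cp = 1 + 3·αold. At most one
formulation (αold, or αG/αS/αT) may be active. The coefficients of the
three-parameter formulation live in that single function precisely so
they can be revised without touching model logic; everything the tests
pin down (the α = 0 reduction, the αold form, monotonicity of the
threshold) is independent of that choice.

**TPU threshold.** Wp is positive only above Cc = Γ*·cp; below it Wp is
represented as +∞ so the min() can never select TPU. With αold = 1 the
threshold is 4·Γ*.

**Limiting-process identification.** The limiting process is always the
argmin of the *carboxylation* rates, with tie priority
rubisco > rubp_regen > tpu. Selecting by minimal assimilation instead
fails below the compensation point, where the (1 − Γ*/Cc) prefactor is
negative and the smallest An corresponds to the *largest* W; the
carboxylation rule is correct everywhere and keeps An continuous across
crossovers.

**Ci basis.** With gmc = ∞ the model is evaluated at Cc = Ci and the
fitted parameters are "apparent". With finite gmc, each process obeys
An = k1·(Cc − Γ*)/(k2·Cc + k3) − RL together with Cc = Ci − An/gmc;
eliminating Cc gives one quadratic per process whose lower root is the
physical solution (the other root diverges as gmc → ∞). The
self-consistent branch is then chosen by evaluating the carboxylation
rule at each candidate's own Cc; a brute-force root-finder on the fixed
point An ↔ Cc agrees to better than 1e-12 on random draws.

## Variable J

Per point, Jactual = (An + RL)(4·Cc + 8·Γ*)/(Cc − Γ*) holds regardless
of the limiting process. Setting Jactual equal to the fluorescence
estimate JF = τ·Qin·φPSII and eliminating Cc yields

    Cc  = Γ*·(JF + 8·(An + RL)) / (JF − 4·(An + RL))
    gmc = An / (Ci − Cc)

τ is a single lumped proportionality (absorptance × PSII partitioning ×
everything else); no attempt is made to factor it. gmc is an effective
conductance and may legitimately be negative when An < 0 at low CO2.
Denominators within 1e-9 (relative to JF) of zero raise a singularity
error; during fitting such points are penalized rather than raised.

**Structural non-identifiability of RL.** When τ and the FvCB
parameters are fit jointly, RL cannot be identified from the curve, even
noise-free. Writing u = An + RL, the reconstructed chloroplast CO2
satisfies (JF − 4u)·(Cc + Km) = Γ*(JF + 8u) + Km(JF − 4u), whose
derivative with respect to u, 8Γ* − 4Km, is the same constant at every
point; an RL shift therefore perturbs every Rubisco-branch residual
equation by a common constant that is absorbed exactly by Vcmax (the
same holds for Tp on the TPU branch, and RuBP-regeneration points are
insensitive to RL altogether because JF = J there). The model surface
passes through (Cc, An) = (Γ*, −RL) by construction for *any* RL. The
default fit list still includes RL for API compatibility, but validation
studies fix RL at its known value — in practice RL should be measured
independently or fixed when using Variable J. Note that the
one-at-a-time interval scan does not detect this degeneracy (it lies
along a correlated direction), so RL's reported interval is
deceptively narrow.

## C4 model

Bundle-sheath CO2 and O2 balances

    Cs = Cm + (Vp − An − RLm)/gbs,   Os = αPSII·An/(0.047·gbs) + Om

are substituted into the bundle-sheath Rubisco rate (enzyme-limited
branch, with Vp = min(Cm·Vpmax/(Cm + Kp), Vpr) and RLm = fRLm·RL) or the
electron-transport rate (light-limited branch, with mesophyll PEP
regeneration x·J/2 and bundle-sheath transport (1 − x)·J, x = 0.4).
Each yields a quadratic in An; the smaller root is taken, and both
roots were derived symbolically from exactly these defining relations
(brute-force root-finders on the same relations agree to 1e-14).
An = min(Ac, Aj). The high-Ci `assumption` option reflects that the
high-Ci processes are rarely distinguishable: `"rubisco"` (default for
fitting) disables the light branch; `"light"` makes Rubisco non-binding
by evaluating the enzyme branch at Vcmax = 1000 µmol m⁻² s⁻¹, which
produces the sharp Apc → Aj transition of the light-limited analysis.
Defaults fRLm = 0.5 and gbs = 0.003 mol m⁻² s⁻¹ are configuration, held
fixed unless explicitly fit.

The empirical non-rectangular hyperbola solves
θ·A² − (s·Ci + Vmax)·A + s·Ci·Vmax = 0 for gross assimilation (smaller
root; θ = 0 handled as the rectangular limit), An = A − RL, and
Amax = Vmax − RL. `low_ci_subset` (default threshold 60 µmol mol⁻¹)
implements the standard low-Ci rule for estimating Vpmax.

## Fitting and uncertainty

Gaussian iid noise on An gives NLL = N·ln(σ√2π) + SSR/(2σ²); its argmin
over parameters is σ-independent and equals least squares. Stages:

1. **Global search** at σ = 1: differential evolution over box bounds
   (population 10× the number of fitted parameters, ≤ 500 generations,
   tolerance 1e-8, Sobol' initialization, seeded and vectorized),
   followed by a bounded Nelder–Mead polish (on by default). Parameter
   vectors where the model is undefined receive a large penalty
   (1e10) instead of raising.
2. **σ estimate**: the RMSE of the best fit (floored at 1e-6 so
   noise-free fits stay finite). Note this divides by N, not N − k.
3. **Intervals**: each fitted parameter is scanned one at a time
   (others held at their best-fit values) for the contiguous region
   where L/Lmax ≥ 0.147; endpoints are bisected to 1e-6 relative. The
   0.147 cutoff equals exp(−χ²₀.₉₅(1)/2) to within rounding, so a
   Gaussian-shaped likelihood yields ≈95% intervals (the package's
   calibration check measures 94.96%). The search extends to the
   optimizer bound ± 9× the bound range (≈10× the upper bound for
   zero-lower-bounded rates); if the relative likelihood is still above
   threshold there, that side is infinite. An infinite upper limit
   marks the parameter unreliable and its estimate is reported NA
   (switchable via `FitConfig.na_policy`).
4. **Profiled intervals** (`FitConfig.profile=True`, off by default):
   the scan re-optimizes the remaining parameters at each point,
   walking outward from the one-at-a-time edges (the profiled region
   always contains the plain one) with doubling steps plus bisection.

AIC = 2k + 2·NLL at the best fit with σ = RMSE, k counting the fitted
parameters plus σ; it is meant only for comparisons within this
package. α parameters are deliberately not box-constrained to [0, 1]
by default: constraining them can bias fits, and values above 1 are
treated as descriptive measures of reverse-sensitivity strength.

## Synthetic data and study conditions

The generator emulates the measurement protocol: reference CO2 steps
through a set-point schedule (built-ins: the 19-point C3 protocol
400…10, 400, 400, (500), 600…1500; a 16-point soybean-style protocol;
a 13-point maize/sorghum-style protocol), Ci tracks the set-point with
a stomatal drawdown factor (default 0.7), leaf temperature is constant
(default 27 °C; kinetics scaled by the temperature presets), and An is
the forward model plus iid Gaussian noise. For Variable-J curves,
φPSII is generated by inverting JF = τ·Qin·φPSII from the Jactual
relation at the true gmc, so the inversion round-trip is exact on
noise-free points. Everything is deterministic per (seed, replicate).

Validation studies use, chosen once as typical of vigorous leaves:

- C3, all processes binding: Vcmax = 150, J = 200, Tp = 12, RL = 1.5
  (µmol m⁻² s⁻¹), αold = 0.5. Along the 17 retained points the low-CO2
  ramp is Rubisco-limited, the shoulder RuBP-regeneration-limited, and
  the four highest set-points TPU-limited with visible reverse
  sensitivity.
- C3 with J non-binding: as above but J = 400, which removes all
  RuBP-regeneration-limited points.
- C4: Vcmax = 65, Vpmax = 140, RL = 1.8 at 31 °C.
- Variable J: Vcmax = 140, J = 210, Tp = 13, RL = 1.2, αold = 0.4,
  gmc = 0.4 mol m⁻² s⁻¹, τ = 0.426, Qin = 2000.
- Noise σ = 0.5 µmol m⁻² s⁻¹; 50 replicates for the false-positive
  study and 200 for the coverage study.

What the generator does *not* emulate: instrument drift, leaks,
non-Gaussian noise, φPSII measurement error by default, or
temperature variation within a curve. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's
own assumptions, not robustness to real-world artifacts.

## Known limitations

- **One-at-a-time interval coverage.** The default interval scan holds
  the other parameters at their best-fit values. When estimator errors
  are strongly correlated, such intervals are systematically narrower
  than the marginal sampling spread (width ratio √(1 − R²)), and the
  σ = RMSE rule shrinks them by a further √((N − k)/N). Under the C3
  study conditions the Tp–αold error correlation is ≈ −0.95, and
  measured per-parameter coverage over 200 noisy curves is ≈0.28 (αold),
  ≈0.31 (Tp), ≈0.72 (RL), ≈0.80 (J), ≈0.84 (Vcmax) — matching the
  linear-Gaussian prediction, i.e. a property of the procedure, not a
  code defect. Profiled intervals (`profile=True`) restore width for
  correlated parameters at extra cost and are recommended when
  coverage matters.
- **False positives near the identifiability boundary.** With J
  non-binding, roughly one noisy curve in ten is still fit marginally
  better by a weak RuBP-regeneration limitation, yielding a finite
  (and then misleadingly tight) J interval; the suppression rate is
  ≈88–92% depending on the noise realization.
- **RL in Variable-J fits** is structurally unidentifiable (see above).
- Temperature presets are editable data transcribed from standard
  literature sources; their numerical values are configuration, not
  asserted behavior.
- The C4 light-limited branch contains no PEP-carboxylase
  co-limitation (sharp Apc → Aj transition), and bundle-sheath O2
  dynamics enter only through the αPSII term.
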