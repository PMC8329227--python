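# Methods

`peritonsim` couples a one-dimensional distributed model of water and glucose
transport through the peritoneal tissue to a lumped peritoneal-cavity
compartment, schedules automated peritoneal dialysis (APD) cycles over
multiple treatment days, and analyses cycle-by-cycle ultrafiltration (UF)
records of the kind a remote-patient-monitoring (RPM) cycler produces.  This
note documents the model, its numerical treatment, the parameter choices, the
synthetic-data generator, and the known limitations.

Units throughout: cm, mL, min, mmHg, mmol/mL.

## Tissue model

The peritoneal interstitium is a deformable porous layer of depth
L = 1 cm (x = 0 at the peritoneal surface, zero-flux at x = L), with an
effective exchange area A in contact with dialysate.  Two fields are evolved:

* fractional tissue hydration θ(x,t) (interstitial fluid volume per tissue
  volume), with interstitial hydrostatic pressure P related to θ by an
  invertible compliance law;
* interstitial glucose concentration C(x,t) (per mL interstitial fluid).

Conservation laws:

    ∂θ/∂t      = −∂j_v/∂x + q_v − q_l
    ∂(θC)/∂t   = −∂j_s/∂x + q_s − q_l·C

with Darcy flow carrying a crystalloid osmotic term (van 't Hoff, reflection
coefficient σ_T of the tissue matrix),

    j_v = −K(θ) ( ∂P/∂x − σ_T·RT·∂C/∂x ),

and diffusive plus convective (sieved, upwinded) solute flux,

    j_s = −θ·D(θ)·∂C/∂x + (1 − σ_T)·C_upwind·j_v.

### Constitutive laws

**Compliance θ(P).**  Logistic between θ_min = 0.17 (collapsed interstitium)
and θ_max = 0.40 (maximal swelling), scale 2.26 mmHg, midpoint 6.0 mmHg.
This places the physiological hydration of 18% at the dry-tissue equilibrium
pressure P_eq ≈ −1.0 mmHg and maps a typical 2-L dwell's intraperitoneal
pressure (~9.5 mmHg) to ~36% — the hydration swing the superficial tissue
undergoes between a dry day and a dwell.  The logistic form is invertible in
closed form, which the solver exploits (the PDE is advanced in θ; P = P(θ)).

**Transport coefficients.**  K(θ) = K0·exp(k_K(θ − θ_phys)) and
D(θ) = D0·exp(k_D(θ − θ_phys)): swollen tissue conducts water and solutes
better.  The sensitivity k_K = 5 is deliberately moderate: with a much
steeper law the freshly hydrated surface layer discharges back into the
cavity during the few minutes of every drain, destroying the cycle-to-cycle
hydration memory that produces the first-cycle UF deficit.

**Capillary exchange.**  A lumped Starling wall distributed through the
tissue: per mL of tissue

    q_v = v(C)·LpS·[ (P_b − P) − ρ_onc·Π_b + σ_g·RT·(C − C_b) ]
    q_s = v(C)·PS·(C_b − C) + (1 − σ_g)·½(C + C_b)·q_v

where v(C) = 1 + g·ΔC/(h + ΔC), ΔC = max(C − C_b, 0), is a Hill-type
vasodilation multiplier (capillary recruitment by local hyperglycemia,
maximum 1 + g).  The oncotic weighting ρ_onc is derived, not set: it is
fixed so that at the dry equilibrium (θ_phys, equilibrium glucose) capillary
filtration exactly balances baseline lymphatic uptake, making the
physiological state a true fixed point.  σ_g = 0.185 is an *effective*
osmotic reflection coefficient of the lumped wall; it is larger than the
small-pore value of classical three-pore accounting because it folds in the
water-exclusive (aquaporin) pathway, whose reflection coefficient is 1, into
a single conductance.  An optional three-pore split decomposes σ_g into a
conductance-weighted mean over pore populations.

**Lymphatics.**  q_l(P) = L0 + λ·clip(P − P_eq − P_onset, 0, P_sat): baseline
uptake L0, an edema-guard rise with interstitial pressure above a small
onset (0.6 mmHg), and saturation once the elevation exceeds 4 mmHg
(lymphatic pumping has finite capacity).  The saturation is load-bearing: a
purely linear law cannot simultaneously (a) return the tissue to
physiological hydration over the ~15-h dry day and (b) leave night-dwell UF
intact — a linear λ large enough for (a) removes ~1.5 mL/min during every
dwell, erasing the UF plateau.  With saturation, the night dwells (pressure
elevation ≫ 4 mmHg everywhere in the wet layer) see a fixed, modest
lymphatic load, while the mildly pressurised daytime tissue sits on the
steep part of the curve and discharges.

## Cavity compartment and cycle mechanics

The cavity holds volume V_ip at glucose C_ip.  Intraperitoneal pressure is
linear above the residual volume (0.95 mmHg + 0.0045 mmHg/mL) — about
9.5 mmHg for a 2-L supine fill — and decays linearly to zero gauge as the
cavity empties below residual.  The tissue boundary condition at x = 0 is
the cavity pressure and glucose; the cavity obeys the matching balances
dV_ip/dt = pump − A·j_v(0) and d(V_ip·C_ip)/dt = pump·C − A·j_s(0), so cavity
+ tissue + pump/capillary/lymph ledgers close exactly.

A cycle is fill (200 mL/min) → dwell (remaining cycle time) → drain
(350 mL/min, stopping at the residual volume — the model's reading of a
cycler that stops when flow falls off).  The residual volume (250 mL) is
constant per patient.  A session is an initial drain followed by n identical
cycles; a treatment day appends the daytime phase: on a dry day (DD) a
100-mL comfort fill rests in the cavity all day; on a wet day (WD) a full
daytime dwell.  The daytime exchange's net UF is measured, as the cycler
measures it, at the next session's initial drain.

The reference prescription is six 90-min cycles of 2 L glucose 1.36%
(anhydrous-glucose convention: 1.36 g/100 mL = 0.0755 mmol/mL), DD regimen.
The WD reference uses a 2.5-L glucose 2.27% daytime dwell: icodextrin, which
clinically maintains the daytime dwell volume, is outside the model's scope,
and a smaller or weaker glucose day dwell deflates over 15 h, leaving the
tissue partially dehydrated and re-introducing a spurious first-cycle
deficit.  The fuller, more tonic glucose dwell emulates the volume-holding
role of the clinical day exchange; its own (strongly negative) simulated net
UF is not a meaningful clinical quantity.

## Numerics

Finite-volume discretisation on a geometrically graded mesh (default 50
cells, ratio 1.05, first cell ≈ 48 µm) — gradients of θ and C live in the
first ~0.2 cm.  Explicit conservative Euler stepping with an adaptive step
size at 40% of the nonlinear stability bound dt ≤ min(Δx²/2(K·dP/dθ + D));
a step that would push θ out of (θ_min, θ_max) is retried at half size,
never clamped.  Upwinding keeps C non-negative.  Because the update is in
flux form, discrete conservation holds to rounding error; every step emits
an exact water/glucose ledger (boundary, capillary, lymph) that the tests
audit at 1e-9 per step and 1e-7 over a full day.  Refining the mesh by
splitting every cell (50 → 100, grading ratio √1.05) changes per-cycle net
UF by ≲ 0.3%, and halving the step-size cap changes the end-of-dwell θ
profile by < 0.1%.

Per-cycle tissue snapshots are taken at the end of each dwell, before the
drain: they represent the hydration state the cycle established (the
few-minute drain partially deflates only the first ~0.05 cm).  Tissue water
changes at cycle boundaries are recorded separately for mass accounting.

## Parameters

`data/parameters_v1.yaml` is the versioned default set; every output embeds
its version and a config hash.  Geometry and physiology anchors (θ marks of
18%/36%/40%, plasma glucose 5 mmol/L, capillary pressure 15 mmHg, plasma
colloid osmotic pressure 22 mmHg, RT = 19 343 mmHg per mmol/mL at 37 °C,
residual volume 250 mL) are standard values.  The free transport magnitudes
(K0, k_K, D0, LpS, σ_g, PS, vasodilation gain/half-saturation, lymphatic
L0/λ/onset/saturation, effective area A) were calibrated jointly so that the
reference DD prescription, run to its periodic state, reproduces the target
cycle-by-cycle pattern: session UF ≈ 440 mL; C1 ≈ −20 mL; C2 ≈ 76 mL; C3+
plateau ≈ 95 ± 3 mL; first-cycle deficit ≈ 111 mL; tissue water uptake
≈ 213 mL during C1 and ≈ 268 mL during C1+C2; daytime exchange ≈ −100 mL;
near-cavity hydration 19% → 36% with the elevation confined to < 0.2 cm.
All magnitudes sit in the physiologically plausible ranges of the
distributed-modelling literature (tissue conductivity ~1e-6
cm²·min⁻¹·mmHg⁻¹, glucose diffusivity ~2e-4 cm²/min, whole-peritoneum
LpS·A ≈ 0.3 mL·min⁻¹·mmHg⁻¹, baseline lymph ≈ 0.6 mL/min).

Problem sizes used by the shipped analyses and checks — 50 cells, 3 simulated
days, 16-day cohorts of 6 + 8 patients — are the package's working defaults;
they reach the periodic state (day 2 and day 3 agree to < 2 mL per cycle)
and the statistical structure of interest.

## The mechanism, in brief

After a dry day the superficial tissue is at ~18–19% hydration and
interstitial pressure ≈ 0; infusing 2 L of dialysate raises intraperitoneal
pressure to ~9.5 mmHg.  During the first cycle the pressure gradient drives
~200 mL of cavity fluid into the first ~0.2 cm of tissue (θ → ~36% at the
surface), and this uptake, not a transport failure, consumes the cycle's
osmotic UF: net UF is negative.  The hydrated layer persists through the
brief drains; by cycle 3 the layer is equilibrated and each cycle's UF is
what the glucose gradient earns (~95 mL).  Overnight-accumulated tissue
water then leaves during the daytime via lymphatics, capillary reabsorption
and slow seepage back into the near-empty cavity, re-establishing the dry
state — which is why the pattern repeats every day in DD but is absent in
WD, where the daytime dwell keeps the layer hydrated (first-cycle deficit
7 mL vs 111 mL with identical night prescriptions).

## Synthetic RPM generator

The statistical generator emulates the *record structure* of a monitored
cohort, not the physiology: per-cycle net UF = cycle-class mean (C1/C2/C3+,
regimen-specific) + patient effect (SD 60 mL) + patient-by-class effect
(SD 45 mL) + day-to-day noise (SD 90 mL); drained = infused + UF with a
constant per-patient residual volume (zero carryover noise).  Class means
default to the observed group medians (DD: −61/170/213 mL; WD: 81/81/115
mL); cycle counts 4–7 (median 5), fill volumes 1600–2300 mL, day-exchange
means −96 mL (DD) / +254 mL (WD), per-patient diuresis around 1150/600 mL.
The observed data report medians and quartiles only, so the variance
components are calibration choices; the patient-by-class component is what
lets the wet-day arm carry a small average C3+ excess yet remain
non-significant under a subject-level repeated-measures analysis, as
observed.  A mechanistic variant replicates the simulator's per-cycle
pattern with observation noise.  Everything is driven by one seeded
generator; a fixed seed reproduces the CSV byte-for-byte.

What passing tests on these data do **not** show: the generator has no
tonicity differences between patients, no adherence gaps or alarms, no
residual-volume drift, and Gaussian noise rather than the heavy-tailed
day-to-day excursions real cyclers record; conclusions about real cohorts
require real records.

## Statistical analysis

Per patient and day, C1 and C2 are contrasted with C3+ (mean of cycles 3 up
to at most 7); days with fewer than three night cycles are excluded with a
warning.  Summaries are two-level: per-patient medians over days first, then
group median [Q1, Q3].  The omnibus cycle-class comparison is a
repeated-measures ANOVA with patients as subjects on per-patient class means
(between-day replication collapsed); post-hoc contrasts are Tukey HSD on the
repeated-measures error mean square (studentized-range distribution).
Drain-volume ratios VdrR_i = drained_Ci / mean(drained C3+) are computed on
drained volumes — with a constant infused volume, (1800 − 61)/(1800 + 213)
= 0.864, consistent with the observed dry-day median of 0.87 — with a config
switch for the literal net-UF ratio.  Ratios are tested against unity with a
one-sided (less) Wilcoxon signed-rank test on all patient-days, paired
VdrR1-vs-VdrR2 with a Wilcoxon on per-patient medians, and regimens are
compared with Mann-Whitney U; exact small-sample null distributions are used
for n ≤ 25, validated in the tests against exhaustive enumeration for
n ≤ 7.  Record exclusions (e.g. one abnormal day-exchange value) are always
an explicit, logged list, never silent.  The pipeline is invariant to input
record order.

## Known limitations

* One-dimensional tissue; no blood-flow limitation, protein/colloid
  transport, or solutes beyond glucose (sodium and urea assumed
  equilibrated).  The interstitial colloid term is folded into the
  calibrated Starling offset.
* Icodextrin is not modelled; the WD day dwell is a glucose stand-in chosen
  for its volume-holding effect, and its simulated net UF should not be
  compared to icodextrin exchanges.
* The drain model stops at a fixed residual volume; real drain termination
  (flow-rate threshold, posture) varies cycle to cycle.
* The effective contact area A is constant; a nearly empty cavity in reality
  loses contact area.
* Tidal/adapted APD, alarms and interruptions are out of scope.
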