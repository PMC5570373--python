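# Model description and methods

This note documents the science implemented in `spinesim`: the model
equations, the assumptions behind them, the default parameter values and how
they were chosen, the numerical choices, and the limits of what the test
suite demonstrates.

## Geometry

The spine head is a hemisphere of volume 0.1 μm³ (an average CA1 spine),
giving a radius `r = (3V/2π)^{1/3}` ≈ 363 nm that also sets the radius of
the flat cylindrical cleft (height 20 nm) between the head and the apposed
presynaptic hemisphere. The head is split into a PSD compartment holding
10% of the head volume (a cylinder under the synaptic membrane, outer
radius 150 nm) and the remaining cytosol. The neck (length 0.5 μm, radius
0.1 μm — typical CA1 values consistent with the 157 MΩ neck resistance) and the shaft (radius 0.5 μm, length
1 μm) are cylinders. Derived surface-to-volume ratios are validated against
the windows in which the Ca²⁺ parameters were calibrated (4–20 μm⁻¹ for the
head, 1–4 μm⁻¹ for the shaft); out-of-window geometries are rejected unless
forced.

Membrane zones by radial distance from the cleft centre: synaptic
(0, 150 nm], perisynaptic (150, 365 nm], extrasynaptic beyond. Interval
edges are half-open below, closed above (a convention; the boundary
placement is not specified more precisely in the literature the zones come
from).

## Glutamate field

A release empties G₀ molecules (default 1500 ≈ one vesicle at 100 mM) at
the cleft centre. Two closed-form regimes:

* **In-cleft (synaptic receptors, r = 75 nm).** Vertical mixing across
  20 nm is effectively instantaneous, so the transient is 2-D:
  `C = G₀/(4πDh(t+t₀))·exp(−r²/4D(t+t₀))·exp(−t/τ_esc)`, where
  t₀ = 0.1 ms is the vesicle-emptying time (it also regularises the point
  source) and τ_esc = 0.5 ms models clearance through the cleft rim. The
  cleft proper is transporter-free: astrocytic processes do not enter it.
* **Porous half-space (perisynaptic r = 257 nm, extrasynaptic path length
  0.48 μm).** `C = 2G₀/(α(4πD*t)^{3/2})·exp(−r²/4D*t)·e^{−k_up t}` with
  tortuosity λ = 1.4 (`D* = D/λ²`), extracellular volume fraction α = 0.38
  and pseudo-first-order uptake `k_up = k_on·B_total` (transporter binding
  linearised; no Michaelis–Menten cycling).

The two regimes are *not* matched point-wise at the rim: the perisynaptic
annulus geometrically overlaps the cleft, but perisynaptic receptors must
respond to transporter removal (the astrocytic leaflets reach the synapse
margin), which an uptake-free in-cleft solution cannot reproduce. Treating
everything beyond the PSD as porous medium reproduces the reference
behaviour — removing transporters raises the perisynaptic glutamate peak by
≈3 μM and the extrasynaptic peak by ≈1.5 μM while leaving the synaptic peak
untouched — at the cost of exact rim continuity.

The extrasynaptic sampling distance (0.48 μm) is shorter than cleft radius
plus neck length: spillover reaches the shaft membrane through the
extracellular space around the neck, not along its axis, and the default
was fixed by the ≈1.5 μM extrasynaptic transporter effect.

Pulses superpose linearly (uptake is linear, receptors do not deplete the
field), so glutamate peaks are exactly linear in G₀. The resting
extrasynaptic level (0.25 μM) adds outside the cleft only.

## Receptor kinetics

Receptors are population-mean state-fraction ODEs
`dp/dt = (A₀ + [Glu](t)A₁)p`; no stochastic channel gating. The NMDAR
schemes have eight states — unbound U, single- and double-liganded C1/C2,
slow/fast desensitised D1/D2 entered from C2 with rates k_d1+/k_d2+, two
pre-open intermediates and the open state — and the AMPAR scheme seven
(three closed, open, three desensitised). The topology is declared in the
config YAML, so alternative wirings can be swapped in without code change.

Rates are stored at a 23 °C reference and Q10-scaled to the simulation
temperature (34 °C) per transition class (NMDAR kinetics 3, AMPAR kinetics
2.4, transporter 3, diffusion 1.3, VDCC gating 3, pump 3, buffer 2.15;
conductances use their own classes). Because a transition and its reverse
share a Q10 class, equilibrium occupancies are temperature-invariant.

Published per-transition rate tables were not available for these exact
schemes, so the defaults were *calibrated*: equilibrium ratios were solved analytically
so that the stationary state at saturating glutamate reproduces the
reference values — open fractions 0.08 (NR2A) and 0.02 (NR2B), a shared
desensitised maximum of 0.81, saturation complete by ≈10 μM — and the
kinetic magnitudes (binding speed, gating speed, the split between slow and
fast desensitisation, deactivation) were then tuned against the dynamic
whole-model behaviours below. Two consequences worth noting: most of the
desensitised mass sits in the slowly recovering pool (85%), which is what
lets 100 Hz trains drive receptors well below their early open levels; and
NR2A deactivation is slow enough that blocking its desensitisation converts
a train into a nearly sustained open state.

Desensitisation inhibition (an AβO effect) multiplies k_d1+ and k_d2+ by
(1 − f), f ∈ [0, 1], per receptor class.

## Electrics

Spine head and shaft are RC compartments joined by the neck conductance
(157 MΩ). The shaft additionally carries a resistive–capacitive load
(250 MΩ, 60 pF) standing in for the unmodelled dendritic tree — these two
numbers were bounded by requiring the unitary EPSP (85 synaptic AMPARs) to
stay below 5 mV and the astrocytic pulse to depolarise the shaft by
4–6 mV. Mg²⁺ block uses the standard extracellular-Mg sigmoid
`B(V) = 1/(1 + ([Mg]/3.57 mM)·e^{−0.062V})`. VDCCs are a single
Hodgkin–Huxley activation gate (m², V½ = +10 mV, slope 6 mV, τ = 1 ms);
the high half-activation keeps them silent at the pairing potential (0 mV)
so that pairing responses remain NMDAR-dominated, while the bAP (a
stereotyped 90 mV double-exponential commanded on the shaft) still opens
them. VDCC current is treated as Ca²⁺-carrying only and is not fed back
into the voltage equation; this also makes the voltage stage independent of
all MCMC-calibrated parameters, so it is computed once per protocol during
calibration. "Pairing" clamps both compartments to 0 mV for the duration
of the train (the depolarisation level is a documented assumption, overridable in
config).

## Ca²⁺ dynamics

Per compartment i: `V_i dCa_i/dt = J_chan − J_PMCA − J_NCX + J_leak −
V_i·(buffer binding) ± J_diff`. Channel influx uses the GHK flux form with
per-scheme single-channel Ca²⁺ permeabilities; the NR2A and NR2B values
(2.57·10⁻⁵ and 2.85·10⁻⁵ μm³/ms) are pinned so that one receptor at rest
under 10 μM clamped glutamate passes 580 and 160 ions/s respectively.
Synaptic receptors feed the PSD, perisynaptic receptors and spine VDCCs the
cytosol, extrasynaptic receptors and shaft VDCCs the shaft.

Extrusion is PMCA (high affinity, K_m 0.8 μM) plus NCX treated as a
low-affinity, high-capacity exchanger (K_m 100 μM — effectively linear in
the operating range). A constant leak per compartment balances the pumps
*and the background channel influx* at rest, making the resting state an
exact fixed point. The immobile buffer (10 μM spine, 13 μM shaft, K_d
2 μM) gives a resting buffer capacity of ≈6 in the spine; the modest
capacity is what the pinned per-channel fluxes require for micromolar
spine transients. Inter-compartment exchange is first-order with rate
`D_Ca·A/(d·V)` using an apparent cytosolic diffusivity of 0.03 μm²/ms
(buffered Ca²⁺ moves far slower than the free-ion value).

The pump densities, buffer levels and VDCC density were calibrated jointly
against the reference outcomes listed here: control HFS spine peak ≈2.9 μM; full
synaptic-NR2A desensitisation block ≈17.9 μM; G₀ = 10,000 HFS peak ≈4.8 μM
within the first ~100 ms with a 0.5–1.2 μM post-peak plateau; removing
synaptic NR2B costs ≈1 μM; astrocytic 20 ms 1 mM pulse → ≈0.087 μM shaft
peak. With these constraints one qualitative statement is only partially
met: under synaptic HFS, extrasynaptic-NMDAR influx and diffusion from the
spine contribute comparably to the shaft transient, rather than diffusion
dominating outright.

The spine-head readout is the volume-weighted mean of PSD and cytosol free
Ca²⁺ (a single head trace is the conventional readout; the pooling rule is a
design choice).

## CaMKII cascade

A structural reimplementation (the original cascade's parameters are
outside the sources used here): lumped two-Ca²⁺ loading of each CaM lobe
(`k·Ca²`), Ca₄CaM binding to CaMKII subunits, neighbour-catalysed
autophosphorylation approximated as `k_auto·[bound]·(active fraction)²`
opposed by a saturable phosphatase (zero-order ultrasensitivity — the
source of the hard activation threshold), translocation of phosphorylated
subunits to the PSD, and anchoring on NR2B tails with capacity
3 slots × #NR2B. CaM and CaMKII totals are conserved exactly. Defaults
were tuned so the qualitative reference behaviours hold under pairing HFS:
no activation without pairing; all downstream outputs blocked at or below a
6:14 NR2A:NR2B split (and equally for a 50% NR2A reduction); complex
formation peaks at an intermediate split near 15:5 (≈1.5× control) and
falls towards 19:1 as anchoring capacity vanishes. The lumped CaM affinity
is deliberately low (half-loading near 200 μM Ca²) because the pairing
clamp drives spine Ca²⁺ to the 10²-μM scale in this model; the constant is
an effective parameter of the lumped two-ion step, not a per-site
dissociation constant. The four reported outputs are peak Ca₄CaM, peak
autophosphorylated subunits, peak PSD-resident CaMKII and the final
(t = 300 s) CaMKII–NMDAR complex count.

## Sensitivity analysis

Fifteen factors (G₀ 500–10000; resting glutamate 0–1 μM; transporter level
0–1 mM — the printed range says "0–1 uM" against a 0.5 mM standard value
and is treated as a typo for mM; six desensitisation-inhibition fractions
0–1; five receptor counts; extrasynaptic AMPAR density 15–30 μm⁻²) are
sampled by Latin hypercube (one sample per equal-probability bin per
factor; integer factors rounded). Each row runs the full simulator and
yields eight outputs (cumulative ions through sNR2A/sNR2B/pNR2B/eNR2B,
spine and shaft Ca²⁺ peaks, spine and shaft voltage peaks). PRCC
rank-transforms factors and outputs, residualises each against all other
factors by OLS, and correlates the residuals; p-values use the
t-approximation with df = n − 2 − (#partialled factors). Significance is
|PRCC| > 0.5 and p < 0.05.

## MCMC calibration

Ten uncertain parameters — VDCC, PMCA and NCX surface densities and
immobile-buffer totals for the spine and shaft locations, plus the shared
buffer on/off rates (the exact composition of the ten-parameter list is a design choice;
the named list is editable) — are sampled
with the affine-invariant ensemble sampler against four features of the
bAP-evoked transient: amplitude and 1/e decay time in the spine head and in
the shaft. Priors are log-uniform spanning 10× either side of the
defaults; the likelihood is Gaussian with 5% feature uncertainties. The
experimental dataset behind the original calibration is not redistributable,
so targets are *synthetic fixtures*: features simulated at known parameters
with seeded multiplicative noise. Parameter recovery on such fixtures
(≥8/10 truths inside 95% credible intervals) is the calibration acceptance
surface; with four features and ten parameters the posterior is strongly
degenerate, so wide marginals are expected and the recovery criterion tests
coverage, not concentration. Chains are exactly seed-reproducible; split
R̂ and a crude autocorrelation-based ESS are reported as diagnostics.

## Numerical choices

* Stiff integration (LSODA) throughout; receptor/voltage stages at
  rtol 10⁻⁸/10⁻⁶, the Ca²⁺ stage at rtol 10⁻⁶, atol 10⁻⁹.
* Integrations are segmented at stimulus times so the solver re-resolves
  each concentration spike; occupancies are re-projected onto the simplex
  at segment boundaries (drift stays below 10⁻⁸ over a full train).
* Output grid 0.05 ms; downstream stages interpolate linearly.
* Generator stationary states solve the null space directly (one balance
  row replaced by normalisation); degenerate generators raise.
* The fast calibration path integrates only the Ca²⁺ stage on a 0.2 ms
  grid with channel fluxes precomputed at resting intracellular Ca²⁺ (the
  intracellular term changes the GHK flux by <10⁻³ at these levels).

## Problem sizes

Default experiment sizes keep a full study reproducible on a laptop: 1 s
trains (100 pulses at 100 Hz, 10 at 10 Hz) with a 0.5 s tail; sensitivity
designs of n = 200 with a shortened (0.3 s) LFS train for screening runs;
calibration chains of 20–24 walkers × a few hundred steps; CaMKII runs of
300 s biological time. All are arguments, not constants.

## Known limitations

* Well-mixed compartments; no 3-D reaction–diffusion, no ER/IP₃ stores,
  mitochondria or mobile exogenous buffers.
* Linear, non-saturating transporter uptake; no astrocyte morphology.
* Deterministic receptor populations: no single-channel noise, so
  trial-to-trial variability is outside scope.
* The synthetic bAP fixtures share the model's own physics; passing
  recovery tests shows the inference machinery is sound, not that the
  defaults match any particular experimental dataset.
* The kinetic defaults are calibrated to reproduce the printed
  steady-state and transient values above, not transcribed from the
  original rate tables; quantitative agreement outside those calibrated
  behaviours should not be assumed.
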