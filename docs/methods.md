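# Methods

`cbcstim` models how rat ON and OFF cone bipolar cells (CBCs) respond to
voltage-controlled extracellular stimulation from a subretinal disk
electrode.  The computation runs in two one-way-coupled stages: a
quasi-static volume-conductor problem gives the extracellular potential
`Ve` everywhere in the tissue, and a multi-compartment cable model driven by
the sampled `Ve` gives membrane voltage, Ca++ channel gating and
intracellular calcium over time.

## Volume conductor

The tissue stack is a 2000 x 2000 um sandwich of three resistive layers:
the electrode carrier chip (100 um, 1e6 Ohm cm), the retina (300 um,
57 Ohm cm) and the silicone tamponade (300 um, 1e6 Ohm cm).  A 50 um
diameter disk electrode sits on the chip/retina interface, extruded 10 um
into the retina, and is held at the drive voltage (Dirichlet).  The distant
return electrode is modelled by grounding the lateral boundaries of the
retinal layer; all other outer faces are insulating (Neumann).

The potential solves div(sigma grad V) = 0, discretized with a 7-point
finite-volume stencil on a structured grid whose planes coincide with the
layer interfaces (face conductances then take the conductivity of the slab
each z-edge crosses; lateral edges on an interface plane average the two
slabs).  The SPD system is solved by Jacobi-preconditioned conjugate
gradients to a relative residual of 1e-8.  Because the problem is linear in
the drive, experiments solve once for a unit drive and multiply by the
stimulus waveform ("quasi-static" factorization); electrode impedance and
capacitive interface effects are out of scope.

Verification: on a homogeneous medium with Dirichlet boundary data taken
from the closed-form equipotential-disk solution
V(z) = (2 V0 / pi) arctan(a/z), the solver agrees with the closed form on
axis to 0.1 % at 2.5 um spacing and ~0.5 % at 5 um (tested bound: 3 %).
Experiment-scale solves use 10 um spacing (20 um in the test suite); grid
refinement tests confirm monotone convergence of sampled compartment
potentials.

## Cell geometries

No public traced reconstructions exist for these cells, so the package
generates canonical synthetic stand-ins: a type-9 ON cell (94 compartments,
~96 um tall, 11 um soma) and a type-3 OFF cell (78 compartments, ~51 um,
9 um soma), each a tree of cylinders plus a spherical soma laid out
dendrites -> soma -> axon -> terminal branches along +z, away from the
electrode.  The x/z skeleton is deterministic; the y ("depth") coordinate
of dendritic and terminal compartments follows a confined normal
distribution (sigma = 0.25 of the local process extent per step, truncated
at 2 sigma), seeded per fixture, so builds are bitwise reproducible.

Region extents and diameters are frozen package conventions chosen so the
fixtures reproduce the qualitative polarization pattern of perpendicular
bipolar cells in this field — terminals depolarize and dendrites
hyperpolarize under the standard terminal-depolarizing pulse, the longer ON
cell out-depolarizes the OFF cell, and clinching the ON axon to 40 % gives
a cell of OFF-like height.  They are not asserted to match any traced cell;
whole-cell voltage and calcium magnitudes therefore differ from values tied
to proprietary reconstructions, and tests assert orderings and saturation
properties, not absolute peaks.

Axial electrics per compartment: half-axial resistance R/2 =
rho_a (L/2) / (pi r^2) with rho_a = 130 Ohm cm; the soma uses the axial
path of an equivalent cylinder of length = diameter (the model needs a
finite somatic R/2 and no spherical convention is standard).  Membrane
capacitance is 1.1 uF/cm^2 times the compartment surface area (cylinder
lateral surface; full sphere for the soma).

`scale_axon` rescales the z-coordinates of axonal and terminal compartments
about the soma.  Only centers move — lengths, diameters, areas and the
compartment count are invariant — so the operation isolates the geometric
effect of axon length on field sampling.

SWC I/O uses type codes 1 = soma, 2 = axon, 3 = dendrite and the custom
code 5 = terminal; on reading, cylinder lengths follow the usual SWC
segment convention (distance to the parent node).

## Membrane model

Each compartment carries the linear leak (g_leak = 0.0417 mS/cm^2,
E_leak = -53.08 mV = resting potential).  Terminal compartments additionally
carry one voltage-gated Ca++ channel: L-type on the ON cell, T-type on the
OFF cell (swappable for the identical-equipment control).

T-type: i = gbar m h (Vm - E_eff), gbar = 0.954 mS/cm^2, with
m_inf = 1/(1+exp(-(Vm-37.55)/3.07)),
tau_m = 1.36 + 21.68/(1+exp((Vm-39.96)/4.11)) ms,
h_inf = 1/(1+exp((Vm-8.97)/8.42)),
tau_h = 65.82 + 0.0023 exp((Vm-80)/4.78) ms.

L-type: i = gbar m^2 h (Vm - E_eff), gbar = 1.088 mS/cm^2, with
alpha_m = 0.427 (Vm-63)/(1-exp(-(Vm-63)/10.5)) /ms (the removable
singularity at 63 mV is evaluated by its series limit),
beta_m = 0.0406 exp((70-Vm)/12) /ms,
h_inf = 1/(1+exp(Vm/66.4)), tau_h = 292 ms.

These kinetics place the channels' operating range well above rest: at
-53 mV both activation gates are essentially closed, the T-gate
deactivating slowly (tau_m ~= 23 ms) and the L-gate almost instantaneously.
That single asymmetry produces most of the ON/OFF differences the
experiments show: brief post-stimulus calcium in the ON cell, sustained
influx and slow recovery in the OFF cell.

Effective reversal potential: intracellular Ca++ is sub-micromolar, so the
outward limb of the channel current is carried mostly by K+.  The model
blends the dynamic Ca++ Nernst potential with a fixed K+ equilibrium
potential, E_eff = w (RT/2F) ln([Ca]_o/[Ca]_i) + (1-w) E_K, at 25 C
(RT/2F = 12.846 mV), E_K = -75 mV.  The weights w_T = 0.55 and w_L = 0.70
are model choices (no published values exist): they put the T reversal near
+33 mV — inward-only currents for sub-0 mV depolarizations, outward
transients during strong pulses — and the L reversal near +62 mV, keeping
the clamp family inward up to the +55 mV step.

Intracellular calcium (terminals only) follows
d[Ca]/dt = -(s/v) i_Ca/(2F) - ([Ca]-[Ca]_res)/tau with tau = 1.5 ms,
[Ca]_res = 0.15 uM, [Ca]_o = 1800 uM held constant, and s/v the
compartment's surface-to-volume ratio.  [Ca]_res is a *floor*: strong
outward transients (mostly K+ charge) cannot deplete the store below the
residual level.  The update uses the exact exponential solution per step.

## Cable integration

The reduced potential V = Vi - Ve - Vrest of compartment n obeys
C_n dV_n/dt = -I_ion,n + sum over neighbors of
[(V_nb - V_n) + (Ve,nb - Ve,n)] / (R_nb/2 + R_n/2), one term per neighbor
at branch points.  Units are frozen repo-wide (mV, ms, kOhm, uF, uA/cm^2,
mS/cm^2, uM, um), making the equations prefactor-free.

Integration is operator-split per dt = 0.01 ms step: (1) gates advance by
their exact exponential update at the current voltage; (2) channel currents
are evaluated explicitly; (3) the linear subsystem (axial coupling + leak)
advances by backward Euler, with the constant system matrix LU-factorized
once per run; (4) calcium advances by its exact exponential update using
the current at the new voltage.  The scheme is unconditionally stable for
the stiff axial coupling and the 5-decade spread of gate time constants;
dt-halving tests confirm first-order convergence.  A guard aborts with a
diagnostic if |V| exceeds 10 V.

Sign convention: polarity names in the stimulation literature are used
inconsistently; this package fixes "cathodic" to mean the drive polarity
that depolarizes the synaptic terminals of a perpendicular bipolar cell
(positive electrode voltage in the volume-conductor frame used here), and
"anodic" the opposite.  Biphasic phase-order effects are therefore best
stated in phase-role terms: the ON cell accumulates the most synaptic
calcium when the terminal-depolarizing phase comes second (its
fast-deactivating L-channel is loaded and then discharges into the inward
window on the return to rest), the OFF cell when it comes first (its
slowly deactivating T-channel keeps conducting through and after the
trailing phase).

## Experiments

Standard placement puts the soma on the electrode axis with the lowest
dendritic compartment 25 um above the electrode plane.  The standard pulse
is 1 V for 1 ms (0.5 ms in the amplitude and burst series); bursts are
5 pulses with configurable inter-stimulus interval; biphasic pulses split
the total width by the percentage x with the second-phase amplitude scaled
by x/(100-x) so the two phase areas cancel exactly (duration split is
fixed by x, so charge balance must come from amplitude).  The position map
defaults to 48 x 17 = 816 placements at 2 um pitch (the grid shape is a
convention; only the count and pitch are prescribed).

Calcium recovery time is measured from the final stimulus offset to the
last time the maximal terminal [Ca++]_i exceeds baseline by 2 % of the
baseline value (a strict criterion: with tau = 1.5 ms, recovery from
1 uM to that band takes ~8 ms even though ~95 % recovery — the usual
visual "back to rest" — takes 4-5 ms; the OFF cell's recovery is set by
the 23 ms T-gate deactivation instead and takes an order of magnitude
longer).  Traces that end above the band are flagged censored.

### Mono-compartment frequency response

An isolated compartment cannot be polarized by a spatially uniform
extracellular field (the cable drive is a difference of potentials), so the
sinusoidal sweep uses a transduction harness: a single terminal-sized patch
(leak + one Ca++ channel + the calcium model, s/v = 3.3 /um) driven by a
sinusoidal transmembrane current whose amplitude is calibrated to polarize
the passive membrane by 100 mV at low frequency — the polarization scale
the field simulations produce at the terminals, and a swing that reaches
the channels' activation range.  The membrane time constant
cm/g_leak = 26.4 ms supplies the high-frequency rolloff; gate kinetics
shape the rest.  Each frequency settles for >= 1.2 s (four L-inactivation
time constants) and >= 3 cycles; the peak inward current of the final cycle
is normalized across the 1-1000 Hz sweep.  The T-type curve peaks at 3 Hz
(slow activation plus 66 ms inactivation make it a band-pass), the L-type
at 5 Hz, above the T-type and within the expected <= 20 Hz; both results
are unchanged under dt halving.  A sodium channel can be plugged into the
same harness via the channel interface (steady_state / step_gates /
current); no sodium kinetics ship with the package.

## Problem sizes and runtimes

Experiment-scale field solves use a 10 um grid (2.9 M nodes, ~45 s once,
cacheable to HDF5); the test suite shares one 20 um solve (~2 s).  Cable
runs integrate 78-94 compartments at dt = 0.01 ms (a 100 ms trace takes
~1 s).  The full frequency sweep takes ~1 minute per channel, dominated by
the 1-3 Hz settling runs.

## Known limitations

* The fixtures are synthetic; absolute Delta-Vm and [Ca++]_i magnitudes are
  fixture-dependent (our OFF-cell peaks run ~1.5-2x above the reference
  values for traced cells, with all qualitative orderings preserved).
* One-way coupling only: membrane currents do not feed back into Ve.
* No calcium diffusion or buffering beyond the single-pool relaxation; no
  synaptic release model.
* The identical-channel-equipment control (channel_swap) is implemented,
  but its fine calcium orderings depend on the ON/OFF depolarization gap,
  which is larger for traced morphologies than for the synthetic fixtures;
  tests assert its structure only.
* The K+/Ca++ mixing weights and E_K are calibrated, not measured; they
  scale current amplitudes but not the selectivity conclusions.
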