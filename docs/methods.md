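# Methods

`mvnflow` simulates steady and RBC-resolved blood flow in cortical
microvascular networks and reproduces, on synthetic networks, an analysis
pipeline for aging-related capillary alterations: layer-specific
constriction/dilation, capillary rarefaction, layer-resolved perfusion
metrics, and a graph taxonomy of venous drainage (tributaries and
pre-convergence capillaries).

## Flow model

Each vessel is an edge with diameter D (µm) and tortuous length L (µm);
bifurcations are nodes. Because Re < 1 throughout the microvasculature,
per-vessel flow obeys Poiseuille's law

    q_ij = pi D_ij^4 / (128 L_ij mu mu_rel(D_ij, Hd_ij)) (p_i - p_j),

with plasma viscosity mu = 1.2 mPa·s and the relative effective viscosity
mu_rel from the empirical in vitro tube-flow law (Pries-type
parameterization; diameter amplitude 220 e^{-1.3D} + 3.2 - 2.44
e^{-0.06 D^0.645} at the 0.45 reference hematocrit). Mass conservation at
interior nodes yields a sparse SPD system for nodal pressures, solved by
direct sparse factorization; flows are reported in µm³/s (1 µm³ = 1 fl),
pressures in mmHg (converted internally to Pa).

Boundary conditions come in two regimes. *Open*: every boundary node
carries a fixed pressure. *Trimmed*: only pial-surface boundary nodes are
pressurized and every subsurface boundary is sealed, so blood enters and
leaves through the surface only. Default pressures are an assumption, not
a measurement: arterial 50 mmHg and venous 10 mmHg at the surface, with a
linear depth attenuation (−15 and +7.5 mmHg respectively at 1,000 µm) so
that deep cut vessels do not act as strong artificial sources or sinks.
All pressure parameters are configurable.

## Discrete RBC tracking

RBCs are point particles of fixed volume 49 fl advected at vf·q/A, where
the velocity factor vf = Hd/Ht comes from the Fahraeus relation
Ht/Hd = Hd + (1-Hd)(1 + 1.7 e^{-0.415D} - 0.6 e^{-0.011D}), inverted
analytically (a quadratic in Hd). The fit can place Ht above Hd below the
RBC diameter (~3 µm); we clamp to Hd >= Ht there so vf >= 1 always.

At divergent bifurcations with parent diameter > 10 µm, RBCs are routed
stochastically with the empirical phase-separation fractions
(logit FQE = A + B logit[(FQB - X0)/(1 - 2X0)], A/B/X0 with the standard
coefficients 13.29 / 6.98 / 0.964 scaled by (1-Hd)/D_parent). At
trifurcations the law is applied pairwise (first daughter against the
area-merged remainder), a choice the source formulation leaves open.
Below the threshold, transit is single file and each RBC follows the
largest pressure force, implemented as the maximum of (pressure drop x
daughter cross-section) over outflow daughters, with ties broken by
larger flow, then lexicographic vessel id, for exact reproducibility. An
RBC never enters a zero-flow daughter.

Tube hematocrit of a vessel is particle count x 49 fl / vessel volume;
it feeds back into mu_rel through a flow re-solve on a fixed cadence
(default every 50 ms of simulated time, a convergence knob validated
against the symmetric-network oracle below). A vessel admits no further
RBC once its tube hematocrit would exceed 0.85 (injection and transfers
throttle), so Ht < 1 is structural. Inflows inject RBCs by a
deterministic fractional accumulator at rate q·Hd_in/V_RBC with inflow
discharge hematocrit 0.3; particles reaching a pressurized boundary node
are removed. Injected − removed equals the population change exactly at
every step.

### Time averaging

Because the RBC distribution and flow field fluctuate, all metrics use
the time-averaged flow field. The averaging window is chosen from the
per-vessel turnover times tau = L / v_RBC: the window is 6x the 90th
percentile of tau, so that >= 90% of vessels complete >= 6 turnovers,
clipped to configurable bounds (1–60 s by default, with a diagnostic when
clipping occurs; at the desk scale used here the chosen windows are
typically 6–10 s). A 2 s warm-up precedes averaging so the hematocrit
field relaxes from its uniform initialization. Simulations are exactly
reproducible per seed.

## Synthetic networks

The reconstructed networks this pipeline was designed around are not
publicly deposited, so a generator produces cortical-column-like networks
with the statistical structure the analysis assumes:

- capillaries form stacked honeycomb lattice planes (degree-3 dominant,
  hence bifurcation-dominated drainage) spanning 1,000 µm of depth,
  jittered in position, with a random 30% of vertical inter-plane links;
  diameters 4 ± 0.5 µm, segment lengths ~60 µm chord x tortuosity
  1.25 ± 0.10 (giving a realistic share of segments <= 70 µm, which the
  rarefaction rule needs);
- penetrating arteriole trunks (3; 15 µm tapering with depth) and
  ascending venule trunks (2; 20 µm) descend from pial stubs with one
  offshoot per crossed plane to the nearest free lattice node; one
  PCV-like venule (45 µm trunk) spans the full depth with offshoots only
  below 600 µm, mimicking the deep-layer-draining principal cortical
  venule (the in vivo PCV trunk is larger still, ~57.5 µm; 45 µm keeps
  the desk-scale trunk from dominating total conductance);
- boundary nodes are the pial stub ends plus the cut trunk bottoms, so
  both open and trimmed regimes are well defined.

Defaults target ~2,200 vessels with a capillary length share of ~96%,
the share the real reconstructions report; lattice size, counts and all
diameter distributions are parameters. What the generator does *not*
emulate: anatomical positioning of penetrating vessels, diving venule
anastomoses, true capillary loop statistics, or any image-derived
geometry — so passing tests demonstrate the pipeline's behaviour on
networks with the right summary statistics, not agreement with any
specific animal.

## Aging scenarios

Capillaries eligible for perturbation must (i) lie within the 5th–95th
percentile of all vessel depths, (ii) be at least two vessels from any
in/outflow boundary (both guards against boundary artifacts), and (iii)
sit toward the venous end of the bed: median topological distance along
flow-directed paths > 3 segments to the nearest penetrating-arteriole
trunk (medianDistMainDA) and > 1 segment to the nearest ascending-venule
trunk (medianDistMainAV). Distances are medians over *all* flow-directed
paths; since pressure decreases strictly along flow the directed graph is
acyclic, and the full path-length distribution is computed exactly by
dynamic programming (equivalent to exhaustive enumeration, bounded at 25
segments). A capillary attached through a single offshoot counts distance
1; distances are in segment counts, which we take to be the thresholds'
units.

Named scenarios: `anesthetized_aged` (eligible L6 capillaries constricted
7%), `awake_aged` (L2/3 +4.5%, L4 +5.1%, L6 −14% plus 10% density
reduction in L6), and the two L6 effects applied separately
(`constriction_only`, `rarefaction_only`). Rarefaction draws
floor(0.10 x L6 capillary count) candidates uniformly without replacement
from eligible capillaries of length <= 70 µm, over 5 replicate seeds, and
constricts them by 97% (diameter x 0.03) — conductance falls by ~10^6,
which removes them from the perfused network (their mean |flow| lands
below the 2.5th percentile of all vessel flows). Cortical layers bin
capillary mean depth at 200 µm steps; the deepest bin (L6, including the
corpus callosum) is open-ended beyond 800 µm.

## Metrics

Per vessel: RBC flux = |q|·htd/V_RBC (cells/s), RBC velocity = vf·|q|/A
(µm/s), linear density = flux/velocity (cells/mm; undefined at zero
velocity and flagged, not dropped). Layer summaries average over analysis
capillaries (filters (i)–(ii) only — the trunk-distance thresholds select
perturbation targets, not the analysis population), reporting mean and
median per layer. Integral capillary-bed inflow/outflow per layer is
accumulated at label-transition nodes (arterial→capillary start points,
capillary→venous end points), binned by the transition node's depth.
Change tables report replicate median ± s.d. (mean also emitted).

## Tributary taxonomy

Nodes are classed by flow direction: divergent (1 in, >= 2 out),
convergent (>= 2 in, 1 out), through (1-1), otherwise unclassified (and
any node touching a zero-flow vessel, whose direction is undefined).
Walking upstream from a venule-branch attachment through convergence-only
junctions collects the tributary: segments whose own upstream node is
convergent are *other tributary vessels*; segments terminating at a
divergence (or boundary) are *pre-convergence capillaries*; vessels above
the last divergence are not members. Through nodes are transparent —
through-joined vessels count as one bifurcation-delimited segment. In a
bifurcation-only drainage tree with k leaves the segment count is 2k−1,
always odd; trifurcations give even counts, classed as the next higher
odd number. Complexity: low (1,3), medium (5,7), high (>= 9). If two
attachments ever compete for a segment (impossible in a tree), the
attachment fewer hops downstream keeps it and both tributaries are
flagged.

## Numerical choices and scaled-down problem sizes

- Advection step: 0.5x the fastest vessel transit time, clipped to
  [0.2, 2] ms; particles crossing several vessels in one step are walked
  through up to 6 hops with leftover time.
- Particles parked at a full daughter or a momentarily dead-ended node
  are retried after the next flow re-solve.
- Direct sparse solve (SuiteSparse via SciPy); singular systems (no
  pressure anchor) raise rather than regularize.
- Default experiments run at desk scale (~2,200 vessels, ~20,000 RBCs,
  windows of 6–10 s), a deliberate scale-down of the reference networks
  (~12,000–19,000 vessels, 14–20 s windows); all sizes are parameters.

## Known limitations

Point-particle RBCs (no deformation, no single-file spacing beyond the
capacity cap), no vessel compliance or pulsatility, no oxygen transport,
no stall/plugging dynamics, and a two-level depth-attenuated boundary
pressure scheme in open mode rather than measured boundary values. The
perturbation applies one scale factor per layer, whereas real aging shows
a distribution of constrictions and dilations.
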