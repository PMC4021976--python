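# Methods

## Model

The network is a four-compartment stoichiometric reconstruction of brain
energy metabolism: neuron (n), astrocyte (a), extracellular space (e) and
blood capillary (c), with the cells split into cytosol (nc, ac),
mitochondria (nm, am) and, for the neuron, synaptic vesicles (nv).  The
default build has **N = 142 reactions over M = 132 species** (N > M, so the
system is underdetermined), covering: capillary glucose and oxygen supply;
glucose routes c→a, c→e, e→a, e→n (neurons receive glucose only through the
interstitium); oxygen routes c→n and c→a; stepwise glycolysis (hexokinase
through pyruvate kinase) with lactate dehydrogenase and reversible
monocarboxylate transport of lactate and pyruvate in both cells; the
pentose phosphate shunt (oxidative branch 2 NADPH + CO2 per G6P, lumped
non-oxidative return); pyruvate import, pyruvate dehydrogenase, the full
TCA cycle and lumped oxidative phosphorylation (P/O 2.5 for NADH, 1.5 for
FADH2) with a ROS side reaction NADH + O2 → NAD+ + H2O2; the
malate–aspartate and glycerol-3-phosphate shuttles; pyruvate carboxylase
(astrocyte only) and cytosolic/mitochondrial malic enzyme; the
glutamate–glutamine cycle (vesicular loading at 1 ATP, release, astrocytic
uptake with 3 Na⁺ co- and 1 K⁺ counter-transport, a minor neuronal uptake
route, glutamine synthetase at 1 ATP, glutamine return, neuronal
glutaminase) and glutamate dehydrogenase in both cells; Na⁺/K⁺ channels,
the astrocytic Na–K cotransporter (1:1) and inward K⁺ channel, and the
Na/K-ATPase (1 ATP : 3 Na⁺ out : 2 K⁺ in); creatine and adenylate kinase;
astrocytic glycogen turnover; and the glutathione/ascorbate antioxidant
system with synthesis confined to astrocytes (cystine supply, transfer
route a→e→n, peroxidase/reductase and dehydroascorbate reduction in both
cells).

Element accounting tracks carbon and nitrogen only (water, protons and
phosphate are untracked).  Coefficients are exact rationals; every
non-exchange reaction is audited for both elements.  Lumpings: the CoA
moiety is untracked (acetyl-CoA counts as C2, succinyl-CoA C4); glutathione
is represented by its glutamyl-cysteine core (C8 N2), so a single lumped
cystine intake supplies its precursors; CO2 is pooled per cell with one
export route per cell; adenine nucleotides are pooled per cell (no explicit
mitochondrial translocase); NAD(H) and FAD(H2) pools are
cytosolic/mitochondrial separate, which is what makes the shuttles
meaningful.

Two closed-pool corrections deserve emphasis because they are easy to get
wrong.  If Na⁺ and K⁺ have no exchange with blood, the sum of each ion's
balance rows is identically zero, so the soft constraints force every ion
balance to strict equality — and solving those equalities proves that
astrocytic glutamate uptake (which moves 1 K⁺ out per glutamate while the
pump returns 2 K⁺ per ATP) carries zero flux in *every* solution.  The
same argument applied to amino nitrogen (with ammonia efflux only) pins
glutamate dehydrogenase and glutathione synthesis at zero.  The build
therefore includes blood–brain ion and ammonia exchange (capillary intake,
efflux and reversible c↔e transport for Na⁺, K⁺ and NH4⁺), which is
standard physiology.

Reversibility: near-equilibrium isomerases, dehydrogenases of the
malate–aspartate shuttle, lactate dehydrogenase, aminotransferases,
creatine/adenylate kinase, glutamate dehydrogenase, the shuttle carriers
and the small-molecule transports (lactate, pyruvate, aspartate, ascorbate,
dehydroascorbate, peroxide, ammonium, blood ions) are reversible;
kinase-driven glycolytic steps, PDH, the TCA dehydrogenases, oxidative
phosphorylation, pumps, channels, the directed glutamate/glutamine cycle
steps and all intakes/effluxes are irreversible.  The full assignment is in
the TSV export (`gliaflux build-network`).

## Constraints

At stationarity the model keeps, for every intracellular and extracellular
species m, the production-network (soft) balance

    (S ν)_m ≥ 0,

i.e. net production is allowed (absorbing pathways outside the
reconstruction) but net consumption is not, while the capillary nutrients
obey strict balances νGlc(→c) = νGlc(c→a) + νGlc(c→e) and νO2(→c) =
νO2(c→a) + νO2(c→n).  The capillary glucose uptake is the only pinned flux;
the oxygen intake is free.  Bounds are [0, ν_max] for irreversible and
[−ν_max, ν_max] for reversible reactions.

ν_max is an **absolute** prior bound (default 1.0) and glucose pins are
swept relative to it.  This is deliberate: the constraint system is exactly
scale-covariant — mapping (g, ν_max) → (λg, λν_max) maps solutions by
ν → λν, a property the test suite asserts — so if the bound were tied to
the pin, the OGI distribution would be identical at every uptake level and
no basal state could be calibrated.  With an absolute bound, raising the
pin moves the carbon-limited polytope relative to the fixed prior, and the
ensemble-mean OGI falls monotonically with uptake, which is the behaviour
the sweep exploits.

The extracellular glucose balance (νGlc(c→e) = νGlc(e→a) + νGlc(e→n)) is a
soft row by default — interstitial glucose may be weakly net-produced — and
can be promoted to a strict equality with the `eq7_strict` switch.

The ROS side reaction is sized through its bound: each cell's H2O2
production is capped at `ros_fraction × g` (default 0.10) so that
detoxifying it demands NADPH on the order of a 5–15% pentose-phosphate
glucose fraction.  Without this cap the ROS column (a full O2 per NADH)
dominates the oxygen balance under the uniform prior and pushes the entire
OGI distribution above 6 at every uptake.

## Sampling

Each sample starts from an independent draw of an uncorrelated uniform
prior over the bounds (pinned components fixed; per-sample seeds derive
deterministically from the base seed and the sample index).  The draw is
replaced by the **exact Euclidean projection** onto the feasible polytope,
so the average distance between solutions and the prior is minimal by
construction — the defining property of the statistically controlled
sampling this framework calls for.  The projection is computed by
least-distance programming: pinned variables are eliminated, equalities are
written as inequality pairs, rows are normalized, and the LDP reduces to a
single non-negative least-squares problem (Lawson–Hanson), a finite,
deterministic active-set algorithm.  Residuals land near machine precision
(~1e-13), far inside the feasibility tolerance ε = 1e-9.  An iterative
most-violated-row scheme (Agmon–Motzkin–Schoenberg) was implemented first
and abandoned: on the full network its residual decays roughly like 1/t
(3e-5 after 10⁶ iterations), so ε = 1e-9 is unreachable in practice.

Draws whose projection fails the feasibility audit are discarded and
counted, never repaired.  An LP feasibility phase (HiGHS) over the same
constraint set serves as an independent non-emptiness oracle in the tests,
and small chain/diamond/two-cell toy networks with grid-enumerable
polytopes bound the sampler's support.

**Known bias.**  Minimal-distance projection of a uniform prior is *not*
uniform over the polytope.  On the toys the per-flux means deviate from the
uniform (grid) means by up to ~0.2 flux units — effluxes and free intakes
are biased toward the prior box interior.  This is a property of the
method, not a defect of the implementation: the sampling is "reasonably
unbiased", and exact uniform sampling (hit-and-run) is out of scope.  Any
statement derived from the ensembles is a statement about the
minimal-distance measure, not the uniform one.

The feasibility tolerance ε = 1e-9 is distinct from the null-flux
classification threshold 1e-6 used downstream: a flux is *null* when its
magnitude is below 1e-6, and a solution is *active* when its
glutamate-glutamine cycle rate strictly exceeds that threshold.

## Observables

* OGI = νO2(→c) / νGlc(→c).  6 is the stoichiometric ceiling for complete
  glucose oxidation; slightly larger values occur because the oxygen intake
  is free and intracellular oxygen may accumulate under the soft balances.
* V_cyc = νGS(a), the astrocytic glutamine synthetase flux.
* CMR_Glc(ox)(n) = ½ νPDH(n) (two pyruvates per glucose).
* astrocytic glucose fraction = (νGlc(c→a) + νGlc(e→a)) / νGlc(→c).
* CCLS flux: net astrocyte→neuron lactate flow, reported on the astrocyte
  side (its reversible transporter flux toward the shared pool; positive =
  ANLS).  The neuron-side value is stored alongside; the two can differ
  because extracellular lactate may be weakly net-produced.
* cellular oxygen consumption: summed O2-consuming flux of reactions scoped
  to a cell, transports excluded.

Binned conditional averages use equal-count quantile bins (default 20) with
standard errors sd/√n; OGI histograms use bin width 0.05.  The curves of
cycle rate versus OGI and of neuronal oxidative glucose versus cycle rate
are **per-level conditional means** — one point per uptake level, the curve
parametrized by the pinned uptake — because within one level the cycle rate
and neuronal PDH compete for the same ATP budget and their within-level
correlation is negative; the positive coupling is a between-level
activation effect.  The lactate-shuttle versus partitioning analysis pools
individual solutions across levels.  Two-regime slopes are weighted
least-squares fits (weights 1/se²) over the low- and high-activity
regimes; the regimes are identified by each level's conditional OGI lying
above or below the awake resting value 5.5 (equivalent to splitting at the
V_cyc breakpoint of the OGI = 5.5 crossing, but robust, since the
per-level OGI is monotone in the uptake while the V_cyc means move
little).

Correlation matrices are Pearson coefficients per reaction pair over a
conditioned solution set, with reactions null (|ν| < 1e-6 throughout the
set) or constant masked rather than propagated as NaN.  The "V_cyc = 0"
condition is realized as a separate ensemble sampled with the glutamine
synthetase flux pinned to zero (virtually every free solution carries
V_cyc > 1e-6, so subsetting would select almost nothing).  The
restructuring statistic — the fraction of between-cell reaction pairs with
|r| > 0.5 under the two conditions — is computed per uptake level and
averaged, a paired comparison at identical uptake; pooling solutions
across levels first would add uptake-driven covariance common to both
conditions and bury the conditioning contrast.

## Study protocol and default parameters

| parameter | default | meaning |
|---|---|---|
| ν_max | 1.0 | absolute prior bound, sets the flux unit |
| ε | 1e-9 | feasibility tolerance |
| null threshold | 1e-6 | flux-is-null / V_cyc-active classification |
| ros_fraction | 0.10 | per-cell H2O2 cap as a fraction of the glucose pin |
| calibration pins | 0.08 … 0.21 (7 values) | coarse probes of mean OGI(g) |
| sweep multipliers | 0.70 … 1.50 × g* (9 values) | calibrated study levels |
| K | 10 000 | solutions per level (default) |
| K_calibration | 2 000 | solutions per calibration probe |
| K_silent | K/2 | solutions per pinned-V_cyc=0 level |

Basal uptake g* is interpolated from the calibration probes at mean OGI =
5.5; the activated state is 1.15 × g*.  Every reported quantity is a pure
function of the run configuration; per-level seeds are spawned from the
base seed.

The test suite runs the same protocol at reduced sizes (K = 1000,
calibration 600, silent 500) and the acceptance script at K = 4000 /
1500 / 2000 — sizes chosen so a full run completes comfortably on one CPU
while keeping standard errors on ensemble means around or below 1% of the
values.

## Synthetic benchmarks

The toy generator produces (i) pinned linear chains whose feasible set is
the monotone non-increasing flux sequences, characterized in closed form;
(ii) a diamond with two parallel routes; (iii) an eight-reaction two-cell
caricature (lumped glycolysis 1 glucose → 2 lactate, lumped oxidation
1 lactate + 3 O2, reversible lactate exchange) on which OGI, partitioning
and the lactate shuttle are all defined and whose polytope is
grid-enumerable; and (iv) random sparse networks with an embedded feasible
point, non-empty by construction.  These emulate the structural skeleton
the analysis assumes — a pinned intake at equality, soft internal rows,
reversible exchanges — but none of the biology: passing the toy suite
validates the constraint/sampler/observable machinery, not the physiology
of the brain reconstruction, and says nothing about kinetic or regulatory
effects that no stoichiometric model represents.

## Numerical choices

Pins are encoded as degenerate bounds and eliminated before projection.
Equality rows enter the LDP as inequality pairs; all constraint rows are
normalized to unit norm.  The NNLS reduction detects an empty polytope via
a vanishing residual component.  The brute-force oracle eliminates equality
rows by Gaussian pivoting and scans the remaining free dimensions (≤ 6) on
a regular grid, so grid points satisfy the equalities exactly.  Ensemble
determinism is bitwise for a fixed configuration; matched-seed runs at
scaled (g, ν_max) reproduce each other to relative 1e-6, limited only by
floating-point arithmetic in the active-set solver.

## Known limitations

* The reference reconstruction's exact reaction list, reversibility table
  and bounds are not published in the main text; this build is a
  pathway-level reconstruction, and quantities that depend on fine network
  asymmetries differ from the printed ones.  In particular the sampled
  astrocyte/neuron oxidative split sits near parity (astrocytic share
  ~55–60% rather than ~35%): under the uniform prior the astrocyte-only
  ATP consumers (glycogen turnover, pyruvate carboxylase, glutamine
  synthetase and its pump load) draw prior-scale fluxes that pull
  astrocytic oxidation up, and nothing at pathway-level
  resolution pins them down.
* Exact projection almost never lands exactly on the V_cyc = 0 face, so
  the free ensembles contain essentially no silent solutions and the gain
  from conditioning on V_cyc > 0 is near zero here (an approximate
  iterative relaxation, stopping short of the exact optimum, would
  instead leave many solutions at the face).  The V_cyc = 0 analyses
  therefore use pinned ensembles.
* The sampling measure is minimal-distance, not uniform (see above).
* No kinetics, no enzyme regulation, no thermodynamic (ΔG) constraints, no
  objective function, and no consumption of pre-stored glycogen; the
  concentration dynamics behind the stationarity assumption are never
  represented.
* The correlation restructuring induced by conditioning on an active
  glutamate-glutamine cycle is present in direction but weak in this
  reconstruction: at equal sample sizes the between-cell |r| > 0.5 mass
  under V_cyc > 0 exceeds the pinned V_cyc = 0 value by only ~0.002 on
  average, comparable to its seed-to-seed fluctuation, so the contrast is
  not statistically reliable at desk-scale sample sizes.
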