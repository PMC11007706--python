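# Model and methods

`gutsim` simulates the digestion of defined meals by an averaged healthy
adult as a chain of well-mixed compartments — plate, mouth, a
three-compartment stomach (fundus, corpus, antrum), the duodenum before
and after the sphincter of Oddi, three jejunal and six ileal units, and a
colon — coupled by feedback-controlled flows. Every compartment is a mass
ledger in grams per chemical component; volumes follow from isochoric
mixing (Σ mᵢ/ρᵢ with fixed pure-component densities), concentrations are
mass over collective volume, and compartmental pH is solved from a proton
balance each step. All slow variables are linearized over the internal
step (1 s by default) and advanced with steady-state rate laws; output is
reported once per minute. The model is fully deterministic.

## State and components

The component roster covers water, protein/peptide/amino acid, the
glyceride ladder (TG → DG → MG + fatty acids), phospholipids, the sugars
(glucose, fructose, sucrose, maltose, maltodextrin, rapidly and slowly
digestible starch, a pentose "rare sugar" used as enzyme inhibitor),
mucus protein, bile salt and the bile-salt–fatty-acid micellar complex,
hydrogen ion, bicarbonate, citric acid, a pancreatic tracer peptide and
the digestive enzymes as carried species. Densities are fixed averages
(water 1, fats 0.9, glucose/starch 1.54, protein 1.35, sucrose 1.59,
pentoses and the micellar complex 1.69, citric acid 1.66 g/mL); hydrogen
ions carry a sentinel density of 10⁶ g/mL so their volume contribution is
negligible. Caloric densities are Atwater values (4 kcal/g carbohydrate
and protein, 9 kcal/g fat), configurable per component.

**pH.** Each compartment's pH solves
`free(pH) + Σ groups cap·C·(f(pH) − f(7)) = added H⁺`, where `f` is the
Henderson–Hasselbalch occupancy of each discrete (pKa, capacity)
titration group (proteins carry groups at pKa 4.5 and 6.8; citric acid
its three acid constants). Occupancies are referenced to the neutral
state so components arrive charge-balanced: buffers added to water leave
pH 7, added acid is shared between the free pool and the buffers.
Bisection on [0, 14] is unconditionally convergent (the balance is
strictly monotone); the scalar API iterates to |ΔH⁺| < 10⁻⁹ mol/L.
Bicarbonate neutralizes acid stoichiometrically and instantly; the
reacted mass is booked as water so the global ledger closes exactly.
Activity coefficients, ionic strength and CO₂ equilibria are out of
scope.

## Meals and oral processing

Meals are sequences of compounds, each solid (particle size, oral and
gastric mechanical breakdown times) or liquid (viscosity), with a
component composition and a decomposition time with which the compound
releases its components into the surrounding fluid. Consumption moves
compound mass from plate to mouth at the meal's rate (mL/min),
proportionally across the remaining compounds. In the mouth, saliva is
added at 4 mL/min while eating (0.3 mL/min basal, 0.5 % salivary
amylase), solid particle size decays exponentially with the oral
breakdown time, and boluses are swallowed into the corpus: liquids with
the next peristaltic tick, solids once masticated below 3 mm or after
three oral time constants. The swallowable size (3 mm) deliberately
exceeds the pyloric sieve (2 mm), so swallowed solids still require
gastric grinding before they can empty — without this separation, solid
meals would behave as liquids at the pylorus.

Compound decomposition is surface-limited: the first-order release rate
accelerates by `max(1, sieve/size)` as grinding shrinks particles below
the sieve size. This is what differentiates bread from pasta — the pasta
fixture differs from bread by slower mechanical breakdown (gastric
grinding time constants 45 vs 30 min, oral 0.75 vs 0.5 min, decomposition
30 vs 20 min) and larger particles (10 vs 8 mm).

## Stomach

The corpus receives boluses and gastric juice (2 % mucus protein, 0.5 %
pepsin, 0.1 M HCl); juice flow follows
`R·1.5·(1 − (5.5 − pH_antrum)/(5.5 − pH_target))` mL/min with target
antral pH 1 and the duodenal protection factor
`R = clamp₀¹(1 − e^(2 − pH_duodenum))`. The fundus is a pressure
reservoir taking corpus overflow (capacity 250 mL) and returning it at
30 mL/min. Gastric tone is
`3 + 0.0117·V_stomach·(CCK/(CCK+1))⁴` mBar and sets the target antral
volume `VaT = 5 + 60·tone/(5 + tone)` mL.

The three compartments exchange volume in a repeating peristaltic cycle,
three cycles per minute. In the first two cycle-thirds the corpus pumps
chyme toward the maximum antral volume (60 mL); in the third the antrum
partially refluxes to the corpus — grinding its solids with the gastric
breakdown time constant — and empties its excess over the target volume
through the pylorus: `J = max(0, V_antrum − VaT)·F` per cycle-third, plus
a basal first-order liquid emptying (20 % of antral volume per
cycle-third, throttled by the same pyloric restriction as `√(F/p)` so
one valve governs all flow while fasted residues still clear).
`F = p/ΣEIS` (p = 0.6, the sum floored at 1) with
emptying-inhibiting stresses of the form `max(0, (signal − θ)/s)` for:
serum CCK, the nutrient osmolarity of the proximal small intestine, low
proximal-duodenal pH, serum GLP-1, and antral viscosity under tone.
Secreted fluids are treated as isotonic electrolyte solutions, so the
osmotic signal is the *nutrient* osmolarity on top of that background;
polymers (starch, maltodextrin, proteins) are osmotically inert until
hydrolyzed, but raise the viscosity signal instead (thickener-dominant
power blend of dissolved polymer content). The entire pyloric outflow is
additionally damped by the energy density of the antral chyme
(`1/(1 + 6·kcal/mL)`), the model's rendering of duodenal caloric
receptors: plain fluids empty fast, energy-dense chyme is metered out.
While a meal is being eaten the fundus accommodates (receptive
relaxation): pyloric outflow is suppressed to 25 % and relaxes back with
a 15-min recovery after the last bite — this is what makes slower eating
finish gastric clearance later and delay the post-meal hunger return.
Only the liquid phase and sub-sieve (< 2 mm) particles pass the pylorus.
During fasted MMC phase-III bursts the antrum is swept down to the basal
target volume.

The excess-over-target form of J is one reading of an ambiguous
emptying relation; it makes emptying rise with overfilling and stop at
the target, and is the reading adopted throughout.

## Secretions and transit

Hepatic bile (basal 0.25 mL/min, plus secretin-driven salt-independent
and recycled-salt-dependent flow at 1 % bile salt) fills the gallbladder
when fasted (capacity 50 mL) and passes through while the gallbladder
contracts exponentially (τ = 15 min) once CCK exceeds 0.3 ppm. Bile
salts resorbed in the ileum return to the hepatic pool (enterohepatic
loop); de-novo synthesis tops the circulating pool up to 4 g. Pancreatic
juice enters past the sphincter of Oddi: water and bicarbonate
(~140 mM) scale with secretin, enzymes (amylase, trypsin-like protease,
lipase, plus the tracer peptide) with CCK, all clamped at maxima.
Intestinal walls secrete water/bicarbonate/mucus as a guess function,
`k₁·secretin + k₂·max(0, 7 − pH)` per unit, plus a small basal flow.

Transit between intestinal units is first-order, `V_i/τ_i` (duodenal
units 15 min, jejunal/ileal 30 min, colon 24 h), scaled by the
ileal-brake factor `g = 1/(1 + 1.2·ΔPYY + 0.8·ΔGLP1)` and by the MMC
multiplier (4 during fasted phase-III episodes, which recur every
~100 min after a 90-min fasted delay while motilin is elevated).

## Mucus layer, enzymes, absorption

Each small-intestinal unit is lined by an unstirred mucus layer
(50–150 µm, thicker distally) over the epithelium. Solute concentrations
at the brush border solve the quasi-steady flux balance
`(D_eff·A/h)(C_lum − C_bb) + v_w·C_lum = uptake(C_bb)` by monotone
bisection; `D_eff` folds a ×3 villous-stirring enhancement into the
mucus diffusivity, and the epithelial water fluxes v_w sum to
6.25 mL/min (≈ 9 L/day) distributed by compartment area. Inside the
engine, `uptake` is the *realized* (competition-corrected) uptake using
the previous step's G, since that is what the epithelium actually
removes; when delivery outpaces the capped uptake the surface
concentration rises above the luminal one (concentration polarization —
pronounced for the glucose drink, absent for the solid meals). The
layer has no storage, so lumen→epithelium mass bookkeeping is exact.

Hydrolysis is Michaelis–Menten with inhibitors,
`v = E·Vmax·S/(Km·α + S·α′)` (α competitive, α′ uncompetitive occupancy
sums), times a trapezoidal pH-activity window (pepsin full between pH
1.5–3.5 with shoulders to 0.5/5.5; pancreatic enzymes neutral-optimal).
Luminal reactions: pepsin and the pancreatic protease (protein →
peptides → amino acids), α-amylase (starch → maltodextrin → maltose,
slowly digestible starch at one-fifth the Vmax, competitively inhibited
by L-arabinose), and bile-enhanced lipase (TG → DG → MG + fatty acids);
released long-chain fatty acids pair with bile salts 5:1 into micellar
complexes. Brush-border enzymes (maltase, sucrase, glucoamylase,
α-dextrinase) act on surface concentrations, with uncompetitive
L-arabinose inhibition of sucrase and maltase; their levels decline
distally along the tract. Every hydrolysis books its water uptake
(e.g. 342 g sucrose + 18 g water → 360 g monosaccharides), so mass is
conserved exactly. Kinetic constants are a documented default table at
plausible duodenal activity levels, not literature truth; all are
configurable.

Absorption per unit: glucose via SGLT-1 (Km ≈ 2 mM), fructose via the
lower-capacity GLUT5, amino acids and small peptides via a pooled
carrier, micellar fat species via their own pathway, plus passive
permeability terms. Carbohydrate and protein carriers are
high-capacity: the operative per-compartment limit is the caloric
ceiling M = 1 kcal/min acting through the competition factor
`G = M/(T + M)`, where T is the summed uncompeted caloric demand —
realized uptake approaches M from below under overload. Fat pathways
are interfacially limited (slow) so meal lipids persist into the distal
small intestine and feed the ileal-brake receptors. Water is
co-absorbed at 0.2 mL/kcal on top of the baseline epithelial flux,
which stops at a 3-mL residual film so fasted compartments do not run
dry.

## Hormones, glucose homeostasis, sensations

Serum hormones follow exact first-order kinetics with degradation
constants CCK 1/3.3, PYY 1/10, GIP 1/7.2, GLP-1 1/2.3, ghrelin 1/10,
motilin 1/15 and secretin 1/2.5 min⁻¹ (midpoint of the quoted 1/(2–3)
range). Hormone units (ppm) are abstract, normalized so 1 ppm CCK is the
half-activation of the gastric tone response; absolute baselines and
stimulus gains are calibration constants. Nutrient-driven secretion
saturates with receptor occupancy: CCK from fat/protein digests at the
duodenal/jejunal brush border; GLP-1 and PYY from the luminal caloric
concentration seen by the L-cell field (distal jejunum, ileum, colon —
intact fat included, since with realistic uptake capacities digested fat
never reaches a purely ileal surface sensor); GIP tracks portal glucose
delivery (reporting only — the optional `gip_incretin_effect` hook that
would let GIP amplify insulin secretion is off by default); secretin
tracks duodenal acidity; gastrin rises with gastric distension and
peptides and is shut off by a strongly acidic antrum (its acid-promoting
action is folded into the target-pH secretion control); motilin and
ghrelin ramp up only in the fasted state (6-h ramp) and are suppressed
by feeding. Fasted motilin drives the migrating motor complex: phase-III
bursts begin 75 min after the fed state ends and recur every 100 min,
multiplying transit rates and sweeping the stomach.

Glucose homeostasis is a portal/liver/periphery loop: absorbed glucose
(plus half of absorbed fructose) enters the portal pool; the liver
passes glucose to the peripheral pool while producing glucose itself
(0.7 mmol/min basal), suppressed by peripheral insulin acting with a
fixed 36-min delay (ring buffer at step resolution); peripheral
utilization grows with glucose and insulin; insulin secretion rises with
peripheral glucose (quadratic above basal) and with the
portal–peripheral difference, cleared at 0.2 min⁻¹. Basal levels
(5 mmol/L, 10 mU/L) are an exact fixed point at zero inflow. The
insulin-lagged utilization produces the post-absorptive glucose
undershoot seen after rapidly absorbed loads.

Sensations are bounded visual-analog scores: fullness saturates with
gastric volume (Hill exponent 2, half-volume 250 mL) amplified by tone
above baseline; hunger rises with ghrelin (half 1.5 ppm) and is damped
by fullness; discomfort scores tone above 10 mBar.

## Calibration and what the fixtures show

Constants the underlying physiology does not pin down (EIS thresholds
and scales, the pyloric constant p, the caloric damping, hormone gains,
kinetic tables) were calibrated once against the model's own reference
conditions: a feedback-stabilized caloric emptying plateau near
2 kcal/min for all three reference meals, complete absorption of a 50-g
glucose drink around 100 min, and the qualitative hormone orderings
(CCK only for fat/protein meals, sustained GLP-1/PYY only when nutrients
reach the distal gut, a lower insulin peak for the slower-breaking pasta
meal, MMC episodes only when fasted). They are not independent
literature estimates, and the test suite pins behavior to these
defaults, not to clinical truth.

The synthetic meal fixtures emulate meal composition, texture and
schedule; they do not emulate inter-individual variability, nutrient
micro-structure, microbial fermentation, or measured serum hormone
units. Passing tests therefore demonstrate internal consistency and the
mechanisms' qualitative fidelity, not quantitative prediction for any
real subject.

## Numerical choices

1-s internal linearized stepping with per-minute reporting; halving the
step changes the reference glycemic trajectory by well under 1 %.
Monotone bisection everywhere a balance is solved (pH, brush border):
unconditionally convergent, 30–60 iterations. Transit fractions are
capped at 50 % per step for stability; hydrolysis and uptake are capped
at substrate/water availability; a negative-mass guard aborts the run
(none occurs at the default step). The global ledger (ingested +
secreted = luminal + absorbed + excreted + stored) drifts by less than
10⁻⁹ relative over the reference runs. Problem sizes used by the
shipped analyses: 1,100 simulated minutes for the three-meal sequence,
about 200 for the glucose drink, 4,000 for the consumption-rate sweep.

## Known limitations

No electrolyte/osmolyte bookkeeping beyond the nutrient-osmolarity
proxy; no interfacial lipolysis or enzyme denaturation kinetics; no
protease inhibitors (hook excluded by design); gastric lipase omitted
(only pepsin in gastric juice); no chylomicron/lymphatic routing; the
colon is a passive reservoir without microbial fermentation; hormone
levels are unitless and comparable only within a run; the GIP→insulin
incretin pathway is a disabled hook pending a richer glucose model.
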