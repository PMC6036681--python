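# Methods

## Headspace accounting

All gas quantification happens in the headspace of a sealed serum bottle.
Units are mmol, ml, bar, K and h throughout, with
R = 0.0831446 ml·bar·mmol⁻¹·K⁻¹.

**Amounts.** At each sampling event *i* the pre-sampling pressure, the GC
mole fractions (renormalized to sum to 1) and the current headspace volume
give per-species amounts `n_j(i) = x_j · P_before · V_h / (R·T)`.
Incubation-phase readings are converted at the incubation temperature
(default 333.15 K); the initial fill state is characterised at the fill
temperature (default 298.15 K) and fill pressure (1 bar) — a 50 % air fill
of a 200 ml headspace then holds 0.85 mmol O₂, which is the convention the
whole pipeline is anchored to. Both temperatures are configurable.

**Withdrawal correction.** The gas removed at event *k* is
`x_j(k)·(P_before − P_after)·V_h/(R·T)`, i.e. the pressure drop measured
with the manometer, not the nominal syringe volume, split by the same
event's GC composition. "Produced/consumed" is defined *net of sampling*:
withdrawn gas is credited back, so `Q_j` tracks what reactions inside the
bottle did. When `P_after` is missing, the nominal draw
`P_after = P_before·(1 − v_gas/V_h)` is assumed with a logged warning.

**Headspace growth.** Each liquid draw (default 1 ml) permanently enlarges
the gas phase; dissolved-gas content of withdrawn liquid is ignored — there
is no liquid-phase state (no Henry's-law partitioning, no CO₂/bicarbonate
speciation). The inert-N₂ balance doubles as a leak/consistency flag: on
clean data |Q_N2| stays within GC noise.

**Summaries.** Yield = `Q_H2/(−Q_CO)` at the final point (defined only when
CO was net consumed; displayed rounded to 2 d.p., computed at full
precision). H₂ onset is the first sampling with `Q_H2` strictly above a
threshold (default 0.02 mmol ≈ GC detection floor for these bottles); O₂
depletion is the first sampling with headspace O₂ strictly below 0.05 mmol.
Both thresholds are conventions, exposed as CLI flags. Growth summary
reports the maximum OD₆₀₀ over sampled points (earliest time on ties) and
the last recorded OD.

## Simulator

The simulator is the package's synthetic-data generator: a deterministic
ODE model whose observation layer emits the exact measurement-table
structure the accounting consumes, so the pair forms a closed
generate-and-recover loop with known ground truth.

State: biomass X (OD₆₀₀ units — no dry-weight conversion), headspace
amounts of H₂/O₂/N₂/CO/CO₂, and a formate pool F, plus five cumulative
pathway extents (WGS, respiration, aerobic CO oxidation, CO loss, FHL)
integrated alongside. Kinetics act on partial pressures
`p_j = n_j·R·T/V_h`; gas–liquid transfer is lumped into the apparent rate
constants. With `f_j = p_j/(K_j+p_j)` and the O₂ inhibition factor
`I = K_I_O2/(K_I_O2+p_O2)` the rates are: Monod aerobic growth
(`mu_max·f_O2·X`) with an anoxic decline term (`k_d·(1−f_O2)·X`),
respiration (`q_o2·f_O2·X`, emitting `y_co2_per_o2` CO₂ per O₂),
O₂-inhibited WGS (`q_wgs·f_CO·I·X`, 1 CO → 1 CO₂ + 1 H₂), an FHL route
(`q_fhl·I·F/(K_F+F)·X`, 1 formate → 1 CO₂ + 1 H₂) gated by the same O₂
inhibition as the anaerobic CODH–hydrogenase couple, aerobic CO oxidation
(`q_aco·f_CO·f_O2·X`, consuming 0.5 O₂ per CO) and a first-order aerobic CO
loss (`k_co_loss·f_O2·n_CO`). Carbon bookkeeping is exact by construction:
CO consumed equals CO-derived CO₂ produced.

**Integration.** Fixed-step classical RK4, default 0.01 h, with sampling
events handled exactly at the scheduled times; fixed-step was chosen over
adaptive integration for bit-reproducibility of the emitted datasets (an
adaptive reference integrator is used as an oracle in the tests). Each
interval is subdivided so the step never exceeds the configured value.
Monod saturation keeps states non-negative; any excursion beyond −1e−9 is
an error, and sub-roundoff dips are clamped to zero.

**Observation layer.** At each sampling: record pressure, fractions and OD
(optionally noisy: additive Gaussian on pressure and OD, multiplicative
Gaussian on fractions followed by renormalization, all from one seeded
generator); physically remove `P·v_gas/(R·T)` moles split by the *true*
composition; record the after-pressure at the same headspace volume (so the
pressure pair is exactly the withdrawal the accounting reconstructs); then
enlarge the headspace by the liquid draw. With noise off the output is an
exact function of the trajectory. If noise inverts the recorded pressure
pair, the after-reading is clipped to the before-reading.

**Presets.** Four scenarios share the default bottle (250 ml / 50 ml,
1 bar fill at 298.15 K, incubation at 333.15 K, 3 ml gas + 1 ml liquid per
event, 18 sampling events over 84 h, denser while the culture is aerobic
and around the reported event times):

* `dsm2542` — WGS-active strain. Initial CO 3.20 mmol and O₂ 0.85 mmol
  (the balance of the 8.07 mmol fill is N₂); formate pool 0.19 mmol so
  that H₂ = WGS + FHL = 2.28 + 0.19 = 2.47 mmol, the supra-equimolar 1.08
  yield.
* `toebii` — control with aerobic CO oxidation only (initial O₂
  0.66 mmol); consumes ~0.37 mmol CO while O₂ lasts, no H₂.
* `thermodenitrificans` — control with only the first-order CO loss
  (initial O₂ 0.83 mmol); ~0.216 mmol CO, no H₂.
* `abiotic_control` — all rates zero; only sampling acts on the bottle.

No rate constants are available for these cultivations, so all kinetic
values are calibration artifacts, not measurements: they were fitted once
so that the *analysis pipeline applied to the noise-free synthetic data*
reproduces the reported endpoint amounts (CO consumed, H₂ and CO₂
produced, growth maxima, H₂ onset), then frozen. Two modelling consequences
are worth flagging. First, growth in this model is limited only by O₂, so
a biomass peak at ~6 h forces near-complete O₂ exhaustion by ~6 h; the
observed multi-hour lag between O₂ depletion and H₂ onset is then carried
by the deep exponential O₂ tail against a very small inhibition constant
(`K_I_O2 ≈ 7e−27 bar` in the `dsm2542` preset). That constant is an
*effective anoxia switch*, not a physiological affinity — the model
reproduces the observable event sequence, not the literal trace O₂
concentration between the two events. Second, `y_co2_per_o2` absorbs CO₂
dissolution and carbonate chemistry, which are not modelled; it is fitted
per scenario (0.34–0.45).

**What the synthetic data does not emulate.** Replicate-to-replicate
biological variability (presets are single deterministic bottles), GC drift
and calibration bias (noise is unbiased), liquid-phase gas dynamics, CO
toxicity, and substrate (medium) limitation of growth. Passing the
recovery tests therefore demonstrates that the accounting is correct under
withdrawals and realistic unbiased noise — not that the kinetic constants
are transferable to real cultures.

## Locus genomics

Pairwise protein comparison is Smith–Waterman local alignment with affine
gaps via the Gotoh three-state recursion: BLOSUM62, gap open 11, extend 1,
where a gap of length k costs `open + (k−1)·extend`. Among equal-scoring
alignments the one ending at the smallest (row, column) is reported;
traceback ties prefer substitution over a gap in the query over a gap in
the subject. Identity is counted over aligned residue pairs only (gap
columns excluded from numerator and denominator); coverage is the aligned
span over the full sequence length. The orthology rule is strict:
identity > 30 % *and* query coverage ≥ 70 % (an option requires subject
coverage too — the choice of query coverage is a convention, since
coverage direction is ambiguous in common usage). Locus-vs-locus pairing
is by reciprocal best score with lexicographic-id tie-breaks, each protein
in at most one pair; AAI is the arithmetic mean identity over the
orthologous pairs. G+C content excludes N from the denominator, and locus
G+C deviation is reported signed, in percentage points against a supplied
genome average.

The fixture mutator substitutes residues at seeded random positions
(monotone in the substitution count via a fixed permutation) until the
identity *realized by the aligner itself* is within ±2 points of the
target; it verifies rather than assumes, because local alignment trims
divergent ends and raises realized identity above the naive substitution
fraction.

Validation is oracle-based: exhaustive enumeration of all gapped local
alignments for sequence pairs up to length 5, and an independent
cross-check of scores against Biopython's `PairwiseAligner` on longer
random pairs. Exact AAI values for real loci depend on BLAST's heuristics
and the real genome sequences, which are outside this package's scope; the
module is validated on synthetic fixtures.

## Numerical conventions and limitations

* Problem sizes: 84 h scenarios at 0.01 h steps (≈ 8 400 RK4 steps) run in
  well under a second; the whole test suite, including a 20-replicate
  noise study and the alignment enumeration oracle, runs in a few seconds.
* Summaries are full precision internally; display rounding (2 d.p.)
  happens only in the JSON/human summary layer.
* TSV dialect: UTF-8, tab-separated, Unix newlines, decimal point, `NA`
  for missing; floats are written as shortest round-trip representations
  and parsed with round-trip precision, so write → read is exact.
* The CLI subcommands are deterministic given `--seed`; zero-noise
  simulations are bit-reproducible and do not consume random numbers.
* No parameter-fitting routines are shipped (presets are constants), no
  leak estimation beyond the N₂ drift flag, no E-value statistics or
  database search on the genomics side.
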