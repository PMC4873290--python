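# Methods

Modeling conventions, numerical choices and their rationale. Units
throughout: biomass in t·km⁻², rates in yr⁻¹, flows in t·km⁻²·yr⁻¹.

## Mass balance

For each living group *i* the master equation

```
B_i (P/B)_i EE_i = Σ_j B_j (Q/B)_j DC_ij + Y_i + E_i + BA_i
```

partitions production into predation (summed over consumers *j*), catch
`Y`, net migration `E` and biomass accumulation `BA`; the unused remainder
`(1 − EE) P` flows to detritus. Exactly one of `{B, P/B, EE}` may be
unknown per living group (`Q/B` unknowns are not solved for). Unknown
biomasses couple groups, so they are assembled into one linear system and
solved with `numpy.linalg.solve`; a rank check names the groups involved
when the system is singular (e.g. two consumers with identical balance
equations). Known-`B` groups then get `EE` (or `P/B`) by direct
substitution. `EE > 1` is never clipped: it is reported as a diagnostic,
because it is the signal that predation plus catch exceed production.

Residuals of the master equation are retained on the solved model; the
test suite requires them below 1e−9 on generated webs.

## Flow network

Flows are `T_ij = B_j (Q/B)_j DC_ij`. Consumer respiration is
`Q (1 − GS) − P` with `GS` the unassimilated fraction (default 0.2);
negative respiration is a hard error, since it means a group produces more
than it assimilates. Producers respire nothing; their primary production
enters the network as an import. Flow to detritus is `GS·Q + (1 − EE)·P`;
detritus pools route their surplus (inflow minus consumption) to export.
Total system throughput (TST) is the sum of consumption, exports,
respiration and flows into detritus.

## Trophic analysis

Trophic levels solve the linear system `TL_j = 1 + Σ_i DC_ij TL_i` with
producers and detritus fixed at 1. Diet imports are treated as
trophic-level-1 food by default (`import_tl="producer"`); the alternative
(`"exclude"`, renormalizing internal diet) is provided because the
convention is not universal. A fixed-point iteration of the same map is
kept as an independent oracle; the two must agree to 1e−8.

The omnivory index is the diet-weighted variance of prey trophic levels
around `TL − 1`. The mixed trophic impact matrix uses
`q_ij = DC_ij − F_ji` (diet minus the predation-mortality fraction) and
`M = (I − q)⁻¹ − I`. Keystoneness is
`KS_i = log10(ε_i (1 − p_i))` with `ε_i` the root-sum-square of group *i*'s
impacts on the other groups and `p_i` its share of living biomass; ranks
are descending with ties broken by name so output is deterministic.

## Network indices

- **Connectance**: realized fraction of possible links among living
  groups, excluding cannibalism, `links / (N (N − 1))`.
- **System omnivory**: consumer omnivory indices weighted by
  `log(B · Q/B)` with a floor of `log(1.01)`. Note this weighting makes
  the index depend on absolute flow magnitude by definition, so it is
  excluded from the scale-equivariance property test.
- **Ascendency / capacity / overhead**: computed on an extended flow
  matrix bordered with an import row and export and respiration columns.
  Both A and C are homogeneous of degree 1 in the flows, so their
  percentages are scale-free.
- **Finn cycling**: with `G_ij = T_ij / inflow_j` and
  `L = (I − Gᵀ)⁻¹`, the cycled part of compartment *i*'s inflow is
  `(L_ii − 1)/L_ii · inflow_i`; the cycling index is its share of TST.
  Mean path length is `TST / (exports + respiration)`.

## Empirical estimators

Log-linear regressions with all coefficients exposed as configurable
presets: asymptotic length from maximum length
(`log10 L∞ = 0.044 + 0.9841 log10 Lmax`), natural mortality from
`L∞`, growth `K` and temperature (Pauly), and consumption rate from
asymptotic weight, temperature, caudal-fin aspect ratio and feeding habit
(Palomares–Pauly). At equilibrium `P/B` is equated with total mortality.
Default temperature is 27 °C (tropical shelf).

## Catch-only estimation

Schaefer surplus production `B' = B + rB(1 − B/K) − C` coupled to effort
dynamics `h' = h (1 + x (B/(aK) − 1))` with `h` the harvest rate, `x` the
effort responsiveness and `aK` the bioeconomic-equilibrium biomass.
`h₀` is set so the first observed catch is matched exactly. Draws of
`(r, K, B₀/K)` from configurable priors are propagated with observed
catches; trajectories that go non-positive or exceed `K (1 + ε)` are
rejected, survivors weighted by a lognormal likelihood of the observed
catches, and resampled to equal weights (SIR). Everything is vectorized
over draws; 10⁴ draws over 15 years fit in well under a second. Collapse
in the forward simulator requires the effort feedback to drive `h > 1`
(catch proportional to biomass cannot reach zero on its own); such runs
are truncated and flagged.

Recovery is validated by simulating catches at known `(r, K)` and checking
the posterior median (within 25%) and credible-interval coverage
(≥ 80% nominal, over 50 replicates).

## Elicitation

Two-round Delphi-style records; round-2 answers supersede round-1.
Consensus requires at least half the panel to agree — within ±20% of the
median for numeric answers, exact match for categorical ones; with 23
panelists, 12 agreeing responses pass and 11 do not. Aggregation reports
mean, sample standard deviation (ddof = 1) and n. Parameter classes judged
unreliable (daily ration, longevity, qualitative stock/catch trends) are
excluded from the export that feeds the food-web model unless explicitly
requested. Panel agreement uses `scipy.stats.spearmanr` (constant vectors
rejected) and a paired t statistic with `df = n − 1` (±inf sentinel when
differences are constant and nonzero).

## Synthetic webs

The generator builds `n` groups in trophic bands with diets pointing
strictly down the bands, draws `P/Q` inside a configurable band
(default 0.1–0.3), then fixes biomasses bottom-up so each group's EE stays
at or below a cap (0.98). Because predators sit in strictly higher bands,
one bottom-up pass suffices and the construction EE values are exact —
they serve as an oracle for the solver. All randomness flows from a single
seed; equal seeds give identical webs. Synthetic interview panels add
mean-one lognormal noise to true parameter values, with round-2 dispersion
shrunk toward the round-1 median.

## Bundled dataset and its limits

The bundled 25-group shelf-fishery table carries `B`, `P/B`, `Q/B` for a
science-based and a fishers'-knowledge parameterization. The corresponding
published diet matrices exist only as journal supplementary material and
are not redistributable here; a clearly labelled synthetic stand-in diet
supplies web structure. Consequences:

- Quantities depending only on the basic table reproduce published values
  (net primary production 3754.46; PP/biomass 19.14 vs 19.16 printed —
  the ~0.1% gap traces to rounding in the printed biomass total).
- Diet-dependent acceptance checks (trophic levels, omnivory, connectance,
  Finn cycling of the case study) are implemented but red until a
  transcription is placed at `tests/fixtures/baia_formosa_diet_{sc,fk}.csv`.

## Problem sizes and budgets

Webs of ~25 groups solve in milliseconds; the 100-web property sweep runs
in seconds. The full test suite, including the 50-replicate catch-only
coverage experiment at 10⁴ draws, completes in well under a minute on one
CPU.
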