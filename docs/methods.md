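# Methods

This note documents the models, calibration procedures, statistical choices
and known limitations of `clamap`. Everything quantitative stated here is
computed by the test suite or the acceptance script; nothing is asserted
about real recordings beyond what the packaged reference table contains.

## 1. Circuit space

Five frontal input regions {ACC, plPFC, ilPFC, OFC, aINS} cross seven output
regions {ACC, plPFC, ilPFC, OFC, RSC, PtA, V1/V2}: 35 circuits. aINS is
never an output (no claustrum neurons project there). Four circuits are
homoloquial (input = output: ACC, plPFC, ilPFC, OFC), 31 heteroloquial.
Laterality (contralateral return for homoloquial circuits) is carried as
nomenclature only — no computation depends on it.

## 2. Synthetic electrophysiology

### Response model

One sweep = 650 ms at 10 kHz: a 100 ms pre-stimulus baseline, three 5 ms
light pulses at 150 ms intervals (onsets 100/250/400 ms), and a tail that
contains the decay of the last response. The subthreshold response to the
pulse train is

    V(t) = V_rest + w · I · Σ_p K(t − t_p) + ε(t),

with `w` the cell's synaptic weight (mV/mW), `I` the light intensity (mW),
`K` a peak-normalized difference-of-exponentials kernel and
ε white Gaussian noise (default SD 0.5 mV, small relative to the planted
effects). Hyperpolarizing excursions are floored at the inhibitory reversal
potential (−75 mV); with the calibrated weights the floor is never reached,
so the envelope stays linear in `w`.

Kernel time constants default to rise 2 ms, decay **50 ms**. The decay is
deliberately slower than a unitary cortical EPSP: the printed AUC magnitudes
(up to ~3,000 mV·ms over a 440 ms integration window) can only arise from a
compound envelope — summed mono- and polysynaptic depolarization and burst
afterdepolarization — and a 20 ms decay would force subthreshold envelope
peaks above 0 mV, corrupting threshold-based spike detection. With 50 ms the
strongest calibrated envelope peaks near −33 mV. Both constants are
config-exposed.

### Spiking

Firing is decided deterministically on the noiseless drive
`g · w · I · K_p` (`g` = spike gain, `K_p` = per-pulse envelope peak; later
pulses ride on earlier tails, so their peaks slightly exceed 1 and the exact
values are used). A pulse elicits an event when the drive reaches the
distance from rest to the action-potential threshold (default −40 mV, i.e.
θ = 30 mV). Type I cells emit one spike per event. Type II cells emit their
full burst (default 3 spikes, 3 ms apart) when the drive also clears
`burst_drive_ratio · θ`, otherwise a single spike — the two-threshold form
decouples *activation reliability* from *burst amplification* (see §3).
Spikes are superimposed on the trace as stereotyped 1 ms triangular
excursions to +30 mV; anything crossing-detectable would do.

The classification sweep (brief 2 ms depolarizing step) is generated
directly: one spike for type I, a burst for type II; every projection
neuron spikes to the step. Membrane capacitance is drawn uniformly from the
subtype range (type I 75–130 pF, type II 130–200 pF) and used as a
consistency check, never as the classifier.

### Between-cell variability and QC

Per-cell weights are lognormal, `|w| ~ LogNormal(mean = |w̄|, CV)`, sign
taken from the circuit weight. QC metadata (resting-Vm drift, access and
membrane resistance changes) are drawn clean by default; a configurable
contamination rate plants disqualifying values. The discard rules are
strict inequalities: drift > 10 mV, either resistance change > 15%.

## 3. Calibration to the reference table

The packaged reference (`circuit_strength_reference.csv`) holds the
published mean ± SEM of AUC and APs/pulse for all 70 (circuit, subtype)
combinations (n = 15 each). Calibration proceeds per combination:

1. **Weight.** The intensity-averaged unit-weight AUC constant `C` is
   measured once by simulating a noiseless unit response and integrating it
   with the same trapezoidal rule and windows as the analysis, so
   `w̄ = AUC_target / C` is exact by linearity. A ≤4-step fixed-point
   refinement against the noiseless forward map (spikes included, gain
   co-scaled so `g·w` is preserved) absorbs the action-potential waveform
   area; the noiseless simulate-then-measure round trip then reproduces all
   56 non-aINS AUC targets to ≲0.1% (the acceptance tolerance is 5%).
2. **Between-cell CV** is taken from the table itself:
   `CV = SEM·√n / |mean AUC|`, clipped to [0.1, 1.2] — the lognormal weight
   model cannot represent the sign-mixed populations implied by near-zero
   means, hence the cap. This reproduces the heterogeneity of the printed
   standardized effects (simulated mean/SEM correlates ≈0.8 with the
   printed mean/SEM landscape).
3. **Spike gain and burst threshold.** The expected APs/pulse has a closed
   form under the lognormal weight distribution (a sum of lognormal survival
   probabilities over intensities and pulses). The APs budget is split into
   reliability `r` (expected events per pulse) and burst amplification:
   `r = min(aps_II, max(2·aps_I, aps_II/b))` for type II (b = burst count),
   `r = aps` for type I. The gain is solved (Brent) so the expected event
   rate equals `r`; the burst threshold ratio is solved so total expected
   APs equal the target. The split is *not* identified by the mean APs
   alone; the factor 2 expresses that type II's larger APs reflect both
   more reliable activation and bursting. Where the printed type I APs
   exceed type II's (a single weak circuit, OFC→CL→ACC, both means within
   ~2 SEM of zero) the type II reliability is floored at the type I level,
   honoring the published finding that no circuit preferentially activates
   type I neurons.
4. **aINS inputs** are forced to weight 0 and gain 0 — the published
   recordings show no observable postsynaptic responses for aINS inputs.
   The nonzero aINS AUC entries in the reference are the recording noise
   floor and are deliberately not reproduced; the simulator's aINS circuits
   yield zero-mean AUC.

`planted_effect_table(inputs, outputs, effect_size)` builds the synthetic
benchmark condition instead: member circuits receive a depolarizing weight
with CV = 1/effect_size (so the per-cell AUC one-sample standardized mean is
the requested size; the integration-noise floor is negligible at the default
mean AUC of 1,000 mV·ms), all other circuits are silent.

## 4. Trace metrics

- **Spike detection**: upward crossings of 0 mV separated by ≥2 ms
  (standard crossing detection; unspecified parameters, config-exposed).
- **APs/pulse**: spikes inside per-pulse windows of 140 ms after onset
  (strictly inside the 150 ms interval), divided by the number of pulses.
- **AUC**: baseline = mean of the 100 ms pre-stimulus window; trapezoidal
  integral of the baseline-subtracted trace from the first onset to 140 ms
  past the last onset (one contiguous window, so inter-pulse tails are
  retained). Spikes are included by default — with the calibrated tables
  this biases spiking circuits' AUC upward by at most ~4%, inside the 5%
  calibration tolerance — and a `clip_spikes` flag interpolates them away.
- **Binary response**: per intensity, the indicator of ≥1 spike in any
  response window; averaged over the six intensities (so the maximum is
  5/6 when the 0 mW sweep is included, as it is throughout).
- **Cell means** average over exactly the protocol's intensity set,
  including the 0 mW sweep.

## 5. Strength matrix

Per (metric, subtype, input, output): the per-cell value list, mean,
SEM = sd/√n and n of QC-passing cells. All 70 entries exist for each metric;
entries with n < 2 report a mean only and are excluded from inference. The
summary CSV is schema-identical to the reference table for direct diffing.

## 6. Inference

### Biclique scan

Candidates: all input-subset × output-subset bicliques (3,937 for the full
design — trivially enumerable, so the search is exhaustive; a greedy grower
is available but off by default and uses the same exhaustive null).
Per-circuit statistic: the one-sample standardized mean t = x̄/(s/√n).
Score: cluster mass Σ(t − τ) over members with cluster-forming threshold
τ = 2 (config). The threshold matters: with a plain sum, extending a true
cluster by any null circuit raises the score half the time and the argmax
would almost never be the exact planted set; with τ = 2 null circuits
contribute negatively in expectation and planted bicliques of per-circuit
size ≈2 (n = 15) are recovered exactly in ≳90% of runs.

Null: cell-to-circuit assignments are permuted uniformly within subtype and
metric, preserving per-circuit n — the strongest reading of "no circuit is
significant" that preserves the pooled value distribution (sign-flipping
would instead assume symmetric per-cell effects). FWE control: the observed
best score is compared with the permutation distribution of the maximum
score over all candidates; p = (1 + #{max ≥ observed})/(B + 1). B must be
≥ 1/α for α to be resolvable (B = 5,000 at α = 0.001 by default). Under the
global null, exchangeability makes P(p ≤ α) ≈ ⌊α(B+1)⌋/(B+1), verified
empirically in the suite; on instances small enough to enumerate every
distinct reassignment, the Monte-Carlo p matches the exact permutation p.

On data calibrated to the full reference table, every non-aINS circuit has
a genuinely nonzero mean with t ≈ √15/CV ≳ 3, so the scan correctly reports
a near-complete subgraph. The selective frontal subgraph in the published
analysis reflects variability structure of the undeposited raw data (and an
unspecified author-side statistic) that summary statistics cannot pin down;
reproducing those exact printed clusters and effect sizes is explicitly out
of scope. The planted-cluster condition is therefore the quantitative
benchmark for the detector.

### Effect sizes and group comparisons

Cohen's d uses the pooled-SD formula. The reference group is the matched
cells' 0 mW AUC values (the published baseline is unstated; this choice is
config-visible, and a one-sample standardized mean is used when no
reference is available — both are flagged, and the printed d values are not
reproduction targets). Subtype comparisons are two-sided Wilcoxon rank-sum
tests on the binary response with midranks for ties; the default p-value is
an exact Monte-Carlo permutation of group labels over the fixed ranks
(20,000 resamples, seeded) because with heavily tied near-zero data the
asymptotic normal approximation is measurably anti-conservative. Direction
is assigned by mean ordering when p ≤ 0.05; fully tied circuits are flagged
with p = 1. Raw p-values are primary; a Benjamini–Hochberg column is
emitted alongside. The omnibus test is Kruskal–Wallis across circuits
(midrank tie correction, χ² reference with groups − 1 df).

## 7. Problem sizes used in the shipped checks

The test suite simulates the full 1,050-cell study once (shared session
fixture), runs the planted-recovery check at n = 15 per circuit with 2,000
permutations, the null-calibration check on 250 metric-level null datasets
at 200 permutations, and the exhaustive-permutation equivalence on a
4-circuit instance with 2,520 distinct reassignments. The acceptance script
uses 525 cells and 5,000 permutations. These sizes were chosen to estimate
each quantity well inside its tolerance; all are parameters, not limits.

## 8. Known limitations

- The trace model is phenomenological: no conductances, no short-term
  plasticity across the three pulses, no latency jitter, no correlated
  (synaptic) noise, no optical power calibration. Passing tests demonstrate
  the *analysis* behaves correctly on data with the assumed statistical
  structure, not that real claustrum recordings follow that structure.
- Firing is deterministic given a cell's weight; real trial-to-trial
  spiking variability would spread binary responses within cells.
- Lognormal weights cannot produce sign-mixed cell populations within one
  circuit, so near-zero-mean circuits (printed CV ≫ 1) are represented with
  a capped CV and a single response sign.
- The reliability/burst split (§3) and the Cohen's d baseline are modeling
  choices the published summary statistics cannot identify; both are
  config-exposed and documented rather than claimed to match the original
  analysis code.
- Whether the published AUC was integrated per-pulse or over the whole
  sweep, and whether spikes were clipped, is unstated; both are flags with
  the defaults above.
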