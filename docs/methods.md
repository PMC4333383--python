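# Methods

## Exchange model

Each protein state is an `ExchangeModel`: per-residue intrinsic rates
`k_int` (default a single base rate of 1 s⁻¹; absolute chemistry is not the
signal of interest — state *differences* in protection are), per-residue
protection factors `P ≥ 1`, and optional cooperative (EX1) segments
`(start, end, k_op)`.

* EX2 residues exchange independently: deuteration probability
  `p_i(t) = f_D (1 − e^{−(k_int/P_i) t})`.
* An EX1 segment opens with probability `w(t) = 1 − e^{−k_op t}`; opened
  molecules carry all segment amides at `f_D`, closed molecules exchange
  EX2-wise under their protection factors.  Segments exchange completely
  upon opening — the simplest kinetics that produces the observed bimodal
  envelopes; partial intra-segment kinetics is out of scope.
* Exchangeable amides: `N_exch = L − 1 − #(prolines at positions ≥ 2)`.
  The N-terminal amide is excluded (back-exchanges within seconds); a
  stricter two-residue exclusion is available via `n_term_skip=2`.
  Side-chain deuterons are assumed fully back-exchanged and ignored.
* Back-exchange is per-deuteron Bernoulli survival with probability
  `recovery` (default 0.70, one global value).  For independent labels this
  is exactly equivalent to scaling every `p_i` by `recovery`, which is how
  it is implemented; the equivalence is verified against a binomial-thinning
  oracle in the tests.

The deuteron-count distribution of a peptide is the exact Poisson-binomial
over its EX2 amides convolved with each segment's two-population mixture
(independent blocks ⇒ plain convolution).  Envelopes place the isotopologue
× deuteron-count product grid at 1.00235 Da isotope spacing and 1.00628 Da
per deuteron, merge peaks by nominal index keeping intensity-weighted exact
masses (so centroids are exact), and apply multiplicative log-normal
intensity noise (σ default 0.05) and optional Gaussian m/z jitter (default
off).  Natural isotope distributions are computed by per-element convolution
from the peptide's elemental composition (pyteomics), truncated at 0.999
cumulative probability.

## Study design defaults

Time points 10/30/60/300/900/3600 s; final D₂O fraction 0.80 (the 4 µl +
16 µl mixing arithmetic is provided as `d2o_fraction`); recovery 0.70;
3 replicates; seeds mandatory whenever noise is enabled.  Each peptide ×
state × replicate also gets an undeuterated (t0) envelope and a
fully-deuterated (FD) control (all exchangeable amides at `f_D`, then
back-exchange).

## Uptake quantification

`D_abs` is the centroid shift against the measured t0 baseline of the *same
replicate* (falling back to the state-mean t0; a theoretical undeuterated
baseline is available via `baseline: theoretical`).  Replicate-matched
baselines keep t0 noise inside the per-replicate variance; a state-mean
baseline would shift all replicates of a state together and inflate the
type-I error of the downstream ANOVA.  `D%` divides by
`N_exch · 1.00628 Da · f_D · recovery`; when FD controls are present the
empirical normalisation `100 (c_t − c_0)/(c_FD − c_0)` is recorded
alongside.  Values above 110 % are flagged, never clipped — clipping would
bias differential means.  Uptake time courses are fitted with
`ΣᵢAᵢ(1 − e^{−kᵢt})` (i ≤ 2, Aᵢ ≥ 0) selected by AICc.

## Differential statistics

Per time point, one-way ANOVA across states on replicate `D%`, then Tukey
HSD pairwise p-values (scipy).  The per-peptide summary is the unweighted
mean of per-time-point differences.  Classification: protected if mean
ΔD% ≤ −3 % and min p < 0.04; deprotected symmetrically; otherwise
unchanged.  Both thresholds are configurable; 3 % retains the smallest
protection worth reporting and 0.04 matches the single-star significance
convention.  The effect-size comparison carries a 10⁻³ % numerical guard so
that effects sitting exactly on the boundary are classified reproducibly
despite centroiding round-off.  No multiple-testing correction across
peptides is applied by default, matching per-peptide reporting practice.

## EX1/EX2 classification

Envelopes are deconvolved to deuteron-count distributions by non-negative
least squares against the natural isotope profile (no smoothing; the
reconvolution residual is reported for QC), replicate-averaged, and fitted
per time point with 1- and 2-component Gaussian mixtures on the deuteron
mass axis (EM, 20 random restarts, ties broken toward the lower first mean,
variance floor 0.04 Da²).  Fitting on the deuteron axis rather than raw m/z
makes the call independent of charge state and isotope profile.  BIC uses a
pseudo-count of 200 spectrum-equivalent observations (the distributions are
normalised, so an effective sample size is a modelling choice; 200 reflects
a well-measured envelope and is configurable).

A time point is called bimodal when **all four** gates pass: ΔBIC(2 vs 1) >
10, component separation > 2 Da, minor weight > 0.15, and separation >
2 × RMS component width.  The fourth (resolvability) gate is this package's
addition: on noisy deconvolutions the second EM component can absorb the
noise tail (width ≈ separation), and a broad unimodal envelope can be split
in half — both satisfy the first three gates without being two distinct
distributions.  A peptide is EX1 if ≥ 1 time point qualifies, EX2 if ≥ 2
time points were fittable and none qualifies, ambiguous otherwise (e.g.
point-mass distributions).  Measured operating characteristics at default
noise (500 simulated peptides each, in the test suite): < 5 % false EX1 on
EX2 peptides, ≥ 95 % sensitivity on EX1 peptides with ≥ 8-amide segments
and opened fraction crossing 0.3–0.7 within the time window.

## Surface mapping

Coverage counts covered residues; redundancy counts covering peptides.
Per-residue consolidation averages covering peptides' mean ΔD% weighted by
1/length (shorter peptides localise better).  Interface inference: protected
peptides sharing ≥ 1 residue with an `rna_binding_motif` interval belong to
the RNA footprint; protected peptides overlapping `front_face`/`back_face`
intervals belong to the inter-molecular interface (face by larger overlap).
Peptides overlapping both are genuinely ambiguous — partially RNA-involved
surface peptides exist — and are reported in **both** lists with a dual
flag rather than silently dropped; they count toward the interface totals.
Face assignment comes from annotation only; no geometry is computed.
`helical_packing(r)` returns `360/r` monomers per repeat (real and rounded).
Per-residue values can be written into the B-factor column of a PDB copy
(gemmi), with unmapped residues set to a sentinel (default 999.0).

## Bundled synthetic studies

`mda5_polyic` (1025 residues): the bound state plants mean uptake
differences for three RNA-footprint peptides (−20/−13/−11 %), six
front-face (−20/−7/−15/−11/−17/−20 %) and five back-face
(−12/−5/−14/−12/−3 %) interface peptides, plus an unchanged surface loop.
Three of the eleven also touch RNA-motif annotations and carry the dual
flag.  `rigi_card2` (230 residues): deprotections plus two EX1 segments
(k_op = 4×10⁻⁴ s⁻¹, closed-state P = 10⁵) whose heavy mode crosses the
detection gates only at 900 s and 3600 s.

Planting is exact: with uniform rates inside a region, noiseless percent
uptake equals `100 · (1 − e^{−kt})` independent of `f_D` and recovery, so
the bound-state rate is root-solved so the time-averaged uptake difference
equals the stated target.  Protein sequences are synthetic (fixed-seed draws
from vertebrate amino-acid frequencies, with each planted peptide's first
residue anchored so labels read conventionally).  Background peptides come
from the stochastic pepsin-map generator (cuts preferentially after
F/L/W/Y/E, fragment lengths 5–25, peptides pooled over digestion passes and
sampled to a target coverage — 0.82 for the MDA5-like study, 0.89 for the
CARD2-like one); background peptides overlapping a planted region are
dropped so the differential signal is carried exactly by the declared
peptides.

The smallest planted effect (−3 %) sits exactly on the default
classification threshold; its measured mean is unbiased around −3.0 %, so
under noise its retention — and hence the interface count — can move by one
depending on the seed.  This is inherent to planting a boundary effect, not
an instability of the pipeline; noiseless recovery is exact (11 = 6 + 5).

## What the simulations do and do not show

The generator emulates the factorial design, exchange kinetics, isotope
structure, back-exchange and intensity noise of a bottom-up HDX-MS
experiment.  It does not emulate chromatographic co-elution and spectral
overlap between peptides, charge-state envelopes beyond a single charge,
retention-time-dependent back-exchange, m/z-dependent resolution, or
inter-replicate biological variability beyond measurement noise.  Passing
tests therefore validate the analysis mathematics and its operating
characteristics under the stated noise model, not robustness to raw-data
pathologies.  Per-residue exchange-rate fitting from overlapping peptides
and multi-charge deconvolution are explicit non-goals.

## Problem sizes

The test suite runs the full MDA5-like study (79 peptides × 2 states × 6
time points × 3 replicates ≈ 3 800 envelopes, under a minute), 500 + 500
peptides for classifier operating characteristics, and 1000 null peptides ×
2 time points for type-I calibration — sizes chosen to give ≤ ±1.5 %
simulation error on the calibrated rates while keeping a full run in a few
minutes on one CPU.
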