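# Methods

## The system and the model

`rsdna` models aqueous solutions of random-sequence DNA oligomers: pools in
which every one of the 4^L sequences of length L is present at the same
concentration c/4^L (c the total strand concentration).  Hybridization is
treated as two-state (bound/unbound, no intermediate states), justified for
L ≤ 20, and at equilibrium.  A pair of strands (i, j) can bind in 2L − 1
mutual alignments; a duplex in any alignment is classified by the defect
vector

    α = (α_s, α_e1, α_e2, α_i)

with α_s the shift (overhang length, signed by 3'/5' side), α_e1 and α_e2
the runs of consecutive mismatched positions touching the two duplex ends,
and α_i the number of internal mismatches.  The number of partner sequences
realizing class α with a fixed reference is the degeneracy

    g(L, α) = n_b^{|α_s|} (n_b − 1)^{α_e1+α_e2+α_i} C(L−2−|α_s|−α_e1−α_e2, α_i)

with n_b = 4 bases.  The classification requires at least two paired bases;
mismatch runs touching an end are external, all other mismatched positions
internal.  An exhaustive classifier (`classify_alignment`) maps every
(partner, shift) to exactly one class; the test suite verifies g(L, α)
against full partner enumeration for L = 3–5.

### Class free energies

Rather than computing 4^L × 4^L sequence-specific free energies, the model
assigns one free energy per class and composition: with f_CG the strong-base
(C/G) fraction of the reference,

    ΔG_fCG(α) = n_st · ⟨stack⟩(f_CG) + ⟨init⟩(f_CG) + n_dangle · ⟨dangle⟩
                + (α_e1 + α_e2) · ⟨mm_term⟩ + α_i · ⟨mm_int⟩,

where n_st = (L − |α_s| − α_e1 − α_e2 − 1) − 2 α_i is the number of intact
WC stacks (each internal mismatch breaks its two flanking stacks; floored at
zero) and n_dangle = 2 when the strands are shifted (each duplex end then
carries an overhang, of which only the first base counts, per the usual NN
convention).  ⟨stack⟩(f_CG) is the expectation of the unified NN stack
(ΔH, ΔS) over the 16 ordered quartets with bases drawn independently
(strong with probability f_CG, split evenly between C and G).  Salt enters
as the entropy-only unified correction ΔS → ΔS + 0.368 · n_st · ln[Na+].

### Pool melting and pairing statistics

Each class contributes the statistical weight g(L, α) · ζ with
ζ = [c] exp(−ΔG/RT).  The bound fraction of the composition class f_CG is

    θ_e^(fCG) = 1 − 2 / (1 + sqrt(1 + (4/4^L) Σ_α g ζ)),

the same algebraic form as the melting of a self-complementary solution.
The ensemble curve averages the L + 1 composition classes with binomial
weights p_L(f_CG) = C(L, f_CG·L)/2^L.  Per-class bound fractions follow by
weighting θ_e with the class share g ζ / Σ g' ζ' and composition-averaging;
summing classes with equal |α| = |α_s| + α_e1 + α_e2 + α_i gives the
error-count distribution.  Tm is defined by θ(Tm) = 1/2 and extracted by
bisection on the continuous model (tolerance 0.01 °C), never by grid
interpolation.

A per-sequence oracle (`theta_sequence_oracle`) evaluates the same bound
fraction for one explicit reference by enumerating every partner and shift
(L ≤ 6) or by uniform partner sampling; because the class counts of any
reference equal g(L, α) exactly, its exhaustive form reproduces the
closed-form class curve to machine precision — the identity that justifies
the mean-field pool formula.  The double sum follows the all-shifts reading;
the alternative most-stable-alignment view is available separately
(`best_shift`, ties broken toward the smallest |α_s|, negative first).

### Contact-quenching observables

A complementary tagged pair A*/B* at c_fluo each inside the pool defines the
stoichiometric ratio φ = c_fluo/(c/4^L).  The tagged-pair term φ ζ_AB joins
the pool sum:

    θ_e^CQ = 1 − 2 / (1 + sqrt(1 + (4/4^L) [φ ζ_AB + Σ_α g ζ])),
    θ_AB   = φ ζ_AB / (φ ζ_AB + Σ_α g ζ) · θ_e^CQ,

with ζ_AB from the sequence-specific NN energy of the printed pair.  As
φ → ∞ both reduce exactly to the two-state curve of the isolated pair.  The
terminal fluorophores stabilize the tagged duplex; this is exposed as an
additive (ΔH, ΔS) offset on the salt-aware NN energy.  A ΔH offset of
−1.2 kcal/mol reproduces the observed ≈30% specific-pairing plateau at
φ = 1, 0.15 M, low temperature, and is the characterized value used in the
tests; its uncertainty is taken as ±0.75 kcal/mol on ΔG_AB (≈8% of the
tagged-duplex ΔG37), propagated as a θ band.  Salt-dependence comparisons
of θ_AB(φ) are judged against the overlap of these bands.

## Parameters

Shipped in `src/rsdna/data/nn_params.tsv` (tab-separated, `#` provenance
header):

| entry | value (ΔH kcal/mol, ΔS cal/(mol·K)) | origin |
|---|---|---|
| 16 WC stacks | SantaLucia 1998 unified | literature |
| INIT_GC / INIT_AT | (0.1, −2.8) / (2.3, 4.1) per terminal pair | literature |
| MM_TERM_AVG | (−3.283, −8.879) per terminal mismatch | mean over the 48 published terminal-mismatch quartets |
| MM_INT_AVG | (0.308, −1.683) per internal mismatch | 2 × mean over the 48 published single-mismatch doublets |
| DANGLE_AVG | (−4.5, −13.294) per overhang end | see below |
| SALT_COEFF | 0.368 cal/(mol·K) per stack per ln[Na+] | unified salt correction |

The dangling-end ΔG37 (−0.377 kcal/mol) is the mean over the 32 published
single dangling-end parameters.  The published per-entry ΔH values scatter
from ≈ +0.5 to −9 kcal/mol, and the plain average of the splits (−2.53,
−6.96) makes defected duplexes too costly at low temperature: it predicts a
defectless-duplex fraction of 0.24 at 0 °C for the 12-mer pool, incompatible
with the 0.10–0.14 range the model is meant to occupy.  The enthalpy/entropy
split of the average — the only free choice in the energetic scheme — was
therefore set to (−4.5, −13.294), which keeps ΔG37 at the literature mean
(leaving all Tm-level predictions essentially unchanged, since melting
happens near 310 K) while giving the low-temperature pairing statistics
their observed weight.  All other entries are plain literature averages.

Concentration conversions use MW(L) = 303.7·L + 79 g/mol (average
single-stranded DNA, 5'-OH); this reproduces the φ = 1 ↔ 16 g/l
correspondence for the 8-mer pool within 3%.

## Counterfactual alphabets

* `all_CG`: every stack replaced by the mean over the four CG-only quartets
  (−9.1, −22.85), initiation by the strong-pair value; degeneracies stay at
  n_b = 4 and the defect increments stay at their standard averages.
* n_b = 2: one complementary base pair; the stack is the arithmetic mean of
  the AT-average and CG-average stacks; degeneracy uses n_b = 2 (mismatch
  factor 1).
* n_b ≥ 4 generalized: uniform-average (f_CG = 1/2) stack energetics with
  n_b-fold degeneracies.

Averaged-energetics alphabets carry no composition dependence, so a single
composition class represents the pool.

## Numerical choices

* All Boltzmann weights are handled in log space (`logsumexp`); the
  two-state fraction 1 − 2/(1 + sqrt(1 + x)) switches to its asymptotic form
  1 − 2 exp(−log x / 2) beyond log x = 500.
* Temperatures are kelvin internally, Celsius at every user interface;
  default grid 0–95 °C at 0.25 °C.
* Non-integer f_CG·L requests are rejected, not rounded.
* Absorbance reduction fits the two linear baselines by least squares;
  Tm extraction runs on a Savitzky–Golay-smoothed (≈4 °C window, order 2)
  continuous model while the stored θ grid stays raw.  Default baseline
  windows are the lowest/highest 15% of the temperature span.
* Class enumeration is O(L³)–O(L⁴) (≈13,000 classes at L = 20); per-class
  energies are cached per (parameter set, alphabet, L, f_CG), so a full
  ensemble melting curve takes well under a second.

## What the synthetic absorbance generator does and does not emulate

`synthesize_absorbance` inverts the two-baseline construction exactly:
linear hypo/hyperchromic baselines plus seeded Gaussian noise.  It emulates
baseline slopes and instrument noise, not baseline curvature, drift between
heating and cooling (hysteresis), evaporation artifacts, or wavelength
dependence.  Round-trip tests on it therefore validate the reduction
algebra and its noise robustness (Tm recovered within 0.3 °C at 1% of the
transition amplitude), not the treatment of non-ideal instrument behavior.

## Known limitations

* Equilibrium only; no kinetics or hysteresis.
* The α parametrization has no bulges, asymmetric loops, hairpins or
  multi-helix states, and no sequence-specific energies for mismatched
  pairings (that is the point of the averaging).
* The all-CG counterfactual is sensitive to how the defect increments are
  treated: keeping them at the natural averages gives θ_0(0 °C) ≈ 0.42 for
  the 8-mer pool, scaling them proportionally with the stacks gives ≈ 0.17.
  The implementation keeps them fixed (the literal reading of "all stack
  energies set to CG").
* The low-temperature error-count bins are length-invariant at fixed
  composition (< 0.1 pp across L = 8–20) but acquire a ≈1.5 pp drift in the
  dominant |α| = 1 bin under ensemble composition averaging, because the
  binomial composition width varies with L.
* Problem sizes used throughout tests and the acceptance script: exhaustive
  enumerations at L ≤ 5, pool statistics at L = 8–20, 40 random pairs for
  sequence-averaged Tm comparisons, 10⁴ samples for the random-collision
  statistic.  These match the desk-scale regime the model addresses.
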