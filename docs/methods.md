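# Methods

## The workflow in one paragraph

`middleup` implements a middle-up forced-oxidation comparability workflow for
IgG1 monoclonal antibodies. The antibody is digested in silico with IdeS and
reduced into its three ~23–26 kDa subunits — light chain (LC), heavy-chain
N-terminal fragment (Fd') and half constant fragment (Fc/2). Each LC-ESI-QTOF
run is reduced to deconvoluted zero-charge subunit masses per chromatographic
peak, matched against a proteoform library (glycans, oxidations,
pyroglutamate, C-terminal lysine) at ±70 ppm, and semiquantified through
extracted-ion chromatograms. The statistic of interest is the relative
abundance of an n-fold oxidized subunit,

    ar = I_nox / (I_0ox + I_nox),

with `I` the EIC peak height of the species' most intense charge state at
±0.01 m/z. Comparing ar over treatment duration between a reference product
(RP) and a biosimilar (BS), and comparing most-abundant oxidation counts
between two antibodies with different methionine maps, yields the two
higher-level outputs: the RP/BS time-course comparison and the per-site
oxidation attribution.

## In-silico digestion

IdeS cleaves the IgG1 heavy chain between the paired glycines of the unique
lower-hinge motif (`...CPAPELLG | GPSV...`), implemented as a cut between the
two G of the single `LLGG` occurrence; heavy chains with zero or multiple
occurrences are rejected rather than guessed. Disulfide reduction is implicit:
subunits are emitted as free chains with no disulfide bookkeeping, matching an
analysis that only ever sees fully reduced chains. Site labels in antibody
numbering (EU numbering for Fc/2) are attached through a per-mAb,
per-subunit integer offset rather than computed by alignment; homologous
positions whose labels differ between antibodies (M83 in one, M85 in the
other) are declared equivalent in configuration.

## Masses

Theoretical masses are isotope-averaged: at 23–26 kDa the deconvolved
quantity is the average mass, so the average scale is the matching currency
throughout (monoisotopic values are computed for cross-checks only). Atomic
weights are the IUPAC 2021 standard weights frozen in `chem.py` for
bit-reproducibility. All modification deltas are derived from composition,
never hard-coded: oxidation = +O (+15.999 Da average), pyroglutamate = −NH3
from Gln or −H2O from Glu, additional C-terminal lysine = +K residue
(+128.175 Da), and the N-glycans from monosaccharide residue compositions
(G0F = HexNAc4 Hex3 Fuc1 = +1445.34 Da; G1F = G0F + Hex = +162.14 Da more).
The proteoform library per subunit is the cross-product of allowed states:
glycans and ±C-terminal K on Fc/2 only, pyroglutamate only on Q/E-starting
chains where configured, and oxidation counts from 0 to the methionine count
plus an unspecific cap (default 4, covering oxidation of non-methionine
residues under harsh peroxide stress).

## Deconvolution

Vendor maximum-entropy deconvolution is replaced by a deterministic
charge-series algorithm with an explicit contract. Averaged window spectra
are centroided (local maxima; intensity-weighted mean m/z over the
half-height support). Every centroid is tried at every charge z in [8, 40]
(covering 22–60 kDa inside m/z 600–3200), giving candidate masses
M = z·(m/z − 1.00728). Candidates are clustered along the mass axis with a
0.2 Da gap rule; a cluster qualifies only if its charge support contains at
least `min_series` = 3 *consecutive* charge states. The consecutive-run
requirement is the harmonic guard: a genuine ESI envelope samples consecutive
charges, whereas the exact 2× mass harmonic (a centroid of true charge z
re-read at 2z) hits only every other charge. Competing clusters are resolved
greedily by abundance weighted with the consecutive-run fraction, each
centroid belonging to at most one reported mass. On clean data the recovered
mass is well inside 20 ppm — comfortably within the downstream 70 ppm
matching window.

Matching reports all library entries within ±70 ppm sorted by |Δppm|; the
closest is the annotation. Each match carries the star notation on the
absolute error: |Δ| ≤ 0.5 Da `*`, 0.5–1.5 Da `**`, 1.5–4.0 Da `***`, larger
errors flagged as rejected. The band edges are treated as half-open
intervals so the rule is total on any input.

## Synthetic data generator

No instrument data ship with the package, so the pipeline is exercised on a
seeded simulator whose defaults *are* the experimental conditions being
modelled:

* **Design** — two mAbs × RP/BS × control (`con`) and forced oxidation
  (`oxi`) × 0/24/48/72 h × 3 replicates; control arms have all effective
  rates zero, so any control duration equals the 0 h profile.
* **Kinetics** — each methionine oxidizes pseudo-first-order with
  probability 1 − exp(−k·t); the subunit oxidation count is the
  Poisson-binomial over its sites, convolved with a truncated-Poisson
  unspecific count of mean k_u·t. Defaults: fast class k = 0.15/h (≥97%
  converted at 24 h; all Fc/2 sites, plus the solvent-exposed infliximab
  LC M55 and Fd' M18), slow class k = 0.002/h for the RP (~13% at 72 h,
  i.e. "mostly unoxidized"), BS slow class = 2× the RP rate, k_u = 0.004/h.
  The slow and unspecific rates were fixed by requiring the generator to
  reproduce the scenario's qualitative endpoints at every duration — the
  most-abundant-species calls, measurable (but small) bevacizumab 3-ox
  species, and Fab subunits that never tip past their unoxidized mode —
  before any pipeline test was frozen. They are generator truth, not
  estimates of real rate constants.
* **Static modifications** — Fc/2 glycan split G0F 0.55 / G1F 0.40 /
  unglycosylated 0.05; Fd' pyroglutamate 0.06; C-terminal lysine retention
  from the product definition (near-complete clipping everywhere except the
  infliximab RP, which retains 30%, mirroring its incomplete clipping).
* **Acquisition** — 0–41 min at 2 spectra/s, m/z 600–3200 in profile mode on
  a fixed 0.02 Th grid. Each proteoform above a 1e-4 abundance floor elutes
  as a Gaussian RT peak (σ = 0.08 min) at its subunit's base RT shifted
  −0.15 min per oxidation (oxidized forms are more hydrophilic on reversed
  phase, and the shift is small enough that oxidation states are only
  partially separated). Intensity is spread over a Gaussian charge envelope
  centred at z* = round(M/1200) with σ_z = 2.5, each charge state an
  isotopically unresolved Gaussian of FWHM ≈ 6/z Da. Noise is a flat
  baseline (2 counts) plus Gaussian noise with an intensity-proportional
  term (σ = 1 + 0.01·I); a Poisson alternative sits behind a config switch.
  Identical seed and parameters give bit-identical runs; the mzML writer
  round-trips numerically.

### What the generator does *not* emulate

Isotope fine structure, adducts, in-source fragmentation, detector
saturation, the undigested-HC contaminant (available behind a flag, default
off), infliximab's low-level fragments, baseline oxidation in unstressed
material, and any RP/BS difference other than the slow-class rate multiplier
(in particular, BS-only trace species such as very high Fc/2 oxidation
states are not produced by default — the report's species-difference list is
exercised with explicit custom presets in the tests). Passing tests
therefore demonstrate that the analysis chain is correct and self-consistent
under realistic peak shapes, envelopes and noise — not that real instrument
data would be this clean.

## Semiquantification choices

The EIC tolerance ±0.01 is read in m/z units (Th). The charge state traced is
the species' apex charge from deconvolution when the species was assigned,
else the theoretical envelope apex. Peak height is taken inside the union RT
window of the subunit's annotations widened by ±1 min, because a subunit's
oxidized states elute as partially separated shoulders of one family.
Replicates are reported as individual points, with mean ± SD as a summary;
the default report quantifies the bevacizumab-like LC 3-ox and Fd' 3-ox
pairs, the configuration of the bevacizumab time-course comparison. A known
limitation discovered during validation: a pyroglutamate form carrying one
extra oxidation is isobaric with the unmodified chain to ≈ −1 Da, i.e. well
inside the ±0.01 m/z EIC window at these masses; when a subunit is almost
fully converted (infliximab LC/Fd'), the residual 0-ox EIC is dominated by
this interference and a level-1 ar there does not track the underlying
fractions. ar levels for such subunits are deliberately not part of the
default report.

## Site attribution

Verdicts are a conservative set-difference over most-abundant oxidation
counts: a subunit whose count equals its methionine count marks all its sites
susceptible; a count of zero marks all resistant; a partial count first
subtracts sites proven resistant through the other antibody's shared or
homologous sites and attributes the remainder only when it is uniquely
determined, otherwise sites stay indeterminate. Conflicting evidence
(susceptible and resistant) demotes a site to indeterminate with the
conflict recorded in its evidence trail. No probabilistic assignment is
attempted.

## Numerical and tie-break conventions

Proton mass 1.00728 Da. Matching ties: all in-window entries reported sorted
by |Δppm|, closest first. Most-abundant ties: lower oxidation count, then
lexical name. Deconvolution cluster ties: higher run-weighted abundance,
then lower mass. Degenerate inputs: empty spectra centroid to nothing, flat
TICs yield no windows, an empty RT window is an error, ar with both
intensities zero is flagged rather than invented. Probability distributions
are renormalized after truncation and checked to sum to 1 within 1e-9.

## Problem sizes

Default runs are full-length (4921 scans over 41 min); one simulated run
plus its complete analysis takes well under a second, so the entire
treatment matrix (84 runs) is simulated and analyzed end-to-end in the test
suite, and the acceptance script re-derives the headline species calls from
two fresh 48 h runs in a few seconds.
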