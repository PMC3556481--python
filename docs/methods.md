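# Methods

## Glycoform model

A glycosite is any Ser or Thr; all are treated as modifiable (for mucin
tandem repeats this is the biologically relevant assumption — the MUC1
20-mer's five Ser/Thr are all known O-glycan acceptors).  A glycan
alphabet is an ordered list of per-site states whose digit 0 is always
UNOCCUPIED; a glycoform is therefore a base-k integer written over the
site list, and the enumerated set is exactly the integers 1..k^n − 1
(the all-zero vector is the unmodified peptide, excluded from counts but
reportable as the naked-peptide control).  Sialyl-Tn is one alphabet
state (one attached disaccharide), not two independent decorations: a
site is naked, Tn, or sialyl-Tn, which is what makes the ternary count
3⁵ − 1 = 242.

Two orderings are offered.  `occupancy` sorts by glycan count then
lexicographically (site 1 most significant) — the order you want when
glycoforms are grouped by number of Tn moieties; `counter` is plain
base-k counting.  Counts and set identity are order-invariant, and the
test suite checks both against an independent brute-force enumeration
(`itertools.product` over all k^n vectors).

A size guard (default n ≤ 20 sites, k ≤ 5 states) rejects accidental
combinatorial explosions; both bounds are per-call configuration.

## Epitope annotation and windows

Annotated epitopes use the convention of the glycopeptide-synthesis
literature: the state name in parentheses immediately after the modified
residue, `RPAPGS(GalNAc)TAPPAHG`.  Under this rule that string places
the GalNAc on Ser-6 of the 13-mer.  Rendering and parsing are mutual
inverses, property-tested on random epitopes.

Candidate windows are cut from the full protein around occupied sites.
In `centered` mode the site sits at position ceil(L/2) of an L-mer,
shifted only as far as the protein termini force (windows are clipped,
never dropped, so short flanks still yield candidates); `tiled` mode
keeps every L-window containing at least one occupied site.  Windows
carry 1-based origins in the parent protein.  Libraries deduplicate on
the rendered string, which collapses the copies of a window repeated by
tandem periodicity; for three or more copies the interior (unclipped)
window set is independent of copy number, which the tests verify by
brute-force extraction on 3- and 5-copy proteins.  The default window
length of 13 is a convenience matching common synthetic glycopeptide
lengths; nothing in the model privileges it, and it is a free parameter.

Biotin/PEG linkers used for plate immobilization are deliberately not
part of the epitope string; they are synthesis plumbing, and a fixed
C-terminal mass tag can be added at the mass-arithmetic level if needed.

## Mass arithmetic

All masses derive from elemental compositions through pyteomics' atomic
mass tables — no hard-coded residue decimals.  Glycan residue masses are
dehydrated (glycosidic-bond) increments: HexNAc from C8H13NO5
(203.0794 Da), NeuAc from C11H17NO8 (291.0954 Da), sialyl-Tn their sum,
Ac3GalNAc (the protected synthetic precursor) HexNAc + 3×C2H2O.  The
adduct model is protonation only, m/z = (M + z·m_H⁺)/z.  Fragment ions
are the b/y backbone series — each cleavage emitted glycan-lost and,
when the fragment spans an annotated residue, glycan-retained — plus the
HexNAc oxonium series (204.087, 186.076, 168.066, 144.065, 138.055,
126.055) and the NeuAc series (292.103, 274.092) for sialylated states.
No isotope envelopes and no intensity prediction: the package computes
positions, not spectra.  Correctness is checked against an independent
hand-coded residue table (agreement to 1e-4 Da) and the b/y pair
identity b_i + y_{n−i} = M + 2·m_H⁺.

## SPR kinetics

Sensorgrams follow the 1:1 Langmuir model: association
R(t) = Req·(1 − e^{−(ka·C + kd)·t}) with Req = Rmax·C/(C + KD),
dissociation R(t) = R(t_a)·e^{−kd·(t − t_a)}, KD = kd/ka.  Units: ka in
1/(M·s), kd in 1/s, concentrations molar internally, KD reported in nM.
Simulation defaults (120 s association, 200 s dissociation, 1 Hz) mirror
a standard kinetic run.  Gaussian noise requires an explicit seed; there
is no hidden global random state anywhere in the package.

`fit_langmuir` fits (ka, kd, Rmax) globally across curves by
Levenberg-Marquardt least squares in log10-parameter space (positivity
for free), restarted from a fixed grid of ka guesses (10³..10⁶) with kd
initialized from the log-linear dissociation tail and Rmax from the data
maximum; the lowest-cost solution wins, making the fit deterministic
given the data.  Standard errors are asymptotic (Jacobian at the
optimum, delta-method back to linear scale).  Non-convergence raises an
explicit error with diagnostics.  Fewer than three distinct
concentrations triggers an identifiability warning: with a single curve,
ka and Rmax are nearly confounded.  Mass-transport limitation, bivalent
analyte, and baseline drift are out of scope — the model is the plain
1:1 used by standard evaluation software, and avidity effects (which can
make ELISA and SPR affinities disagree) are a documented non-goal.

## ELISA dose-response

The four-parameter logistic is parameterized
y = bottom + (top − bottom)/(1 + (EC50/x)^hill) so hill > 0 is an
increasing curve, matching ELISA signal direction; at x = EC50 the
response is exactly midway between the asymptotes.  Starting values are
deterministic: asymptotes from the data extrema, EC50 from the point
nearest half-maximum, hill = 1.  Fits require ≥ 5 points; after fitting,
R² < 0.9 (flat or non-monotone data) or a decreasing fitted curve raises
a fit-quality error carrying the achieved R² rather than returning a
meaningless EC50.  Fold-differences are ratios of EC50s, weaker binder
in the numerator.

## Synthetic data and what the tests show

The fixture generator emulates the *shape* of a mucin experiment: a
repeat unit of configurable length with exactly the requested number of
Ser/Thr sites at random non-adjacent positions (MUC1-like defaults:
20-mer, 5 sites, 3 copies), ELISA points from known 4PL parameters
(bottom 0.05, top 1.8 OD, EC50 10 ng/ml, hill 1 — the range of a strong
glycopeptide binder), and sensorgrams from known constants
(ka = 5×10⁴ /(M·s), kd = 0.025 /s, KD = 500 nM, Rmax = 100 RU — mid-range
for antibody/glycopeptide interactions).  Identical spec + seed gives
byte-identical files, with ground truth written alongside.

Recovery tolerances were fixed before the simulations were run: on
noiseless data both fitters recover generating parameters to numerical
precision; at 2% of Rmax Gaussian noise with three concentrations
spanning 0.1–10 × KD (50 seeds), the median relative KD error must stay
under 10%; at 5%-of-range noise on an 8-point dilution series
(100 seeds), mean EC50 bias must stay under 5%.  These problem sizes
(≈ 320 points per sensorgram, 8-point ELISA series) are the package's
chosen benchmark scale.

What the synthetic data deliberately lacks: real mucin repeats are not
random sequences (the generator controls only length and site count, not
proline periodicity or composition bias); real sensorgrams carry drift,
bulk refractive-index jumps and mass-transport effects; real ELISA noise
is heteroscedastic.  Passing recovery tests therefore demonstrates the
estimators are correctly implemented and well-conditioned on clean 1:1 /
4PL data — not that they are robust to instrument artifacts.

## Packaged reference tables

The package ships small text tables used as fixtures and benchmarks: the
two phases of the MUC1 repeat unit (FASTA), three benchmark annotated
epitope strings, an SPR kinetic-constant table for two monoclonal
antibodies against three (glyco)peptides (the chi² column is the
instrument software's fit residual, carried as inert metadata), and a
10-patient IHC staining table used by the positivity counter.  Printed
KD values in the SPR table reflect 4-significant-digit rate constants,
so recomputed kd/ka agrees within half a display unit on the
self-consistent rows and within 0.2 nM everywhere.

## Known limitations

- No biosynthetic feasibility weighting: all k^n − 1 glycoforms are
  treated as equally possible; glycosyltransferase kinetics and
  site-specific occupancy priors are out of scope.
- No N-glycosylation, no branching beyond fixed per-state compositions.
- No immunogenicity or epitope-scoring model: the library is a
  combinatorial design surface, not a predictor of antibody responses.
- The binding module analyzes monovalent 1:1 kinetics; bivalent/avidity
  models are not implemented.
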