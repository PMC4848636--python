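# Methods

## Tight-binding inhibition model

The kinetics module treats one enzyme–inhibitor pair under initial-velocity
conditions.  With total enzyme `E0`, total inhibitor `I0` and apparent
dissociation constant `Ki_app`, 1:1 mass balance gives the complex
concentration as the smaller root of `x² − (E0 + I0 + Ki_app)x + E0·I0 = 0`,
and the fractional residual activity is `vi/v0 = 1 − x/E0` (the Morrison
equation).  The root is evaluated in the cancellation-free product form
`x = 2·E0·I0 / (s + √(s² − 4·E0·I0))`, which keeps the model and the
independent bisection solver in agreement to ~1e-10 relative even where
`vi/v0` is tiny.  The bisection solver (`equilibrium_fraction_bisection`)
exists purely as a cross-check oracle and shares no code path with the model.

Fitting is single-parameter unweighted nonlinear least squares
(`scipy.optimize.least_squares`, tight tolerances) on pooled points, with
`Ki_app` parameterised on a log scale to enforce positivity.  `E0` is fixed —
it is known from active-site titration — with an optional diagnostic co-fit.
The initial guess is the interpolated inhibitor concentration at half
activity minus `E0/2` (at `vi/v0 = 0.5` half the enzyme is complexed),
falling back to the median of the grid.  The standard error comes from the
Gauss–Newton covariance with the delta method for the log parameter.
Curves whose activities all sit at ~1 raise a "no inhibition" error rather
than returning a meaningless bound; enzymes quantified only in activity
units are refused by the molar fitter.

The substrate correction `Ki = Ki_app/(1 + S0/KM)` assumes purely
competitive binding (the canonical Kunitz reactive-loop mechanism); the
result object records that assumption.  Missing `KM` is an explicit error —
the uncorrected value is never silently passed through.  Tight binding is
declared at `Ki ≤ 1e-7 M`, boundary inclusive.

Active-site titration assumes stoichiometric binding (`[E0]/Ki ≥ 100`;
smaller ratios attach a validity warning without suppressing the result).
A least-squares line through the descending points with activity in
[0.15, 0.85] is extrapolated to its x-intercept, the equivalence point where
total inhibitor equals total enzyme for a 1:1 complex; the intercept is
reported on the same concentration axis as the input amounts.

Reversibility is classified from two diagnostics with configurable
tolerances: activity must rise strictly with substrate concentration at
0.5/1/2 KM (each step > 2 percentage points, chosen to exceed typical
triplicate spectrophotometric scatter) and be stable over preincubation time
(range ≤ 5 points).  A still-falling time course yields
`equilibrium_not_reached`; a flat substrate response yields `inconsistent`.

## Channel-block analysis

All electrophysiology operates on steady-state summaries, not raw traces;
leak subtraction and filtering are hardware-bound preprocessing and out of
scope.  Percent block is `100·(1 − I_toxin/I_control)`, clamped to [0, 100],
computed by convention at the 0 mV test pulse unless stated otherwise.
The Hill fit estimates IC50 and (by default) the Hill coefficient `h`, both
log-parameterised; `fix_h=1` reproduces a one-site fit.  Diagnostic flags
mark curves whose plateau never reaches 50% ("IC50 extrapolated"),
non-bracketing designs and non-monotonicity beyond 5 points.

Chord conductance `G = I/(V − Erev)` excludes points within 5 mV of the
reversal potential (the quotient degenerates there); `Erev` is supplied or
estimated as the zero-crossing of the control IV by linear interpolation.
The Boltzmann fit estimates `V_half`, a positive slope factor `k` (log
parameterised) and `Gmax`; flat series return `converged=False` and series
that do not span the transition (normalized G entirely above 0.3 or below
0.7) are flagged.  V½ shifts are tested with a two-sided paired t-test
(α = 0.05); identical pairs give t = 0, p = 1, and a constant offset with
zero within-pair variance is reported as a certain shift rather than a
division-by-zero.  Voltage independence of block requires ≥ 3 test
potentials spanning ≥ 40 mV and holds when the max–min spread is within 5
percentage points (chosen to exceed run-to-run TEVC variability at n ≥ 3) or
the linear trend is non-significant.

## Motif analysis

Alignments are consumed, not built (ClustalOmega or any MSA tool upstream).
Framework detection scores each column by the fraction of records carrying
Cys and requires exactly six columns at conservation ≥ 0.9 (configurable);
individual records lacking a framework cysteine are flagged per record.
Windows are anchored on each record's **own** cysteines in ungapped sequence
coordinates — not on alignment columns — so an insertion between Cys V and
Cys VI raises a per-record "non-canonical C-window" error instead of a
silent misalignment.  Residue numbers follow each record's published
(UniProt-style) numbering via a per-record offset.

The class table is a single configurable mapping: negative {D,E}, positive
{K,R,H}, polar uncharged {S,T,N,Q,C,Y}, hydrophobic {G,A,V,L,I,P,F,M,W}.
Histidine is counted as positive and proline as hydrophobic, matching the
conventions of the dendrotoxin literature this analysis follows; X or
non-standard letters are propagated as "unclassifiable", never assigned.

Exposure filtering keeps window positions with relative ASA strictly > 50%.
With a per-residue ASA table the set is decided by majority across records;
without one the built-in fully-exposed Kunitz set {X(a−2), X(a+1), X(a+3),
X(b+1), X(b+2)} is used and tagged "fold-default" in the output.  Buried
or partially-exposed positions are carried in reports but never enter
profiles.

Compensation is judged per window: verdicts are *identical* (equal class
vectors), *compensated* (every class change pairs with the reverse change at
another exposed position of the same window — i.e. the difference decomposes
into transpositions; a 3-cycle of classes preserves the multiset but is
**not** compensated), or *non-compensated*.  The overall verdict is the
worse window.  Cross-window multiset preservation is reported separately and
never upgrades a verdict, since the biological reading of compensation is a
local swap on one contact patch.  Grouping is the transitive closure of the
pairwise relation; in compensated mode the relation need not be transitive,
so any closure-merged pair that is itself non-compensated is surfaced as a
warning.  Strict mode (identical class vectors) is an equivalence relation
and always refines the compensated partition.

The dendrotoxin fixture uses the mature α-DTX sequence numbered from 1 and
the mature DTX-K sequence with offset +22 (precursor numbering), which
places the literature's key residues — Lys25/Lys28/Pro30, Trp47/Lys48,
Arg74/Arg75 — at their published numbers.  The kalicludine fixture is a
*synthetic* stand-in: the real AsKC window residues are published only as a
figure, so the fixture plants class vectors that realise the reported
relationship (AsKC1 ≡ AsKC2, AsKC3 non-compensated at X(a−2)).

## Structure exposure

Shrake–Rupley ASA uses a deterministic golden-spiral point set (default 960
points, probe 1.4 Å, heavy atoms only, built-in overridable element radius
table; altloc A; missing radii are an error listing the atoms).  Per-atom
ASA is the exposed point fraction times `4π(r_vdw + probe)²`; residue ASA
sums its atoms.  At 960 points the sampled area matches the single-sphere
and two-sphere spherical-cap closed forms within 0.5% and 1% respectively,
and 960 vs 4000 points differ by ≤ 1% of the sphere scale on random
clusters.

Relative ASA divides by the ASA of the same residue extracted alone in its
observed conformation — the closest literal reading of an "in vacuum"
reference — rather than an extended Gly-X-Gly tripeptide; the convention is
recorded in the output metadata so tables computed under other conventions
can be supplied to the motif filter instead.  Because the sphere point set
has a fixed orientation, rotation invariance holds only to sampling
tolerance (≲ 1–2 percentage points at 960 points); translation invariance is
exact.  Contacts are inter-residue heavy-atom pairs within 4.0 Å (inclusive),
labelled by backbone membership (N, CA, C, O).

## Synthetic data: what it does and does not emulate

Generators are deterministic functions of (parameters, seed) and default to
the published assay designs: 12-point inhibition curves at `[E0]/Ki_app`
around 10 with the inhibitor grid from 0 to 5·E0, titrations spanning 1.5×
the equivalence point, 8-point dose–response grids over 2 decades centred on
the IC50, and IV families over −40…+40 mV in 10-mV steps with slope 8 mV.
Noise is multiplicative Gaussian because photometric and TEVC errors scale
with signal.  The MSA generator plants a six-cysteine scaffold (Cys VI =
Cys V + 4), draws exposed window residues from requested classes, applies
intra-window swaps for compensated variants and single distinct changes for
non-compensated ones, and emits the intended partition recomputed
independently from the planted class vectors; inconsistent plant
specifications are rejected at generation time.

Passing tests on these data demonstrate correctness of the estimators and
the pattern logic under the stated error model — they do not demonstrate
robustness to structured experimental artefacts (substrate depletion, slow
binding, rundown, series resistance, alignment errors, phylogenetic
correlation), none of which the generators simulate.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
round-trip fits use 8–12 point curves; oracle comparisons use 1000 random
parameter triples (Morrison) and 100 random clusters (contacts); stochastic
calibration uses 200 seeded replicates per fitter; planted-truth recovery
uses 100 seeded alignments of 6 sequences.  All optimisers run with
`xtol = ftol = gtol = 1e-15` so noise-free round trips are exact to ≤ 1e-6
relative; ties in verdict ordering resolve identical < compensated <
non-compensated; degenerate inputs (flat curves, all-zero conductance,
single-voltage grids) raise typed errors rather than returning fits.

## Known limitations

* No progress-curve or slow-binding kinetics; `KM` values are inputs.
* No kinetic modelling of block on/off rates or state dependence.
* Compensation treats positions independently within a window; no
  structural weighting of the swap partners.
* The isolated-residue ASA reference differs from Gly-X-Gly-normalised
  scales; thresholds tuned for one convention should not be mixed with
  tables from the other.
* The kalicludine fixture is synthetic (see above); conclusions about the
  real AsKC sequences require their UniProt records.
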