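# Methods

This note documents the models implemented in `endoreg`, the defaults
they ship with, the synthetic study conditions used by the tests and
the acceptance script, and the numerical and design choices that were
genuinely open.

## Coordinates and genome model

All coordinates are 0-based, half-open; GFF3 input/output uses the
1-based closed convention.  Genomes default to circular (a bacterial
chromosome) and all interval arithmetic wraps modulo the length.
Ambiguity codes are rejected; `N` is admitted only behind an explicit
flag, and every profile calculator masks (NaN) positions whose windows
touch an `N`.  Functional categories are free strings assumed to be
pre-flattened to a common annotation depth; no ontology hierarchy is
modelled.  Upstream windows are fixed-length and are *not* truncated at
the upstream gene boundary by default (a `clip_to_gap` mode exists):
with gene-dense genomes a fixed window is the comparable choice across
genes, at the cost of occasionally averaging over coding sequence.

## DNA physical properties

**Dinucleotide tables** (base-stacking energy, kcal/mol; propeller
twist, degrees) assign each position the mean of the two flanking step
values (one step at linear ends).  The tables ship as YAML in
`endoreg/data/` and are classical literature values; they are data, not
code, and can be edited without touching logic.

**Curvature** uses a wedge model: each step contributes a deflection
vector (roll, tilt) rotated by 360°/`helical_repeat` (default 10.5
bp/turn) per step; curvature at a position is the magnitude of the
resultant over a centred 31-bp window divided by the number of steps
(degrees/step).  The shipped wedge table is duplex-symmetric (reverse-
complement steps carry equal roll and negated tilt), which makes the
profile of the reverse complement the exact mirror of the profile of
the forward strand — a property the tests assert to 1e-9.  The
dominant AA/TT wedge reproduces the macroscopic curvature of phased
A-tracts.

**SIDD.**  A state of a superhelical domain of length *N* opens *r*
runs totalling *n* bp with free energy

    G(state) = a·r + Σ_open b(base) + (K/2)·(σN/h + n/h)²,

where `a` is the nucleation cost of one denatured run (both
helix–coil junctions), `b` the per-base-pair separation energy, and
the quadratic term the torsional cost of the residual linking
difference after `n/h` turns are absorbed by the open region.  The
per-base opening probability is

    p(x) = Σ_{states opening x} e^(−G/RT) / Z,

and the reported track is `G(x) = −RT·ln(p(x)/(1−p(x)))`, clipped to a
ceiling of `θ + 2RT` where opening underflows, so profiles stay
bounded and plottable.

Defaults (37 °C, YAML-configurable): σ = −0.055, a = 12.0 kcal/mol,
b_AT = 0.255 and b_GC = 1.301 kcal/mol/bp, K = 9.0 kcal/mol per
(linking-difference turn)², h = 10.5 bp/turn, θ = 12 kcal/mol, runs ≤
150 bp, at most two simultaneous runs.  The separation energies are
the classical copolymeric values; the nucleation cost is set slightly
above θ so that a torsionally relaxed domain (σ = 0) admits no open
state within the threshold — the model then correctly reports an
all-ceiling profile — while remaining within the range quoted for the
two-junction initiation cost.  K is the effective stiffness for the
default 250-bp analysis window (the per-domain torsional coefficient
scales as ~C·RT/N, and 9.0 sits in that range for windows of one to a
few hundred bp); it positions the closed-state energy of an AT-rich
window near the opening cost of a ~10-bp AT run at the default σ, so
destabilized sites resolve clearly instead of saturating at either end
of the scale.

State-space handling: sequences no longer than the window are solved
as one exact domain — circular domains enumerate wrapping runs, which
makes the homopolymer-circle profile translationally constant to
machine precision.  Longer sequences are processed in overlapping
250-bp windows whose 50-bp flanks are discarded, each window treated
as an independent linear domain of its own length; window edges are
therefore the one place the approximation is visible, bounded by the
flank discard.  Within a domain, all single-run states are enumerated
exactly; two-run states are enumerated over runs that can possibly
enter a retained state (intrinsic cost `a + B` within the threshold
budget), with a 5000-run cap that is never reached at the defaults.
The exhaustive-enumeration oracle in the test suite bounds the
threshold error at ≤ 1e-4 in p(x) on short duplexes (observed ~3e-8).

**Null models.**  The global null permutes all bases uniformly; the
local null permutes each maximal coding/non-coding segment (segments
from the union of gene intervals; an origin-spanning run on a circle
is one segment).  Both conserve their composition claims exactly, and
the tests assert them exactly, not within tolerance.

## Motif and promoter scanning

IUPAC patterns are matched exactly at every placement on both strands
(minus-strand hits reported at forward-strand coordinates), overlaps
included, crossing the origin on circular inputs.  The two-box
promoter model scores each box by its fraction of matching positions
(IUPAC-aware; `N` always matches), accepts boxes at similarity ≥ the
tolerance (inclusive — "50% similarity" admits exactly 4/8), requires
both boxes on one strand in 5'→3' order, and constrains the spacer to
a closed range (σ³² defaults: CTTGAAAA, CCCCTNT, 11–15 bp, 0.5).  The
IHF consensus is stored as the contiguous 13-mer `WATCAANNNNTTR`.
Expected counts under an i.i.d. base model multiply per-position match
probabilities; observed-vs-expected uses the exact two-sided Poisson
test (doubled smaller tail, capped at 1) plus a normal z-score.

## Intergenic classes and bimodality

Adjacent gene pairs with a positive gap define one region each
(origin-spanning gap included on circles; overlapping pairs produce
none, with a warning): divergent ←·→, convergent →·←, tandem same-
strand, the latter split intra-/inter-TU by shared TU membership.
Per-region statistics are the mean and the minimum of the profile —
both are exported because duplex destabilization is an extreme-value
phenomenon, and the choice between them is a genuinely open question.

The visually motivated stable/unstable split of tandem regions is
operationalised as: *bimodal* iff the 2-component Gaussian mixture
beats the 1-component fit by more than 2 BIC units, or the Hartigan
dip test rejects at 0.05.  The dip statistic is computed by the
GCM/LCM modal-interval algorithm (implemented here; validated against
the known two-point-mass value of 1/4 and by calibration simulations);
its p-value is a seeded bootstrap against the uniform null, which is
conservative for unimodal bell-shaped samples.

## Neighbourhood conservation

Two genes are genome neighbours when at most `max_gap = 5` genes
separate them (circular rank distance), and network neighbours when at
most one intermediate node separates them in the interaction network.
Common connected components (CCCs) are computed by partition
refinement — split blocks into connected components alternately in
each graph until fixed point — which converges to the unique partition
into maximal sets connected in both graphs; a recursive-splitting
brute-force oracle checks this on random graph pairs.  Transcription-
network edges are symmetrized.

An ancestral component is *testable* in the descendant when ≥ 2
members have orthologs, and *conserved* when those orthologs induce a
connected subgraph of the descendant genome-neighbourhood graph (for
the interval-graph structure this reduces to: at most one cyclic rank
gap exceeds `max_gap + 1`).

**r-transcripton test.**  Each simulation repeatedly draws a size X
from the observed transcripton-size pool, places X distinct unused
genes within a window of 5 consecutive gene ranks (window drawn
uniformly among those with enough unused genes; X is redrawn up to 50
times before the simulation ends by exhaustion), retains the set when
≥ 2 members have descendant orthologs, and stops at 38 retained sets.
The simulation statistic is the number of retained sets conserved as
components; the reported p is `#{null ≥ observed}/n_sims`, with the
+1-corrected value alongside.  Because the statistic is a small
integer with heavy ties, this p is valid but conservative and cannot
be distribution-uniform; the calibration analyses therefore use the
rank-randomised (tie-broken) p, which is exactly uniform under
exchangeability, and additionally check the primary p for
super-uniformity.  TU fates (monocistronic / identical / similar /
split / merged-reorganized / unclassifiable) follow set relations
between a descendant TU's ancestral orthologs and the ancestral TU
inventory.

## Association statistics

Category-vs-stability tests are two-sample rank-sum tests (exact null
for groups ≤ 25 without ties, normal approximation with continuity
correction otherwise; two-sided by default, one-sided by flag), with
BH adjustment reported across all categories tested.  Category
representation uses the exact two-sided hypergeometric convention
(sum of outcomes no more probable than the observed one).  Multiplicity
comparison rank-tests per-gene label counts, with optional exclusion
of genes carrying a designated blanket label.

## Synthetic study conditions

The generator's defaults define the conditions every test and the
acceptance script run under; they are not tuned per test.

* `buchnera-like` preset: 550 genes in TUs drawn from sizes
  {1,1,1,1,2,2,3,4}, mean gene 93 bp and gap 16 bp (a ~600-kb,
  ~90%-coding chromosome scaled to ~60 kb so a full SIDD profile takes
  ~1 s), coding GC 0.26, non-coding GC 0.20; `ecoli-like` raises GC to
  0.52/0.46.  Sequences are i.i.d. per region — no codon structure —
  which is exactly the structure the base-composition null models
  assume, and sufficient for every consumer in scope.
* 30 planted transcriptons: runs of 2–5 consecutive genes, separated
  by > 5 genes so their CCCs stay distinct; network edges form a path
  through each run plus 20% genome-distant noise edges that provably
  cannot extend a planted component.
* Descendant: planted members always survive; other genes retained
  i.i.d. at 0.6; rearrangement keeps planted runs contiguous and
  permutes everything else as blocks (or shuffles fully, or not at
  all).  Gene sequences are carried over; intergenic sequence is
  redrawn.
* Sinks: 50-bp windows at 95% AT centred 125 bp upstream of target
  starts, strand-aware — the planted analogue of a promoter-associated
  destabilization centre.
* Category effect: labelled genes (default 50) receive upstream sinks;
  for the many-replicate statistical calibrations a Gaussian surrogate
  of promoter-window values is used instead (baseline 10 kcal/mol,
  s.d. 2.0 — the dispersion the sequence-level pipeline produces —
  shift 1.5 kcal/mol toward instability), isolating the statistical
  layer from the physics, whose end-to-end behaviour is verified once
  per suite at full scale.

Problem sizes used by the heavier analyses: r-transcripton calibration
at a 300-gene ancestor, 200 repeats × 200 simulations; planted-
significance at the full preset with 500 simulations; rank-test
type-I error with 10,000 null replicates at n = 30/30 and power with
200 replicates at n = 50/50.

What passing these tests does *not* show about real data: real
genomes have codon structure, shared promoter architecture and
correlated base composition that the i.i.d. generator lacks; the
synthetic orthology is exact and one-to-one, whereas real orthology
calls carry error; and planted effects are homogeneous across genes.
The pipeline's inferential machinery is validated here; its biological
conclusions on a real genome still depend on the quality of the
annotation, networks and orthology supplied.

## Degenerate inputs and numerical choices

Empty gene tables, single-gene genomes, zero-length gaps, overlapping
genes (warn; union segments / no region), windows longer than the
sequence (warn; empty), all-tied samples (rank p = 1, dip = 0), and
promoter tables with malformed rows (rejected with line numbers) are
all handled explicitly.  Boltzmann weights are computed relative to
the minimum-energy state; p(x) = 0 reports the ceiling rather than
−∞.  All stochastic components take explicit integer seeds, recorded
in outputs; the pipeline manifest hash-lists every output so reruns
with the same config and seed are byte-identical.

## Known limitations

* The SIDD model truncates at two simultaneous runs and bounded run
  length; strongly stressed or very long AT stretches approaching the
  run bound would need the unbounded multi-run treatment.
* Curvature, stacking and propeller twist are table-driven proxies,
  not mechanics; alternative published tables can be dropped into the
  YAML files.
* σ⁷⁰ promoter prediction is ingested, never computed; analyses that
  need transcription starts (5' UTR lengths, promoter presence
  fractions) are only as good as the supplied table.
* The two-box scan's similarity definition is stated exactly
  (matched-position fraction, inclusive threshold) but other tools'
  unpublished scoring will not match count-for-count.
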