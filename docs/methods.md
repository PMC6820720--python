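# Methods

## Problem

Selective ¹³CH₃ labeling of Ala/Ile/Leu/Val (and optionally Met/Thr)
methyls in an otherwise deuterated protein gives sharp methyl-TROSY
spectra even for very large systems, but the resonances must be assigned
to specific methyl groups before they are useful.  When backbone-based
experiments are unavailable, the only generally accessible data are
methyl–methyl NOEs.  `methylassign` assigns methyl ¹H/¹³C resonances by
matching the network of measured NOESY cross peaks to the network of
short inter-methyl distances computed from a known 3D structure.

## Expected peaks from structure

Each labeled methyl contributes one expected 2D [¹H,¹³C]-HMQC peak
(observation probability 1).  For every ordered methyl pair whose
*effective distance*

    d_eff = ( Σ_{i=1..3} Σ_{j=1..3} d_ij^-6 )^(-1/6)

over the nine inter-proton distances is below a cutoff `d_cut`, one
expected NOESY peak per direction is generated with observation
probability `p_noe` (default 0.1 — most expected NOEs at a generous
cutoff are not observed).  For nine equal distances d this reduces to
d_eff = 9^(−1/6) d ≈ 0.693 d, so a 5 Å effective cutoff admits
inter-carbon separations up to 5.0/0.693 + 2×1.1 ≈ 9.4 Å.  Leu δ1/δ2 and
Val γ1/γ2 geminal pairs additionally contribute short-mixing HCcCH-type
correlations (probability 1) when such a spectrum is available.

When the input structure lacks hydrogens, methyl protons are placed with
ideal staggered tetrahedral geometry (C–H 1.1 Å, 109.47° from the
carbon–stem bond, torsions 60°/180°/300° from the reference substituent).
Methyl rotation is not averaged: the r⁻⁶ sum over nine distances is
insensitive to the torsion origin at the precision required.  For
homo-multimers, chains with identical sequences are treated as symmetry
copies of one resonance set; the effective distance between two methyls
is the minimum over all copy pairs, so inter-subunit contacts map onto
the same resonances.

## Measured peak preparation

Measured NOESY lists may be filtered for donor/acceptor reciprocity and
signal-to-noise (S/N ≥ 2 by default).  The S/N cut is applied first and
reciprocity is evaluated among the survivors, so a peak whose mirror
partner is weak is removed as well (the conservative reading of applying
both filters).  Each side of every NOESY peak is attributed to the
residue-type class of the HMQC peak minimizing
max(|ΔH|/tol_H, |ΔC|/tol_C) over the side's available coordinates
(3D lists have one incomplete side and use the single coordinate);
peaks whose best match exceeds the tolerance on either side go to an
untyped catch-all list that downstream matching checks against all type
pairs, so no measured peak is discarded.  Residue types come from the
user (labeling schemes, per-peak annotations) or from packaged
chemical-shift statistics: Ala, Ile δ1 and a merged Leu/Val class own
their mean ± 1 s.d. shift boxes; peaks in the Ala/LeuVal overlap are
resolved greedily toward Ala up to the sequence count ("max-ala") or kept
fully ambiguous.

## Assignment optimization

The optimization unknown is the anchor map: which measured HMQC peak
carries each methyl's resonances.  Anchoring fixes the methyl's ¹H/¹³C
shifts, and every expected NOESY/geminal peak whose two methyls are
anchored maps to the best-matching measured peak within the tolerance
box (tolerances 0.4 ppm ¹³C, 0.04 ppm ¹H).  The score of a state is

    Σ_mapped p · Π_dims exp(−Δ²/2σ²)  −  λ · #degenerate atom pairs

with σ the nucleus tolerance, Δ the deviation of the measured coordinate
from the atom's anchored shift, and λ (default 0.5) a penalty per
same-nucleus atom pair whose anchored shifts coincide within tolerance.
The penalty is counted for methyl pairs that are degenerate as
resonances — both nuclei within tolerance, hence two atom pairs — and
deliberately not for near-degeneracy in a single nucleus: single-nucleus
proximity is a property of the measured spectrum, not of the assignment,
and penalizing it would make discarding assignments outscore making
them.  Several expected peaks may map to one measured peak (genuine
shift degeneracy); the penalty discourages but does not forbid it.
Unmapped expected peaks simply forfeit their probability mass.

Because anchored shifts coincide with measured HMQC coordinates, the
best match for an expected peak depends only on the anchor pair of its
two methyls.  All best matches are therefore precompiled into per-list
lookup tables, making score changes O(degree) and the search cheap (the
hot loop is compiled with numba).

The search itself is a steady-state evolutionary algorithm over anchor
states: a population (default 200) of random initial assignments,
tournament selection, recombination that inherits each methyl's anchor —
and hence all of its peak mappings — from one parent (a geminal pair
travels as one unit), light mutation, and a greedy local optimization of
every offspring (`local_iterations` proposals per call, default 15,000).
Local moves are: re-anchoring one random methyl (occasionally a full
best-improvement scan over its candidates), anchor swaps, cyclic
three-anchor rotations, simultaneous double swaps (which escape
coupled-swap local optima, including the stereo mirror of two geminal
pairs), joint re-anchoring of a geminal pair onto an anchor pair
supported by the measured geminal list, and joint re-anchoring of an
expected NOESY peak's endpoints onto an anchor pair strongly supported
by some measured peak.  Only strictly improving moves are accepted, so
the per-call score trace is monotone.  A call returns early when no
proposal has been accepted for a while (a pure compute saver).  The
generation budget (default 40, stagnation stop after 10 idle
generations) and offspring count (population/5) resolve the loop
structure the literature leaves open.  Each run is an independent
restart; run *i* uses seed `seed + i`, and all results are a pure
function of (inputs, configuration, seed).

## Consensus and confidence

Three batches of runs (default 100 per cutoff) are performed with
cutoffs `d_cut − 0.5`, `d_cut`, `d_cut + 0.5` and pooled before
consolidation, which de-sensitizes the result to the arbitrary cutoff
choice; a single-cutoff mode reproduces the degraded variant.  Per atom,
the consensus shift is the global maximum of a sum of Gaussians centered
at the per-run values with s.d. equal to the tolerance, located over the
values refined by a tol/20 local grid (ties toward the lowest ppm).  An
assignment is **strong** when more than a threshold fraction (default
0.8; 0.9 as a stricter option) of all runs agree with the consensus
within tolerance for both nuclei, and the methyl carries at least one
mapped methyl–methyl NOE (median over runs) — no strong assignment
without an experimental basis.  The threshold is interpreted as the
run-agreement fraction rather than the literal integral of the kernel
sum inside ± tolerance: a unanimous run set concentrates only ≈68% of a
single Gaussian's mass within ± 1 s.d., which would absurdly classify
unanimity as weak.

Geminal Leu/Val methyls carry no a-priori stereospecific identity, so in
each run the pair's two (¹³C, ¹H) shift pairs are redistributed by size
(ordered by ¹³C, ties by ¹H; each ¹H stays attached to its own ¹³C)
before per-nucleus consolidation.  This joint redistribution keeps the
¹H and ¹³C consensus mutually consistent, which consolidating the nuclei
independently does not, and no stereospecific claim is made.  The
geminal ordering key (¹³C first) is a package choice; the source
protocol specifies only "smaller/larger".

Evaluation against a reference shift list counts a strong assignment as
correct when both nuclei agree within tolerance (geminal pairs compared
as ordered pairs after the same redistribution); the explained-NOE
fraction is the mean over runs of the fraction of measured NOESY peaks
mapped by at least one expected peak.

## Synthetic data generator

The generator emulates the study conditions of a structure-based methyl
assignment experiment without requiring experimental downloads:

* Methyl groups are packed by rejection sampling in a sphere at a
  protein-like density of 4.3×10⁻³ methyls/Å³ (≈146 labeled methyls in a
  28 kDa AILV-labeled protein of ≈34,000 Å³), minimum separation 3.5 Å,
  geminal partners 1.8–3.0 Å apart, with ideal methyl protons on random
  stem orientations.  At this density the 5 Å effective-distance NOE
  network is essentially one connected component with mean degree ≈5,
  as in compact proteins; sparser packing fragments the network into
  small, intrinsically ambiguous islands.
* Shifts are drawn per methyl type from the packaged statistics, so
  realistic within-tolerance degeneracy occurs at natural rates.
* The HMQC list contains one peak per methyl minus dropouts; the NOESY
  list contains both directions of every pair under the simulation
  cutoff, each observed with probability `p_obs`, optionally
  de-reciprocated, jittered (s.d. expressed as a fraction of the
  tolerance), and contaminated with artifact peaks uniform in the
  occupied shift ranges; S/N values are log-normal.  A geminal HCcCH
  list is emitted for every Leu/Val pair.
* Ground truth (atom shifts, peak origins) is retained, and the exact
  generating state is reproducible from the seed.

What the generator does *not* emulate: spin diffusion and
distance-dependent NOE intensities, lineshape and overlap-induced peak
merging, temperature/sample variations between spectra, and
structure-vs-solution discrepancies (the coordinates used to generate
the data are the coordinates used to assign them).  Passing tests on
synthetic data therefore demonstrate the correctness and calibration of
the algorithmic machinery under controlled conditions, not performance
on any particular experimental system.

## Numerical and design choices

* Matching is box-limited: a measured coordinate farther than one
  tolerance from the anchored shift in any dimension cannot match.
* The effective distance sums the nine r⁻⁶ terms in sorted order, making
  the function exactly symmetric in its arguments.
* Diagonal expected NOESY peaks are off by default; intra-residue
  geminal NOE peaks are on by default (they are genuine short contacts),
  both configurable.
* Ile labeling defaults to δ1 only; γ2 is available through the scheme
  grammar (e.g. `I(d1,g2)`).
* Degenerate inputs: empty HMQC lists, non-NOESY lists passed to the
  filter, sequence/structure mismatches and infeasible packing all raise
  immediately, before any optimization.
* The consensus of an empty value set is undefined (atom reported
  unassigned, shift 999.0 in `.prot` output).
* S/N has no standard XEASY column; the writer appends a trailing
  `#SN <x>` comment token that the package's reader understands.
* Problem sizes in the test-suite and acceptance script (50-methyl
  benchmarks, 20 runs per cutoff, population 50, 3,000 local iterations,
  a handful of seeds) are reduced-budget study conditions chosen so the
  whole suite runs on a laptop-class single core; the defaults
  (population 200, 15,000 iterations, 100 runs) reproduce the
  full-budget protocol.

## Known limitations

* The scoring function is a reconstruction: the historical algorithm's
  exact weights are unpublished in the source describing this protocol,
  so this package fixes the Gaussian-alignment + degeneracy-penalty form
  documented above.
* Anchoring ties shifts to HMQC peaks; a methyl whose HMQC peak was not
  picked cannot be assigned (NOESY-only anchoring is not attempted).
* Sparse or fragmented NOE networks (isolated methyl pairs) are
  intrinsically ambiguous and will, correctly, come out weak.
* Near-degenerate same-type methyl clusters can sustain a coherent wrong
  solution across runs (a swapped pair that explains the data equally
  well); such errors are rare and spatially local, and the strong/weak
  classification is the guard against most of them.
* Runtime scales roughly linearly in the methyl count for fixed network
  density, but the evolutionary search is stochastic: hard instances
  (low information content) take the full generation budget.
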