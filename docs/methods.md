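# Methods

## Digestion model

RNase T1 cleaves single-stranded RNA on the 3′ side of guanosine, leaving a
2′,3′-cyclic phosphate on the upstream product and a 5′-OH on the
downstream product; the cyclic phosphate can hydrolyse to an open 3′-linear
phosphate (one water heavier). The enzyme is described by an `EnzymeSpec`
(cleavable residue set plus termini chemistry), so other single-residue
cutters can be plugged in, but only T1 chemistry is exercised by the tests.

Candidate generation enumerates every fragment delimited by construct ends
and/or cleavage sites with at most `max_missed` internal sites (default 8 —
partial digests routinely retain that many missed cleavages in their longer
products; configurable). Internal fragments are expanded over both 3′
termini forms; the construct's native 5′ end (cap species, else
triphosphate) is attached only to position-1 fragments; fragments ending at
the construct 3′ end keep 3′-OH. Candidates above a 30 kDa processing cap
are dropped. The enumerator is verified against brute-force digestion over
every cut-site subset, exhaustively over all cleavable/non-cleavable
patterns up to length 12 (fragment spans depend only on that pattern) plus
random full-alphabet sequences.

Uniqueness counts all substring placements of a fragment's sequence in the
full construct — including the poly(A) tail, because that is the ambiguity
an identification actually faces. A sequence whose required termini are
chemically impossible at every placement is *nonspecific*.

## Mass convention

Internal residues are nucleoside monophosphates minus water, so every
residue carries one phosphate: A 329.05252, C 305.04129, G 345.04744,
U 306.02530, m1Ψ 320.04095 Da (m1Ψ = U + CH₂; 2′-O-methylation likewise
adds CH₂). A fragment's neutral composition is

    Σ(residues) + H₂O + Δ(5′ terminus) + Δ(3′ terminus)

with Δ(cyclic) = +HPO₃ − H₂O, Δ(linear) = +HPO₃, Δ(p/pp/ppp) = n·HPO₃, and
a cap species contributing its own composition delta plus 2′-O-methylation
of the residues it covers. Under this accounting the last residue's own
phosphate serves as the 3′ phosphate of a 5′ backbone piece, which makes
the fragment-ion identities exact: c_i + y_(n−i) = M + H₂O and
w_j = y_j + HPO₃ for every cleavage ordinal; a_i = c_i − HPO₃ and a-B
additionally loses the free nucleobase. Atomic masses are hard-coded IUPAC
monoisotopic values (no network dependency) and cross-checked in the tests
against pyteomics' NIST table, which serves as the independent
atomic-mass-sum oracle throughout. Negative-mode ions are deprotonated
species: m/z = (M − z·m_p)/z with the proton mass, not the H-atom mass.

## Identification and filtering

MS1 peaks (neutral masses, or m/z + charge which are converted first) match
every candidate within 5 ppm; ambiguity is preserved as one record per
peak–candidate pair and resolved only by the uniqueness/coverage layer.
The MS2 confidence score is this package's own, documented surrogate for
proprietary search-engine scores:

    0.5 · (fraction of theoretical c/y/w/a-B ions at z = 1–2 matched)
  + 0.5 · (fraction of observed intensity carried by matched peaks)

It is deterministic, bounded in [0, 1] and monotone in matched evidence; a
noiseless complete ion set scores exactly 1. The filter stack mirrors
standard oligonucleotide map-generation settings: specific termini only,
at most one placement, |Δppm| ≤ 20 (kept as a separate post-filter from the
5 ppm detection tolerance — both are exposed since they are distinct
settings), confidence ≥ 0.90, MS2 evidence required, observed monoisotopic
mass required. Filtering is idempotent and monotone; the removal report
charges each record to the first criterion that rejects it.

## Coverage, merging, decoys, maps

Coverage marks every position of each *unique* identification's span;
percent coverage divides by the non-poly(A) position count, and fragments
overlapping the tail contribute only their non-tail positions (numerator
and denominator exclude the same region). Merging digests takes the union
of per-condition masks while retaining provenance; merged percent is
therefore never below any individual percent. The decoy control re-runs
the *entire* pipeline — candidate enumeration, matching, scoring,
filtering — against composition-preserving shuffles of the construct
(exact per-base counts, hence exact length and GC), which removes
GC-sampling variance from the specificity comparison. Decoy coverage is
typically a few percent, driven by short fragments whose sequence happens
to recur in the shuffle — the same behaviour seen when random control
sequences are searched alongside the true sequence.

Maps are rendered with matplotlib's SVG backend. The linear style
lane-packs fragment bars over a position axis above a per-position
coverage track; the spiral style walks the sequence along an Archimedean
spiral whose turn count grows with √length so any construct fills the
square canvas. Colours: one per source, red for positions covered by two
or more sources, gray for no coverage; layout is deterministic
(fixed svg hash salt).

## Multi-attribute monitoring

Capping efficiency is 100·Σ(capped areas)/Σ(all areas) over a 5′-terminal
species table (capped species plus uncapped tri-/di-/monophosphate forms);
it is scale-invariant and bounded. Poly(A) lengths are assigned as
n = round((M − M₀)/329.05252) with M₀ the tail fragment's termini-plus-
linker base mass (18.0106 Da for a bare 5′-OH/3′-OH tail); assignment
requires a residual within 0.25 Da — generous at the 329 Da residue
spacing yet far below half a residue, so integer assignment is robust.
Unassignable peaks are dropped, never redistributed; modal length takes
the smallest length on abundance ties. A helper solves adjacent
negative-mode charge-state pairs (z = (m₂ + m_p)/(m₁ − m₂)) for users
without deconvoluted input; it is documented as approximate and full
isotope deconvolution is out of scope (areas and neutral masses are
accepted as input).

## Synthetic data generator

The simulator emulates an online immobilized-enzyme digest whose extent is
set by residence time and temperature. Each cleavable site i is cut
independently with probability p_i = 1 − exp(−k_i·τ):

| parameter | default | meaning |
|---|---|---|
| `column_volume` | 70 µL | plausible bed volume for a 2.1 × 30 mm cartridge; configurable, not asserted as any instrument's true value |
| `flow_rate` | 50 µL/min | τ = volume/flow = 84 s at default |
| `k_ref` | 0.008 s⁻¹ | gives p ≈ 0.5 at the 25 °C/50 µL·min⁻¹ reference point — a mid-partial digest |
| `q10` | 2.0 | typical enzymatic temperature coefficient |
| `accessibility_sigma` | 1.0 | lognormal spread modelling structured vs unpaired guanosines |
| `hydrolysis_fraction` | 0.16 | linear-phosphate share of cut termini, the level reported for online digests |

The accessibility draw depends only on the seed, so digests of one
construct at several temperatures share site accessibility as a real
molecule would; mean fragment length is then monotone in temperature and
flow rate for any seed. Expectation mode (the default) computes exact
expected abundances, n·p_left·p_right·Π(1−p_interior), and splits each cut
terminus exactly by the hydrolysis fraction — it removes Monte-Carlo flake
from tests; sampling mode draws per-molecule cut patterns and binomial
termini. Both conserve nucleotides: Σ(length × abundance) = n·L.

MS emission places up to three consecutive charge states per fragment
inside the 450–3000 m/z scan window (weights 0.5/0.3/0.2), adds Gaussian
ppm noise (default 2 ppm) to every m/z, and produces MS2 spectra
(theoretical ion set, jittered near-uniform intensities) for the 1000 most
abundant precursors — of the order of what data-dependent acquisition
selects over a gradient of this length. The default study conditions used
by the acceptance script are 5/25/45 °C at 50 µL/min, 10⁴ molecules,
a 930-nt construct with a 70-nt tail, capping efficiency 0.863, and a
poly(A) length distribution N(71.8, 1.5) whose rounded mode is 72 nt.

What the generator does *not* emulate: chromatographic elution and
retention times, isotope envelopes and their deconvolution errors,
intensity-dependent noise, co-isolation/chimeric MS2, or carryover.
Passing round-trip tests therefore demonstrate the correctness and
internal consistency of the computational pipeline under controlled noise,
not instrument-grade performance on real data.

## Parameter recovery

The hydrolysis fraction is re-estimated from identified termini as the
MS1-area-weighted linear share of cut termini. Two selection rules keep
the area weighting unbiased: a peak counts only when every candidate it
matched shares one terminus class, and any span touched by a
mixed-terminus ambiguity is excluded with *both* its forms (dropping one
side only would over-represent the counterpart); spans whose cyclic form
falls below the scan window's singly-charged cutoff are excluded because
only their heavier linear form would be detectable. The recovery test
checks the estimate against the binomial 95 % interval at the simulated
molecule count (10⁴); peak-level tolerance losses remove whole abundance
blocks and hence inflate the estimator's variance beyond a binomial at the
(much larger) identified-termini count.

## Numerical and interface choices

* Coordinates are 1-based inclusive everywhere, matching how sequence maps
  are read; boolean masks use index 0 = position 1.
* FASTA T residues are transliterated to U with a warning (constructs are
  often stored as DNA templates); multi-record FASTA is an error.
* Decoys, digests, MS noise and spectra ordering are all deterministic per
  seed; pipeline runs write the seed, package version and a config hash
  into every table header, and identical configurations reproduce
  byte-identical CSVs.
* Imported identification tables (arbitrary search-engine exports) are
  absorbed through a column-alias map; confidence values above 1 are
  interpreted as a 0–100 scale; positions missing from the table are
  recomputed by substring placement and uniqueness is re-classified.
  An optional "Best ASR"-style column passes through untouched — it is a
  proprietary metric and is never computed here.

## Known limitations

* The independent-site Bernoulli cutting model has no cooperativity and no
  explicit secondary-structure input; accessibility is a static lognormal.
* The confidence score is not calibrated against any commercial engine;
  its 0.90 default threshold mirrors common practice, not a benchmark.
* Isobaric candidates within the MS1 tolerance all receive the full peak
  area (ambiguity is preserved, not arbitrated), so area-based summaries
  other than the terminus estimator should be read with that in mind.
* Real charge-state envelopes, adducts and isotope structure are not
  modelled; the adjacent-pair deconvolution helper assumes clean
  consecutive charge states.
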