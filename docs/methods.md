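# Methods

This note documents the models, conventions and numerical choices behind
`casarray`, and what its synthetic fixtures do and do not demonstrate.

## Coordinates, alphabets, randomness

All sequences are stored as uppercase DNA, top strand 5′→3′; RNA views
(T→U) are produced only for folding. Coordinates are 0-based, half-open.
Every stochastic routine takes an explicit seed (or a
`numpy.random.Generator`); the same seed reproduces the same output
byte-for-byte.

## Spacer generation and the benchmark library

`generate_spacer(length, gc_target, seed)` realizes the GC target as an
exact count: `round(gc_target·length)` (half-up) positions are drawn
uniformly without replacement and assigned G or C with equal
probability; the rest are A or T with equal probability. Exact-count
construction makes library composition testable exactly, at the cost of
a small quantization of the target (e.g. 0.39 on a 25-mer realizes
10/25 = 0.40).

The benchmark library is 45 + 6 = 51 dummy spacers of 20 nt: five per
10 %-GC decile from 10 % to 90 %, plus six pilot spacers spanning
30–80 % GC. Only the pilot range is fixed by the recipe; their
per-decile composition (one each at 30, 40, …, 80 %) is this package's
choice and is recorded in the library's `recipe` field.

## GC-window statistics

`sliding_gc` emits full-width windows (default 5 nt) at every start and
then one window each of widths 4, 3, 2 anchored at the 3′ terminus, for
(L−4) + 3 windows on an L-mer — 19 on a 20-nt spacer. The shrinking tail
raises resolution where it matters: adjacent to the downstream cleavage
site.

`group_profiles` splits a library into response tertiles *by count*
(sizes as equal as possible, ties broken by stable input order) because
the grouping boundary is genuinely open; the choice is surfaced in the
group records. Standard error is the sample standard deviation (ddof=1)
over √n.

`window_predictive_power` fits, per window start, an ordinary
least-squares regression of response on window GC across the library and
reports R² as the squared Pearson correlation; degenerate fits
(zero-variance response or predictor) are defined as R² = 0. R² is
invariant under affine transformation of the response, which the suite
checks.

Natural spacers (25–36 nt) are compared by 3′-anchored stacking:
sequences longer than 25 nt lose their 5′ excess, shorter ones are
left-padded with gaps, so every row's 3′ terminus aligns. Column
statistics exclude gaps from both numerator and denominator; all-gap
columns are missing and drop out of window means. The IUPAC consensus
keeps, per column, every base at frequency ≥ 0.25 among non-gap
residues and emits the minimal covering code — the threshold is chosen
so a 50/50 two-state column yields a two-fold code (C/T → Y, as in the
separator motif GTYTA) and is configurable.

## Structure scoring

The interference score of a spacer is max(0, −ΔG_ensemble) of the folded
concatenation spacer + downstream gRNA (repeat + spacer), joined
directly with no linker — the two are adjacent in the unprocessed
transcript. Two interchangeable backends satisfy the same contract:

- `thermodynamic` (default): ViennaRNA's partition function at 37 °C,
  default parameter set. Ensemble free energies depend on the energy
  parameter set and version, so score *magnitudes* are
  backend-versioned; the package's claims are about ordering and sign.
- `oracle`: an exact weighted Nussinov dynamic program maximizing
  Σ pair weights (GC = 3, AU = 2, GU = 1) over pseudoknot-free
  structures with hairpin loops ≥ 3 nt, rescaled at 0.8 pseudo-kcal/mol
  per weight unit. It is exact (the suite checks it against exhaustive
  enumeration up to 14-mers), fully deterministic and dependency-free,
  and doubles as the independent oracle for the thermodynamic backend's
  qualitative properties.

Backends are never substituted silently; requesting an unavailable one
raises an error that names the alternative.

Risk flags: `HIGH` if the last-3-nt GC fraction is ≥ 2/3 (two of the
three residues next to the cleavage site are G/C — the last three bases
are the single most predictive window); otherwise `ELEVATED` if the
context score strictly exceeds the library's 75th percentile; otherwise
`LOW`. Both cutoffs are package choices, exposed as parameters. Note the
percentile rule is relative: in a tiny library the top-scoring spacer is
flagged unless scores tie.

## Array construction and fragment prediction

An `ArrayDesign` is leader + Σ(separator? + repeat + spacer) +
(separator? + trailing repeat) + 3′ flank, with typed features that tile
the sequence exactly (checked on construction, and by a GenBank
round-trip test). A separator policy assigns one entry per cleavage site
(i.e. per repeat, trailing repeat included): none, the species' full
natural separator, or any literal. The trailing repeat defaults on — a
two-gRNA assay array then has three cleavage sites.

Cleavage is modelled exactly at each repeat's first residue;
intra-repeat cut offsets are not modelled. Because separators sit
immediately upstream of repeats, each separator stays attached to the
*upstream* fragment: single-gRNA fragments are repeat + spacer
(+ following separator), and the leader fragment absorbs the first
separator. For the two-gRNA assay layout (57-nt leader, 41/42-nt units,
158-nt trailing region) this yields fragments 57/41/42/158 without and
61/45/46/158 with the AAAT-everywhere policy.

The polyadenylation screen searches the sense strand for 12 human
poly(A)-signal hexamer variants (AATAAA, ATTAAA, TATAAA, AGTAAA, AAGAAA,
AATATA, AATACA, CATAAA, GATAAA, AATGAA, TTTAAA, ACTAAA), overlapping
occurrences included; the motif set is configurable.

## Ligation planning

Constraints: single-stranded oligos ≤ 60 nt; internal junctions are 4-nt
5′ overhangs; overhangs must be pairwise distinct *globally* (pot
products are ligated together in a second round, so per-pot uniqueness
would not prevent misligation), non-palindromic, and no overhang may be
the reverse complement of another (both exclusions toggleable); ≤ 8
duplexes per pot, pots balanced to within one duplex, larger pots first;
plan ends blunt (In-Fusion joins the array to the vector). The planner
enforces a fragment cap of max_oligo − overhang_len for every fragment —
slightly tighter than strictly necessary for internal duplexes, but it
guarantees both strands of every duplex respect the cap.

Search: junctions start at the most balanced spacing for
⌈L / (cap − overhang)⌉ fragments — one overhang short of the cap, since
at the cap exactly the junctions have no slack — and are perturbed
deterministically (0, +1, −1, … up to ±24) with backtracking. A node
budget (200 000 placements) bounds pathological backtracking; on
exhaustion the planner retries with one more fragment, up to +16, then
raises an explicit infeasibility naming the first violated constraint
(e.g. duplicate overhangs on homopolymer input). Plans are verified
before being returned; `verify_plan` independently rechecks lengths,
complementarity, overhang constraints, pot partitioning and the exact
round trip from oligos back to the source sequence.

## Processing quantification

Peak areas are taken as proportional to RNA mass (the instrument reports
mass, and the worked 0.28 arithmetic assumes it). Replicates are
normalized to the lowest-total replicate, markers excluded from the
totals. Peak→fragment matching uses a ±10 % relative sizing tolerance
(configurable): within each connected cluster of mutually in-tolerance
peaks and fragments, equal counts resolve one-to-one by sorted order; a
single peak may stand for several fragments only when they form a
declared co-migrating group (e.g. a 41/42-nt doublet); otherwise the
ambiguity is an error listing candidates. The 25-nt sizing marker is
always excluded. Percent-of-max = 100 × (single-gRNA area / total
non-marker area) / theoretical ceiling; it is invariant under uniform
area scaling, and the ceiling under uniform length scaling.

## Synthetic electropherograms

`simulate_electropherogram` models an array pool processed to
completeness c: every cleavage fragment appears with area ∝ c·length,
the remaining (1−c) of the pool appears as one intact-transcript peak,
plus the 25-nt marker; multiplicative Gaussian noise perturbs areas
(σ = 2 %) and sizing (σ = 0.5 %). It deliberately omits partially
processed intermediates, baseline drift and peak overlap — so the
round-trip test (recovered percent-of-max within ±2 points of 100·c)
validates the quantification arithmetic and matching logic, not the
instrument's peak calling on real traces, where intermediates and
co-migration would add error the matching tolerance and fragment groups
are designed to absorb.

## Species registry

The registry ships mature repeats for LbCas12a and AsCas12a from
standard literature and the printed synSeparators (AAAT, TTTT). The full
16-nt separator entries are synthetic placeholders constrained to the
documented properties (5′ GTYTA motif, AT-rich, 3′ terminus equal to the
synSeparator), labelled as such in their provenance fields; any analysis
that depends on the full separator itself must override them with the
published sequences. Nothing in the test suite or acceptance script
depends on the placeholder content.

## Problem sizes

The test suite and acceptance script run the library at its native size
(51 spacers), the structure-sign check on 200 random 20-mers against a
41-nt context, the planner round-trip on 500 random sequences of
50–3000 nt, and the capability demonstration on a 30-gRNA (~1.5 kb
flanked) array — the scales the package is intended for.

## Known limitations

- No pseudoknot prediction: the repeat's natural pseudoknot is outside
  the folding model; scores concern spacer-context pairing only.
- No genome-wide spacer discovery, PAM scanning or off-target search.
- No melting-temperature or synthesis-cost optimization of oligos.
- No kinetic model of Cas12a cleavage; time courses are quantified
  point-wise.
- Exact ensemble free energies (and any R² computed from them) are
  ViennaRNA-version-dependent; only signs/orderings are asserted.
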