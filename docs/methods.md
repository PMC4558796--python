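# Methods

This note documents the models, scores and procedures implemented in
`blockshift`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions that
make runs reproducible.

## Alignment model and coordinates

A pairwise alignment is two gapped rows (query, template) over one column
axis, with three enforced invariants: equal row lengths, no gap–gap
column, and each row ungapping exactly to its sequence.  All internal
coordinates are 0-based half-open; rendered reports are 1-based.  `.` is
accepted as a gap on input (A2M dialects) and normalised to `-`; input is
case-insensitive.  The first FASTA record is the query unless the caller
says otherwise — the package never guesses which sequence is closer to the
structure.

## Blocks

Template secondary structure is supplied per residue (3-state `H/S/C`, or
a DSSP string collapsed as H,G,I → H; E,B → S; else C — note DSSP's own
`S` code means *bend* and collapses to coil, while plain 3-state files may
use either `S` or `E` for strand).  Maximal H/S runs become elements,
subject to minimum lengths of 4 (helix) and 3 (strand); element
delineation algorithms themselves (DSSP and the like) are external inputs
by design.  A block is the contiguous column window covering one
element's template residues.  Its non-gap fraction is aligned pairs over
element length (anchored on the template, not on columns); blocks under
the 0.5 default are reported but never refined, because a mostly-gapped
block has too little signal to shift responsibly.

## Sequence score

Profiles are built over the 20-letter alphabet from aligned-FASTA MSAs
projected onto the master's columns, with two pre-filters mirroring
ordinary profile hygiene (drop rows above 0.94 identity to the master;
optional minimum coverage).  Henikoff position-based weights are scaled
to sum to the profile's effective sequence number
neff = exp(mean column entropy), so effective counts grow with diversity
while duplicated rows collapse to a single observation.  Smoothed
frequencies use substitution-conditional pseudocounts,
p̃(a) = (n(a) + τ·g(a)) / (Σ_b n(b) + τ), where g(a) = Σ_b f(b)·P(a|b)
and P(a|b) is derived analytically from the rounded half-bit BLOSUM62
scores (λ = ln 2 ⁄ 2, columns renormalised) against the standard BLOSUM62
background composition.  τ defaults to max(1, 5 ln neff): shallow
profiles get proportionally more smoothing.  `X` contributes background
composition wherever identity matters.

The column score is the symmetric log-odds form

    s(x, y) = ½ Σ_a [ n_x(a) ln(p̃_y(a)/p_bg(a)) + n_y(a) ln(p̃_x(a)/p_bg(a)) ]

(nats).  It is exactly zero when both smoothed columns equal the
background, symmetric by construction, and grows when the columns share
over-represented residues.  A block's sequence score is the sum over its
aligned pairs.  Profiles can also be synthesised from a single sequence
(one-hot plus pseudocounts), so the tool runs with no MSA at all.

## Structure score

Contacts are unordered template residue pairs with |i − j| ≥ 2 (immediate
sequence neighbours touch trivially and carry no register information;
the separation is configurable) and distance strictly below 6.5 Å under
one of two definitions: distance between side-chain centers (the default,
paired with the bundled Miyazawa–Jernigan energies) or minimum distance
between any side-chain atoms (paired with user-supplied matrices in mode
`O+G+M`; without a user matrix that mode falls back to the MJ energies
over any-atom contacts, with a logged notice).  A side-chain center is
the centroid of side-chain heavy atoms; glycine and side-chain-less
models fall back to CA with a warning, standard practice for
contact-potential work.  Contacts involving residues the structure does
not resolve are dropped.

Published contact energies are negative for favorable pairs, so the score
of an aligned pair (template i, query i′) is the **negated** energy sum
over i's contact partners' aligned query residues; higher is better, and
a partner aligned to a gap contributes zero rather than rewarding the
destruction of contacts.  Custom matrices are interpreted with the same
energy convention (lower = more favorable) and must be symmetric.

Because partners may lie anywhere in the template, structure scores are
evaluated against the *current full alignment state*, which is why blocks
are refined sequentially N → C with accepted variants committed before
the next block is scored (a flag can freeze the state instead).

## Variants

Three families per block: *Original* keeps the gap pattern and shifts the
query by k (sign convention: +k moves query residues toward the
C-terminus, i.e. template residue t takes the query residue assigned to
t minus k); *Left*/*Right* first pack the block's query residues against
one end of the element, consolidating internal gaps on the opposite side,
then shift.  Mode `O` evaluates Original k = ±1…±4 (≤ 8 variants); modes
`O+G`/`O+G+M` evaluate the Left and Right families at k = 0…±4 (≤ 18
unique candidates) with the untouched original retained as the incumbent.
Duplicates are detected by realized block pair set, first listed wins
(family order Original, Left, Right; ascending shift within family).

Shifting borrows query residues from, or returns them to, the loops
adjacent to the block.  A loop whose residue content is unchanged keeps
its original columns byte-for-byte — so the incumbent realization is the
identity.  A changed loop is re-gapped deterministically by packing its
query residues left against its template residues, leftovers gap-aligned
at the right; a miniature re-alignment of loops was deliberately
rejected so that every accepted change is attributable to block scores.
Consequences worth knowing: returning residues to a loop displaces that
loop's previous pairing (visible in the planted-shift fixtures), and a
shift that would consume residues committed to another element's block,
or run past a sequence end, is infeasible and silently omitted rather
than generated in a broken form.  Residue content of both sequences is
conserved exactly under every realization.

## Decision rule

Sequence and structure scores of the incumbent and all unique variants
are z-standardized across the candidate set (sd 0 maps all z to 0) and
combined as S_comb_I = w₁·z_seq + (1−w₁)·z_str, S_comb_II likewise with
w₂.  Filter 1: the variant maximising S_comb_I must *strictly* exceed the
incumbent's, else everything is rejected.  Filter 2: the selected variant
must also strictly exceed the incumbent's S_comb_II.  Ties keep the
original; among tied maximal variants the first in canonical order wins.
The weights behind the published tool are not public; the defaults here
are w₁ = w₂ = 0.5, exposed in the configuration, and a `calibrate`
subcommand grid-searches the weight on synthetic recovery cases rather
than baking in an unverifiable constant.  The SVM-based second filter of
the original method (mode `O+G+M+S`) is a trained artifact that cannot be
reproduced from public information; the mode flag is reserved and
rejected with a clear message.

The identity gate applies before any scoring: refinement runs only when
the template-to-structure sequence identity (computed over the aligned
positions of a global alignment between the two sequences) is strictly
greater than the threshold, default 0.5.  How a homolog structure should
be mapped onto the template is not specified anywhere authoritative; this
package uses the global-alignment mapping, taking all aligned pairs.

## Global aligner

The built-in pairwise aligner is a standard affine-gap global DP (gap of
length L costs open + (L−1)·extend, defaults 10/1, BLOSUM62) with
deterministic tie-breaking (diagonal > up > left).  It exists as plumbing
— for the template↔structure mapping and for unaligned input — not as a
contribution; its optima are cross-checked in the tests against
Biopython's independent implementation.

## Synthetic generator

`make_case` builds: a template of `n_blocks` ideal helices (CA radius
2.3 Å, rise 1.5 Å, twist 100°; one CB pseudo-side-chain 1.0 Å radially
outside the CA, a displacement chosen so the canonical i/i+3 and i/i+4
helix neighbours fall inside the 6.5 Å cutoff while i/i+2 stays outside)
joined by extended 10-residue loops; helix sequences with hydrophobic
residues at heptad positions 0 and 3 cycling through LIFVM and polar
positions cycling through EKSQA with period 5, so no composite period of
4 or less exists and shifts up to ±4 can never tie the true register; a
query obtained by substituting template residues at rate
1 − signal_strength under the BLOSUM62-conditional model; profiles that
mix one-hot columns with background by the same factor (depth 10
pseudo-observations per column); and a starting alignment produced by
applying the planted shifts with the package's own variant-realization
machinery.  Defaults: 3 blocks of 12, loops of 10, signal_strength 0.7
("moderate noise"), all deterministic given one integer seed.

What this emulates: the misregistration error class, hydrophobic
periodicity, contact-bearing elements, profile sharpness scaling with
conservation.  What it does not: real β-sheet pairing geometry, long-range
tertiary contacts between elements (each helix only contacts itself, so
structure signal is weaker and mostly edge-driven — much like the
exposed-edge-strand failure mode of the real method), structurally varied
loops, alignment errors other than rigid block shifts, and realistic MSA
depth/phylogeny.  Recovery results on these fixtures therefore
demonstrate correctness of the machinery and of the decision logic under
a known truth, not expected accuracy gains on real proteins.

## Problem sizes and tolerances

The test and acceptance runs use 76-residue templates (3 × 12-residue
helices plus loops), 20 noise-free and 50 moderate-noise seeded cases —
ample to exercise every decision path while keeping a full run in
seconds.  Floating-point comparisons in tests use pytest's default
relative tolerance; the contact cutoff is located by bisection to 10⁻⁴ Å
when verifying strictness.  Scores are reported to 3 decimals in text
reports and 6 in JSON; reports carry no timestamps, so identical inputs
produce byte-identical files.

## Known limitations

* Loop re-gapping is positional, not score-driven; a refined alignment
  can trade loop pairs for block pairs (loops are not scored).
* Only PDB-format structures, one chain, first model by default; mmCIF is
  out of scope.
* The sequence score is the symmetric log-odds core of profile–profile
  comparison without the statistical-significance machinery of full
  profile-comparison suites.
* Query secondary structure is accepted for display only; it plays no
  role in scoring (the feature set that used it belongs to the
  unavailable SVM filter).
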