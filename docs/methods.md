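# Methods

## Mass model

All masses are monoisotopic, computed from IUPAC/CODATA atomic masses
embedded as constants to ≥ 6 decimal places (C 12 exactly, H 1.0078250,
N 14.0030740, O 15.9949146, S 31.9720710, …).  Only singly protonated
positive-mode species are modelled: `protonated_mz(f) = mass(f) +
1.007276 Da`, i.e. an H atom minus one electron.  Adding the proton
*mass* rather than the H-atom mass is the convention that reproduces
four-decimal reference values such as 257.1132 for C11H16N2O5; the two
conventions differ by the electron mass (0.00055 Da), which is visible
at that precision.

Theoretical m/z are reported at 4 decimals.  Comparisons against
two-decimal printed fragment values use round-half-up
(`round_half_up`), because published m/z tables round ties up while
Python's `round` is banker's.

`ElementCounts` serves two roles: a molecular species (all counts ≥ 0)
or a signed composition delta such as the C2H4 gap between Val and Ala
residues.  `monoisotopic_mass` rejects deltas; their signed mass is
available as `.mass`.

## Residue library

Residues are in-chain units (free amino acid − H2O).  The library
ships the 20 canonical residues plus Hyp (= Pro + O), MeEGlu (= Glu +
CH2) and PyroGlu (= Glu − H2O), flagged `unnatural`.  Leu and Ile are
kept as distinct entries with identical composition.  User extensions
go through a YAML/dict override (code → name, formula, unnatural,
extra diagnostic ions); the packaged set is never edited in place.

Diagnostic-ion rules are declarative and derived at load time:

* every residue: the immonium ion, residue − CO + H, charge +1;
* Pro: the DKP ring companion ion at residue + H (m/z 98.06);
* Leu/Ile: the immonium ammonia-loss ion (m/z 69.07) — retained as an
  optional side-chain diagnostic for both, *not* as a Leu/Ile
  discriminator, since their compositions are identical;
* Tyr: side-chain quinomethide neutral loss C7H6O from the precursor;
* MeEGlu: methanol neutral losses −CH3OH and −(CH3OH + CO).

Phe's immonium (120.08) doubles as its side-chain diagnostic and needs
no extra rule.

## Fragment prediction and matching

Cyclic dipeptides are predicted as: precursor; ring neutral losses
−H2O, −CO, −(CO+H2O); methyl-ester losses when a residue carries one;
per-residue immonium, companion ions and side-chain losses.  No
combinatorial ring-opening fragmentation or intensity prediction is
attempted.  Linear peptides get the standard b/y ladder (b_i = first i
residues + proton; y_i = last i residues + H2O + proton) plus residue
diagnostics; position-resolved modification tags shift every ion
containing the tagged residue.

Peak matching is greedy nearest-m/z within tolerance, one-to-one in
both directions: candidate (fragment, peak) pairs are taken in order of
increasing distance, exact ties broken toward the lower predicted m/z.
This makes matching deterministic, idempotent and invariant under peak
permutation.  Intensities are ignored in matching (presence/absence
evidence only) but retained for reporting.

Default tolerances: 10 ppm precursor, 0.02 Da fragments, 0.01 Da when
matching edge mass differences against residue-exchange deltas.  All
are configurable (`PipelineConfig`, YAML-loadable).

## Evidence tiers

Matched fragments are counted by class and combined as
`2·immonium + 1·neutral_loss + 1·diagnostic` (weights configurable).
Tier *confident* requires the immonium ions of both residues (one ion
suffices for a homodimeric CDP) or one immonium plus two neutral
losses; *candidate* requires ≥ 2 matched fragments of any class;
anything else, or a precursor outside tolerance, is *weak*.  The
immonium-dominant weighting mirrors which ions are decisive when an
analyst confirms a DKP by eye; since no quantitative weighting is
established for this evidence, the cut-offs are exposed in config
rather than hard-coded.

## Propagation

Residue-exchange rules are all pairwise composition differences among
library residues, deduplicated by composition delta (so one rule for
CH2 lists Gly↔Ala, Val↔Leu/Ile, Ser↔Thr, Asp↔Glu, Glu↔MeEGlu, …).
Zero-delta pairs (Leu↔Ile) carry no precursor-mass signal and are
excluded.

Propagation is breadth-first within each cluster, to a fixpoint: an
unannotated neighbour whose precursor delta matches a rule is proposed
every compatible single-residue exchange of the annotated node's
candidate; a proposal must pass the precursor window and reach the
acceptance tier on the neighbour's own spectrum.  Conflicting proposals
keep the highest weighted evidence; exact ties whose candidates differ
only by Leu↔Ile merge into one "Leu/Ile" annotation, other ties are
marked unresolved with every tied name emitted in the report tag.
Cross-cluster steps are restricted to a whitelist of deltas (H2O by
default — the Glu↔PyroGlu relationship, which in practice links a Glu
cluster to its pyroglutamate analogues elsewhere in the network).
Seeds are never overwritten and re-running propagation on its own
output is a no-op.

Node processing order is ascending (precursor m/z, RT, id) everywhere,
so reports are reproducible byte for byte.

## De novo reconciliation

A dipeptide hit carrying a net −18.011 ± 0.02 Da tag (or whose node
precursor already equals residues + proton) is isobaric with the DKP.
It is revised to the cyclic form when the CDP evidence reaches the
acceptance tier *and* the node's cluster already contains a
CDP-annotated node — cluster context is what distinguishes a genuine
DKP from a real dehydrated linear peptide.  For Glu-containing hits the
competing explanation, a linear peptide with Glu cyclized to PyroGlu,
is scored on the same spectrum and wins only with strictly stronger
evidence.  Hits longer than two residues pass through unchanged.
De novo rows are joined to nodes by feature id, falling back to nearest
precursor within 10 ppm and RT within 0.25 min — a declared convention,
since result tables in the wild rarely share keys with network exports.

## Isomer classification

Annotations are grouped by elemental formula.  A composition subgroup
of exactly two members with distinct RTs is a *diastereomer pair*
(identical constitution; C18 reversed phase separates the epimers);
two or more distinct compositions under one formula are *positional
isomers*; larger same-composition subgroups are *unresolved*.  The
Leu/Ile elution-order heuristic (Ile elutes earlier within a
same-formula pair) is opt-in and labels its assignments as heuristic;
by default Leu/Ile stays merged.

## Synthetic data

The fixture generator emulates the inputs of an FBMN study with
planted ground truth.  Spectra are the predicted fragment lists minus
independent dropout draws (precursor always kept), with log-normal
intensities (base 1000 counts, σ = 0.5 in log space) and optional
uniform noise peaks over [50, precursor + 5] m/z whose intensities sit
below the 10th percentile of true peaks — noise stresses the tolerance
windows without inverting presence/absence evidence.  Recorded
precursors carry Gaussian mass error (σ = 5 ppm, truncated at the
10 ppm precursor tolerance).  Edges connect compounds sharing ≥ 2
predicted fragment m/z at two decimals, which clusters CDPs by
amino-acid composition exactly as shared immonium ions do in real
networks; an explicit cluster assignment can replace the rule.
Generation is bit-reproducible for a fixed spec and seed.

What the generator does **not** emulate: chimeric spectra, isotope
envelopes, co-elution, intensity-dependent peak picking, retention-time
drift, or realistic modified-cosine edge scores.  Passing tests on
these fixtures therefore demonstrate the correctness of the annotation
logic under its stated assumptions, not recall on raw instrument data.

The packaged reference set lists the 53 CDPs detected in
*Limosilactobacillus reuteri* culture with their reported m/z and RTs.
Formulas are always derived from residue composition; three rows whose
printed formulas disagree with the derivation are flagged
`formula_discrepant`, and two rows whose printed m/z is > 20 ppm from
the derived [M+H]+ (cyclo(Pro-Pro), cyclo(Asp-Tyr)) are flagged
`mz_discrepant` and treated as transcription errors.

## Problem sizes and test design

Tests run the pipeline on panels of up to 30 distinct reference CDPs
(noise-free recovery must be 100 % at tier confident) and on 10–12
compound panels across a dropout × seed grid (recovery must be
non-increasing in dropout).  Propagation is cross-checked against an
exhaustive assignment search on networks of ≤ 5 nodes, where
enumeration over all candidate assignments is tractable.  These sizes
exercise every code path — larger panels only repeat residue
combinations already covered.

## Known limitations

* Only [M+H]+ is modelled; multiply charged species, other adducts and
  isotope patterns are out of scope.
* Stereochemistry within a diastereomer pair is not assigned — RT
  separation shows *that* two epimers exist, not which is which.
* Dataset-scale totals (node counts, library-match counts) depend on
  the instrument run and are not reproducible from desk-scale inputs;
  the pipeline reports its own provenance partition instead.
* The evidence weights and tier cut-offs formalize a qualitative
  practice; they are sensible defaults, not fitted parameters.
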