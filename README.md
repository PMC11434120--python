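# cdpmine

Deep mining of cyclic dipeptides (CDPs) and small peptides from
LC–MS/MS feature-based molecular networks.

## The problem

Fermentation extracts of lactic-acid bacteria such as
*Limosilactobacillus reuteri* are rich in 2,5-diketopiperazines (DKPs)
— cyclic dipeptides with documented anti-inflammatory and antimicrobial
activity.  Spectral-library matching annotates only the few DKPs a
database happens to contain, and de novo sequencing engines misread
them: a DKP is isobaric with its "dehydrated" linear dipeptide, so the
cyclic form is reported as a linear peptide with a −18.01 Da tag.

`cdpmine` implements the deep-mining strategy an analyst applies by
hand to a feature-based molecular network (FBMN):

1. **Exact mass.** A DKP's formula is the sum of its two residue
   compositions (cyclization removes the water a residue already
   excludes), so every residue pair with [M+H]⁺ within tolerance of a
   node's precursor is a candidate:
   `m/z = m(res_a) + m(res_b) + 1.007276`.
2. **Diagnostic ions.** Candidates are kept only with fragment support:
   immonium ions (residue − CO + H, singly charged; Pro 70.07, Hyp
   86.06, MeEGlu 116.07, PyroGlu 84.04, Tyr 136.08), small neutral
   losses (H₂O, CO, CH₃OH for methyl esters), and residue companion
   ions (the proline ring ion 98.06, the tyrosine quinomethide loss).
3. **Network propagation.** Within a cluster, an edge whose precursor
   mass difference matches a single residue-exchange delta (28.031 Da =
   C₂H₄ for Val↔Ala, 42.047 Da = C₃H₆ for Leu↔Ala, 15.995 Da = O for
   Pro↔Hyp, 18.011 Da = H₂O for Glu↔PyroGlu, …) proposes the exchanged
   CDP for the unannotated neighbour, accepted only with fragment
   evidence.  Runs to a fixpoint; seeds are never overwritten.
4. **De novo reconciliation.** Dehydration-tagged dipeptides in
   CDP-containing clusters are rescored as the cyclic form (and, for
   Glu-containing hits, against the competing linear PyroGlu reading).
5. **Isomer classification.** Same formula + same residue composition
   at two retention times ⇒ diastereomer pair; same formula, different
   composition ⇒ positional isomers; Leu/Ile is reported as "Leu/Ile"
   unless the opt-in elution-order heuristic is enabled.

The library covers the 20 canonical residues plus the three
non-canonical residues recurrent in *L. reuteri* DKPs — Hyp (Pro + O),
MeEGlu (Glu + CH₂) and PyroGlu (Glu − H₂O) — and is extensible via a
YAML config.

## Worked example

`examples/predict_fragments.py` predicts the diagnostic ions of
cyclo(MeEGlu-Hyp):

```
cyclo(Hyp-MeEGlu)  formula C11H16N2O5  [M+H]+ calcd 257.1132

  [M+H]+               m/z   257.11   (precursor, from cyclo(Hyp-MeEGlu))
  [M+H-H2O]+           m/z   239.10   (neutral_loss, from ring)
  [M+H-CO]+            m/z   229.12   (neutral_loss, from ring)
  [M+H-CO-H2O]+        m/z   211.11   (neutral_loss, from ring)
  [M+H-CH3OH]+         m/z   225.09   (neutral_loss, from MeEGlu)
  [M+H-CH3OH-CO]+      m/z   197.09   (neutral_loss, from MeEGlu)
  imm(Hyp)             m/z    86.06   (immonium, from Hyp)
  imm(MeEGlu)          m/z   116.07   (immonium, from MeEGlu)
```

The methanol losses identify the methyl ester of MeEGlu; the two
immonium ions pin both residues, which is what elevates an annotation
to the *confident* tier.

`examples/annotate_network.py` generates a five-compound synthetic
network and annotates it from a single cyclo(Val-Pro) seed:

```
              name    formula  theoretical_mz  observed_mz    rt      level ...
    cyclo(Gly-Pro)  C7H10N2O2        155.0815     155.0813  3.62 propagated
    cyclo(Ala-Pro)  C8H12N2O2        169.0972     169.0968  5.05 propagated
    cyclo(Pro-Val) C10H16N2O2        197.1285     197.1279 12.71   database
    cyclo(Ser-Asn)  C7H11N3O4        202.0822     202.0822  1.10    revised
cyclo(Leu/Ile-Pro) C11H18N2O2        211.1441     211.1440 18.79 propagated
```

The `level` column is the provenance: the database seed, three CDPs
reached by residue-exchange propagation (the 14.02 Da Val→Leu/Ile step
is mass-ambiguous, hence "Leu/Ile"), and one de novo "dehydrated
Asn-Ser" revised to its cyclic form.

`examples/classify_reference_set.py` classifies the packaged reference
set of 53 CDPs detected in *L. reuteri* culture and prints its 16
diastereomer pairs and 15 unnatural-residue CDPs.

## Command line

```sh
cdpmine simulate --spec fixture.yaml --seed 3 --out data/
cdpmine annotate --mgf data/spectra.mgf --nodes data/nodes.tsv \
                 --edges data/edges.tsv --denovo data/denovo.tsv --out out/
cdpmine report --annotations out/annotations.tsv
```

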