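"""Classify the packaged 53-CDP reference set.

Groups the curated *L. reuteri* CDP annotations by elemental formula:
members with the same residue composition at two retention times are
diastereomer pairs (stereochemistry resolved only by C18 elution);
same-formula/different-composition members are positional isomers.
Also counts CDPs containing an unnatural residue (Hyp, MeEGlu, PyroGlu).
"""

from cdpmine import classify_isomers, classify_unnatural, reference_cdp_annotations

annotations = reference_cdp_annotations()
groups = classify_isomers(annotations)
counts = classify_unnatural(annotations)

pairs = [g for g in groups if g.relation == "diastereomer_pair"]
print(f"CDP annotations:           {counts['total']}")
print(f"unnatural-residue CDPs:    {counts['unnatural']}")
print(f"diastereomer pairs:        {len(pairs)}")
print()
for g in pairs:
    rts = ", ".join(f"{a.rt:.2f}" for a in g.members)
    print(f"  {g.members[0].name:<22} {g.formula.hill():<12} RT {rts} min")
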