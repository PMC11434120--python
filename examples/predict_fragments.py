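"""Predict the diagnostic MS/MS ions of a cyclic dipeptide.

Builds cyclo(MeEGlu-Hyp) — glutamate 5-methyl ester paired with
4-hydroxyproline — and prints its theoretical [M+H]+ and fragment list.
The immonium ions (86.06 for Hyp, 116.07 for MeEGlu) identify the
residues; the methanol losses betray the methyl ester.
"""

from cdpmine import cdp_fragments, make_cdp, round_half_up

cdp = make_cdp("MeEGlu", "Hyp")
print(f"{cdp.name}  formula {cdp.formula.hill()}  "
      f"[M+H]+ calcd {cdp.precursor_mz:.4f}")
print()
for frag in cdp_fragments(cdp):
    print(f"  {frag.label:<20} m/z {round_half_up(frag.mz, 2):>8.2f}   "
          f"({frag.kind}, from {frag.provenance})")
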