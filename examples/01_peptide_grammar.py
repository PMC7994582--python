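"""Parse CTD phosphopeptides in repeat notation and inspect their geometry.

The spacing between the outermost pSer-Pro motifs is the lever that decides
whether one two-domain isomerase molecule can engage both motifs at once.
"""

from ctdbind import (CTD_PEPTIDES, extinction_coefficient, locate_psp_motifs,
                     motif_spacing, parse_peptide_spec)

for name in ["NMR-1R", "NMR-2R", "NMR-3R", "NMR-4R", "NMR-5R"]:
    p = CTD_PEPTIDES[name]
    spacing = motif_spacing(p)
    print(f"{name}: {len(p)} residues, {p.n_repeats} repeats, "
          f"motifs at {locate_psp_motifs(p)}, "
          f"spacing {'-' if spacing is None else spacing}, "
          f"eps280 {extinction_coefficient(p):.0f} /M/cm")

# the same grammar accepts ad-hoc designs
custom = parse_peptide_spec("AS(YSPTpSPS)(YSPTSPS)(YSPTpSPS)YS", name="custom-3R")
print(f"\n{custom.name}: motif spacing {motif_spacing(custom)} residues")
print("A spacing of ~28 residues (5R) spans the distance between the WW and")
print("PPIase binding sites; 1R peptides carry a single motif and cannot bridge.")
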