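"""Cut stress-induced peptide sequences into a k-mer fragment library.

Each peptide is sliced by a sliding window into every 4-10-mer, and each
fragment gets a Kyte-Doolittle GRAVY score (positive = hydrophobic) plus
charged/aromatic residue counts.
"""

from pepterface import SIPRecord, generate_library, gravy, library_summary

sips = [
    SIPRecord("BIP142_3", "LAEDTFGEIS"),
    SIPRecord("OSIP77_1", "MKRLSSDDEE"),
    SIPRecord("OSIP12_2", "AVILLFW"),
]

library = generate_library(sips, kmin=4, kmax=10)
print(f"{len(library)} fragments from {len(sips)} peptides")

full = gravy("LAEDTFGEIS")
print(f"GRAVY(LAEDTFGEIS) = {full.gravy:+.2f} -> {full.klass}")

summary = library_summary(library)
print(f"hydrophilic fragments: {100 * summary['frac_hydrophilic']:.1f}%")
print(f"charged residues:      {100 * summary['frac_charged_residues']:.1f}%")
# A mostly-hydrophilic library suggests the peptides target globular
# protein surfaces rather than membrane-spanning hydrophobic patches.
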