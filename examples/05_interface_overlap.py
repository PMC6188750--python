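"""Does a predicted peptide pocket sit on a dimer interface or known site?

Interface residues are chain pairs whose C-alpha atoms lie strictly below
6.0 A; any shared residue between the predicted pocket and the interface
(or an annotated ligand site) flags a potentially regulatory binding mode.
"""

from pepterface import interface_residues, pocket_at_interface, pocket_at_site
from pepterface.interface_overlap import SiteAnnotation
from pepterface.synthetic_data import ComplexSpec, PlantedInteraction, make_complex

model, _ = make_complex(ComplexSpec(planted=(
    PlantedInteraction("interface_ca", 5.5),
)))
iface = interface_residues(model, "A", "B")
print(f"interface residues (A-B): {sorted(iface.residues)}")

pocket = {("A", 1), ("A", 42)}
flag, shared = pocket_at_interface(pocket, iface)
print(f"pocket on dimer interface: {flag} (shared {sorted(shared)})")

atp_site = SiteAnnotation("2VTB_D", "ligand", "ATP",
                          frozenset({("D", 436), ("D", 485)}))
flag, shared, kind = pocket_at_site({("D", 436), ("D", 440)}, atp_site)
print(f"pocket on {atp_site.ligand_code} {kind} site: {flag} "
      f"(shared {sorted(shared)})")
# A peptide whose pocket overlaps an ATP site may compete with the
# cofactor; one overlapping a subunit interface may block complex assembly.
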