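"""Residue-level interaction profiles from classified contacts.

Toy complexes are generated with prescribed contact geometries, classified
by the distance-based rules, and aggregated into per-residue profiles and
halogen-bond shares.
"""

from oxascreen import interaction_profiler as ip, synthetic_data as sd

# ten compounds: all hydrogen-bond to 201; a halogenated subset also
# reaches 236 and 233 -- the classic halogen-bond acceptors of this pocket
prescriptions = []
for k in range(10):
    p = [(201, "hbond"), (278, "hydrophobic")]
    if k < 6:
        p.append((236, "halogen_bond"))
    if k < 2:
        p.append((233, "halogen_bond"))
    prescriptions.append(p)

contacts_per_compound = [
    ip.detect_contacts(*sd.generate_complex(p, seed=k))
    for k, p in enumerate(prescriptions)
]
profiles = ip.residue_profiles(contacts_per_compound, [201, 233, 236, 278])
print("residue  fraction  composition")
for prof in profiles:
    comp = ", ".join(f"{k}={v:.2f}" for k, v in prof.composition.items())
    print(f"  {prof.residue_number:>4}  {prof.fraction_of_compounds:8.2f}  {comp}")

shares = ip.halogen_contributions(contacts_per_compound)
print("\nhalogen-bond shares:",
      ", ".join(f"{res}: {share:.2f}" for res, share in shares.items()))

# 'fraction' is the share of compounds touching the residue; compositions
# sum to 1 over that residue's contacts; halogen shares sum to 1 overall.
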