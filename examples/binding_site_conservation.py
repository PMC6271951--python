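"""Conservation profile of the biotin carboxylase ATP binding site.

Loads the bundled 21-residue binding-site table (E. coli numbering, seven
bacterial isoforms), summarizes the per-position Shannon entropies and
classifies each position's conservation pattern.
"""

from oxascreen import conservation_profiler as cp

table = cp.load_binding_site_table()
mean, sd = cp.entropy_summary([p.entropy_bits for p in table])
background = cp.background_max_entropy(cp.load_background_composition())
print(f"binding-site positions: {len(table)}")
print(f"mean +/- sd sequence entropy: {mean:.2f} +/- {sd:.2f} bits")
print(f"background (protein-like) maximum entropy: {background:.2f} bits\n")

for pos in table:
    cls = cp.classify_position_conservation(pos)
    residues = "".join(pos.residues[c] for c in cp.ISOFORM_CODES)
    print(f"  {pos.residue_number:>4}  {pos.entropy_bits:5.2f} bits  "
          f"{residues}  {cls}")

subs = cp.mutated_binding_site("Sp")
print(f"\nE. coli -> S. pneumoniae requires {len(subs)} substitutions:")
print("  " + ", ".join(f"{a}{n}{b}" for n, a, b in subs))

# Entropies far below the ~4.19-bit background mark a conserved pocket;
# gram_specific positions (169, 204, 287, 437) separate the two groups and
# drive the broad-spectrum design problem.
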