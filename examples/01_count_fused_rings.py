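"""Count three-membered rings fused to a breaking bond (the n3 descriptor).

Each three-membered ring containing the breaking bond signals sigma
delocalization that lowers the intrinsic activation barrier by ~10 kcal/mol.
"""

from strainlfer import BreakingBond, build_graph, count_fused_three_rings

cases = [
    # name, structure (SMILES or (atoms, bonds)), breaking bond (atom indices)
    ("ethane", "CC", (0, 1)),
    ("cyclopropane", "C1CC1", (0, 1)),
    ("cyclobutane", "C1CCC1", (0, 1)),
    ("ethylene oxide", "C1OC1", (0, 1)),
    ("oxetane", "C1COC1", (1, 2)),
    ("bicyclo[1.1.0]butane (central bond)", "C1C2CC12", (1, 3)),
    (
        "[1.1.1]propellane (interbridgehead bond)",
        (["C"] * 5, [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3), (0, 4), (1, 4)]),
        (0, 1),
    ),
]

print(f"{'substrate':45s} n3   intrinsic-barrier effect")
for name, structure, (i, j) in cases:
    graph = build_graph(structure)
    n3 = count_fused_three_rings(graph, BreakingBond(i, j))
    print(f"{name:45s} {n3}    ~{-10 * n3:+d} kcal/mol")

# n3 = 0 (ethane, cyclobutane, oxetane) means no sigma-delocalization boost;
# propellane's n3 = 3 explains its "spring-loaded" reactivity: ~30 kcal/mol
# of intrinsic-barrier lowering on top of its strain-release driving force.
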