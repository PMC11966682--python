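"""Enumerate cubane valence isomers and classify spin-population records.

The three records below are synthetic stand-ins shaped like broken-symmetry
QM/MM output for three protein conformations: two positive site populations
(the delocalized mixed-valence Fe2.5+ pair) and two negative ones (the
antiferromagnetically coupled ferrous pair).
"""

from fesepr import (
    SpinPopulationRecord,
    classify_from_spin_populations,
    compare_assignments,
    enumerate_valence_isomers,
)

isomers = enumerate_valence_isomers()
print(f"{len(isomers)} valence isomers of a 4-site [4Fe4S]1+ cubane:")
for iso in isomers:
    print(f"  mixed-valence {iso.mixed_valence_pair}  |  ferrous {iso.ferrous_pair}")

records = {
    "conformer-A": SpinPopulationRecord((+3.05, +3.10, -2.90, -2.95), source="A"),
    "conformer-B": SpinPopulationRecord((-2.85, -2.80, +3.00, +3.05), source="B"),
    "conformer-C": SpinPopulationRecord((+3.00, -2.88, +3.08, -2.92), source="C"),
}
assignments = {}
print("\nclassification from spin populations (synthetic records):")
for name, rec in records.items():
    va = classify_from_spin_populations(rec)
    assignments[name] = va
    print(f"  {name}: mixed-valence {va.mixed_valence_pair}, "
          f"ferrous {va.ferrous_pair}, margin {va.margin:.2f}")

a, b, c = assignments.values()
print("\npairwise relations between conformers:")
print("  A vs B:", compare_assignments(a, b), "(roles swapped on the same partition)")
print("  B vs C:", compare_assignments(b, c), "(a different pair partition)")
print("The margin is the population gap between the two groups; a large")
print("margin means the partition is unambiguous for that record.")
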