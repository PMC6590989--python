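"""Measure the membrane-localized share of a reporter in a confocal image.

Simulates a cell whose reporter places 60% of its signal on the plasma
membrane, segments the membrane ring from the dye channel, and quantifies the
background-excluded reporter fraction inside the ring.  A clustered variant
of the same cell shows the higher perimeter CV that patchy expression causes.
"""

from raftcrac import CellImageSpec, ConfocalImage, gen_confocal_cell, membrane_fraction

for kappa, label in ((0.0, "uniform membrane expression"),
                     (5.0, "clustered membrane expression")):
    cell = gen_confocal_cell(CellImageSpec(f_membrane=0.6,
                                           clustering_concentration=kappa,
                                           seed=3))
    q = membrane_fraction(ConfocalImage(cell.membrane_channel,
                                        cell.reporter_channel,
                                        cell.nuclear_channel))
    print(f"{label}:")
    print(f"  planted f_membrane 0.60 → measured {q.membrane_fraction:.3f}")
    print(f"  perimeter CV (clustering index): {q.membrane_cv:.3f}")

print("\nThe membrane fraction is ring reporter intensity over whole-cell")
print("intensity, both with sub-background pixels excluded; the CV rises when")
print("the same signal concentrates in patches instead of coating the ring.")
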