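"""Scan transmembrane segments of a TRP channel for CRAC cholesterol motifs.

Builds the two published TM fragments of mouse TRPA1, scans them with the
extended CRAC pattern (L/V)-X1-5-(Y/F/W)-X1-5-(K/R), and prints every anchor
triple.  Overlapping triples are distinct motifs: the 780-790 stretch alone
hosts three.
"""

from raftcrac import CRAC_EXTENDED, ProteinRecord, report_matches, scan_sequence

tm2 = ProteinRecord("TM2-fragment", "mouse", "VFLSSIFGYCK", offset=780)
tm4 = ProteinRecord("TM4-fragment", "mouse", "LLYLQR", offset=850)

for rec in (tm2, tm4):
    matches = scan_sequence(rec, CRAC_EXTENDED)
    print(f"{rec.id} ({rec.first_residue}-{rec.last_residue}): "
          f"{len(matches)} motif(s)")
    print(report_matches(matches).to_string(index=False))
    print()

print("Each row is one (apolar, aromatic, basic) anchor triple; positions are")
print("native residue numbers, so e.g. 780/786/790 reads V780-F786-K790.")
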