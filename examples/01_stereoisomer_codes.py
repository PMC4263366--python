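"""Walk through the 5-digit chirality code for the 32 aldohexopyranoses.

Each stereocenter C1..C5 carries one digit, 2 or 4, fixing the sign of its
improper-dihedral minimum (+35.264 or -35.264 degrees).  The digit string
determines the sugar name: C1 sets the anomer, C2-C4 the base sugar, C5 the
d/l series.  Swapping every digit yields the enantiomer.
"""

from sugarosp import all_identities, code_to_identity, enantiomer_of

print("All 32 stereoisomers:")
print(f"{'index':>5}  {'code':>5}  name")
for ident in all_identities():
    print(f"{ident.index:>5}  {ident.code:>5}  {ident.name}")

print()
glucose = code_to_identity("22222")
mirror = enantiomer_of(glucose)
print(f"{glucose.name} ({glucose.code}, index {glucose.index})")
print(f"  enantiomer: {mirror.name} ({mirror.code}, index {mirror.index})")
print(f"  index identity: 33 - {glucose.index} = {33 - glucose.index}")
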