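"""Affinity arithmetic on the packaged radioligand-displacement table.

Loads the 21-compound IC50 table, derives pIC50, and prints the fold-change
comparisons that frame the structure-activity discussion.
"""

from fentsar.io import affinity_frame, load_reference_affinities
from fentsar.sar import fold_ratio

records = load_reference_affinities()
aff = affinity_frame(records).set_index("compound_id")

print("compound  IC50(nM)   pIC50")
for cid in ("F01", "F02", "F03", "F15", "F07"):
    row = aff.loc[cid]
    pic = "   -  " if row["censored"] else f"{row['pic50']:6.2f}"
    print(f"{cid:8s} {row['ic50_nM']:9.2f}  {pic}")

print()
print("fold changes (IC50 ratios; >1 means the first compound binds worse):")
for a, b, note in (
    ("F03", "F01", "removing one CH2 from the N-chain"),
    ("F02", "F01", "opening the piperidine ring"),
    ("F01", "F12", "para-F on the anilide ring helps"),
    ("F06", "F14", "3-Me added to the beta-OH scaffold"),
):
    print(f"  {a}/{b} = {fold_ratio(aff.loc[a, 'ic50_nM'], aff.loc[b, 'ic50_nM']):7.2f}   ({note})")

measured = aff[~aff["censored"]]
print()
print(
    f"measured IC50 span: {measured['ic50_nM'].min()} nM "
    f"({measured['pic50'].idxmax()}) to {measured['ic50_nM'].max()} nM "
    f"({measured['pic50'].idxmin()})"
)
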