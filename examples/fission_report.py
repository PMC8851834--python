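"""Forensics of a broken mitochondrial gene (the ccmFc pattern).

Generates a target genome carrying the "leafy" layout — the reference
two-exon gene broken into three fragments, with a plastid-bearing
insertion between FR2 and FR3 — plus the "sweet potato" layout with
planted coding expansions, and prints what the analyzer infers.
"""

from orgamosaic import analyze_fission, simulate_fission_fixture

target, ref, model, plastome, _truth = simulate_fission_fixture("leafy", seed=1)
report = analyze_fission(target, ref, model, plastomes=[plastome])

print("leafy layout")
for fr in report.fragments:
    print(
        f"  {fr.label}: target {fr.genomic.start}-{fr.genomic.end}, "
        f"reference nt {fr.ref_span[0]}-{fr.ref_span[1]}, {fr.identity:.1f}% id"
    )
print(f"  coding loss at break 1: {report.break1_lost_aa} aa")
print(f"  intron loss at break 2: {report.break2_lost_nt} nt")
gap = report.fr2_fr3_gap
print(
    f"  FR2-FR3: {gap.status}, insertion {gap.insertion_len} bp "
    f"({gap.plastid_bp} bp of plastid origin)"
)
print(f"  intron binding window: {report.binding_region_status.status}")

target, ref, model, _, _ = simulate_fission_fixture("sweet_potato", seed=1)
report = analyze_fission(target, ref, model)
exp = report.expansion
print("sweet-potato layout")
print(f"  ccmFc1 reads on {exp.ccmFc1_aa} codons to its new stop")
print(f"  ccmFc2 starts {exp.ccmFc2_aa} codons upstream at the nearest in-frame ATG")

# 43 aa is the coding segment deleted at the first break; 3500/2800 bp the
# intronic insertion and its plastid-derived content; 185/118 aa the coding
# expansions forced by losing the ancestral stop/start codons.
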