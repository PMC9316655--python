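"""Annotate a query spectrum against a small compound table.

Retrieves candidates within 20 ppm of the precursor (over the default
adduct set), scores each against a predicted fingerprint — here the
glucose fingerprint stands in for a model prediction — and prints the
Tanimoto-ranked list.
"""

from specfid import (
    CompoundRecord,
    compute_fingerprint,
    rank_candidates,
    retrieve_candidates,
    topk_hit,
)

db = [
    CompoundRecord("glucose", "WQZGKKKJIJFFOK-GASJEMHNSA-N", "OCC1OC(O)C(O)C(O)C1O", "C6H12O6", 180.0634),
    CompoundRecord("fructose", "RFSUNEUAIZKAJO-ARQDHWQXSA-N", "OCC1(O)OCC(O)C(O)C1O", "C6H12O6", 180.0634),
    CompoundRecord("caffeine", "RYYVLZVUVIJVGH-UHFFFAOYSA-N", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "C8H10N4O2", 194.0804),
]

precursor_mz = 181.0707  # [M+H]+ of a 180.0634 Da compound
candidates = retrieve_candidates(precursor_mz, "positive", db)
print(f"{len(candidates)} candidate(s) within 20 ppm of m/z {precursor_mz}:")
for match in candidates:
    print(f"  {match.compound.id:9s} via {match.adducts} ({match.ppm_error:.1f} ppm)")

predicted = compute_fingerprint("OCC1OC(O)C(O)C(O)C1O")  # stands in for a model output
ranked = rank_candidates(predicted, candidates, query_id="demo")
print("Tanimoto ranking:")
for rank, (match, score) in enumerate(ranked.entries, start=1):
    print(f"  {rank}. {match.compound.id:9s} score {score:.3f}")
print("top-1 hit for glucose:", topk_hit(ranked, "WQZGKKKJIJFFOK-GASJEMHNSA-N", 1))
# Caffeine's mass is ~13 Da away, so it never enters the candidate list;
# the two isobaric hexoses are separated by fingerprint similarity alone.
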