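"""MinHashed atom-pair fingerprints and similarity.

Shows the shingle representation (pairs of circular substructures with
their bond distance), the MinHash fingerprint, and how well the MinHash
match fraction estimates the exact Jaccard similarity of the shingle sets.
"""

from nporigin import enumerate_shingles, map4_fingerprint, map4_similarity

caffeine = "Cn1cnc2c1c(=O)n(C)c(=O)n2C"
theobromine = "Cn1cnc2c1c(=O)[nH]c(=O)n2C"
aspirin = "CC(=O)Oc1ccccc1C(=O)O"

shingles = {s: enumerate_shingles(s) for s in (caffeine, theobromine, aspirin)}
print("caffeine shingle set size:", len(shingles[caffeine]))
print("example shingles:", sorted(shingles[caffeine])[:3], "\n")

fps = {s: map4_fingerprint(s) for s in shingles}
for name_a, name_b, a, b in [
    ("caffeine", "theobromine", caffeine, theobromine),
    ("caffeine", "aspirin", caffeine, aspirin),
]:
    exact = len(shingles[a] & shingles[b]) / len(shingles[a] | shingles[b])
    est = map4_similarity(fps[a], fps[b])
    print(f"{name_a} vs {name_b}:")
    print(f"  exact Jaccard of shingle sets : {exact:.3f}")
    print(f"  MinHash match fraction (d=1024): {est:.3f}")

print(
    "\nThe match fraction is an unbiased estimate of the Jaccard similarity;"
    "\nclose analogs score high, unrelated scaffolds score near zero."
)
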