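"""Build the 16-bit weight-6 barcode codebook and decode noisy words.

The codebook guarantees a minimum pairwise Hamming distance of 4, which
lets the decoder correct any single flipped bit and refuse ambiguous
words instead of guessing.
"""

from eelkit.codebook import assign_genes, decode_word, generate_codebook, validate_codebook

# the full deterministic construction, then the 448 codes used per channel
book = generate_codebook(n_bits=16, weight=6, min_distance=4, size=448)
report = validate_codebook(book)
print(f"codebook: {report['n_entries']} codewords, "
      f"min pairwise distance {report['min_pairwise_distance']}, "
      f"weights {report['weight_histogram']}")

genes = [f"Gene{i:03d}" for i in range(440)]
assignments, book = assign_genes(book, genes)
print(f"assigned {len(genes)} genes; {len(book.blank_labels)} blank codes "
      "remain as negative controls")

word = list(book["Gene007"].bits)
print("clean word     ->", decode_word(word, book))
word[3] ^= 1
print("1 bit flipped  ->", decode_word(word, book))  # corrected
word[9] ^= 1
print("2 bits flipped ->", decode_word(word, book))  # no-call, never a guess

# A no-call on double errors is what keeps the blank-based false-positive
# rate meaningful: miscalls would leak into gene counts silently.
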