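"""The two automated scoring algorithms on small worked examples.

Sentence scoring ignores word order; word-list scoring aligns lists of
unequal length by greedy single-word deletion before a position-by-position
comparison, with homophones ("whine"/"wine") credited via a
grapheme-to-phoneme lexicon.
"""

from vocsim import (
    align_and_score_words,
    brute_force_alignment_score,
    clean_text,
    homophone_matcher,
    score_sentences,
)

# Order-insensitive sentence scoring: the classic three-word example.
res = score_sentences([clean_text("Skipped Abbey rocks")],
                      [clean_text("Abbey skipped rocks")])
print(f"sentence scoring, scrambled order: {res.n_correct}/{res.n_total} correct")

# Word-list alignment: the recognizer heard an extra word ("big").
res = align_and_score_words(clean_text("the big cat sat"), clean_text("the cat sat"))
print(f"word alignment with insertion:     {res.n_correct}/{res.n_total} correct")

# The brute-force oracle enumerates every deletion set and agrees here.
res = brute_force_alignment_score(clean_text("the big cat sat"),
                                  clean_text("the cat sat"))
print(f"exhaustive oracle:                 {res.n_correct}/{res.n_total} correct")

# Homophones score as correct when matched phonetically.
res = align_and_score_words(clean_text("red wine"), clean_text("red whine"),
                            matcher=homophone_matcher())
print(f"homophone-aware matching:          {res.n_correct}/{res.n_total} correct")
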