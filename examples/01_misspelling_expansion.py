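"""Build the cannabis lexicon and expand corpus misspellings.

Walks through the character n-gram method on the canonical worked example
(marijuana vs. marijuahana), then expands a small corpus vocabulary and
shows which candidates attach to which dictionary terms and why.
"""

from cannascreen.lexicon import (
    build_lexicon,
    char_ngram_profile,
    expand_misspellings,
    expansion_report,
    ngram_cosine,
)


def main() -> None:
    lexicon = build_lexicon()
    print("dictionary terms:", ", ".join(sorted(lexicon.all_terms())))
    print()

    # -- the worked example ------------------------------------------------
    a = char_ngram_profile("marijuana", 1, 3)
    b = char_ngram_profile("marijuahana", 1, 3)
    print("profile('marijuana'):   A x%d, JU x%d (no AH)" % (a.counts["a"], a.counts["ju"]))
    print("profile('marijuahana'): A x%d, H x%d, AH x%d, AHA x%d"
          % (b.counts["a"], b.counts["h"], b.counts["ah"], b.counts["aha"]))
    sim = ngram_cosine(a, b)
    print(f"cosine similarity = {sim:.4f} -> rounds to {round(sim, 2)}")
    print(f"threshold for 'marijuana' is {lexicon.thresholds['marijuana']:.2f}: "
          f"{'ACCEPT' if sim >= lexicon.thresholds['marijuana'] else 'REJECT'}")
    print()

    # -- expanding a corpus vocabulary --------------------------------------
    vocabulary = [
        "marijuahana", "marijuanna", "cannabiss", "canabis", "epidiollex",
        "fracture", "needed", "ragweed", "seaweed", "patient",
    ]
    print("candidate vocabulary:", ", ".join(vocabulary))
    lexicon.misspellings = expand_misspellings(vocabulary, lexicon)
    for row in expansion_report(vocabulary, lexicon):
        print(f"  {row['variant']:<12} -> {row['term']:<10} "
              f"cos={row['similarity']:.3f} (threshold {row['threshold']:.2f})")
    rejected = sorted(
        set(vocabulary)
        - {v for vs in lexicon.misspellings.values() for v in vs}
        - set(lexicon.all_terms())
    )
    print("rejected (below every threshold):", ", ".join(rejected))


if __name__ == "__main__":
    main()
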