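# config {"generator": {"abstract_words": 100, "author_pool": 0, "authors_per_article": 4, "n_articles": 30, "n_journals": 20, "n_topics": 4, "paragraphs_per_section": 3, "plants": [{"author_overlap": "shared", "copy_fraction": 0.9, "n_pairs": 2, "same_journal": false, "same_year": false, "target": "methods_section"}, {"author_overlap": "disjoint", "copy_fraction": 0.9, "n_pairs": 1, "same_journal": false, "same_year": false, "target": "intro_section"}, {"author_overlap": "shared", "copy_fraction": 1.0, "n_pairs": 1, "same_journal": false, "same_year": false, "target": "fulltext"}], "review_fraction": 0.075, "seed": 42, "vocab_size": 1500, "words_per_paragraph": 60, "year_range": [2000, 2009], "zipf_exponent": 0.5}, "granularity": "SECTION", "min_words": null, "pairing": "either_direction", "section_filter": null, "seed": 42, "threshold": 0.5}
unit_a	unit_b	article_a	article_b	ratio_forward	ratio_reverse	pair_ratio	shared_author	granularity	section_class_a	section_class_b
A00000:sec0	A00014:sec0	A00000	A00014	1.000000	1.000000	1.000000	1	SECTION	INTRODUCTION	INTRODUCTION
A00000:sec1	A00014:sec1	A00000	A00014	1.000000	1.000000	1.000000	1	SECTION	METHODS	METHODS
A00000:sec2	A00014:sec2	A00000	A00014	1.000000	1.000000	1.000000	1	SECTION	RESULTS_DISCUSSION	RESULTS_DISCUSSION
A00003:sec1	A00026:sec1	A00003	A00026	0.876682	0.886274	0.886274	1	SECTION	METHODS	METHODS
A00004:sec1	A00022:sec1	A00004	A00022	0.881833	0.894901	0.894901	1	SECTION	METHODS	METHODS
A00012:sec0	A00020:sec0	A00012	A00020	0.895530	0.897029	0.897029	0	SECTION	INTRODUCTION	INTRODUCTION
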