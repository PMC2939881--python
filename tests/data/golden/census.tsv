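# config {"generator": {"abstract_words": 100, "author_pool": 0, "authors_per_article": 4, "n_articles": 30, "n_journals": 20, "n_topics": 4, "paragraphs_per_section": 3, "plants": [{"author_overlap": "shared", "copy_fraction": 0.9, "n_pairs": 2, "same_journal": false, "same_year": false, "target": "methods_section"}, {"author_overlap": "disjoint", "copy_fraction": 0.9, "n_pairs": 1, "same_journal": false, "same_year": false, "target": "intro_section"}, {"author_overlap": "shared", "copy_fraction": 1.0, "n_pairs": 1, "same_journal": false, "same_year": false, "target": "fulltext"}], "review_fraction": 0.075, "seed": 42, "vocab_size": 1500, "words_per_paragraph": 60, "year_range": [2000, 2009], "zipf_exponent": 0.5}, "granularity": "SECTION", "min_words": null, "pairing": "either_direction", "section_filter": null, "seed": 42, "threshold": 0.5}
stratum	N	pairs_total	pairs_SA	pairs_DA	pairs_unknown	frequency	odds_SA_DA
INTRODUCTION	30	2	1	1	0	0.066667	1.000000
METHODS	30	3	3	0	0	0.100000	
RESULTS_DISCUSSION	30	1	1	0	0	0.033333	
all	90	6	5	1	0	0.066667	5.000000
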