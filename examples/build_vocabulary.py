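"""Build the locus-pair vocabulary that serves as the topic model's lexicon.

A locus pair (LP) is an unordered pair of fixed-width genomic bins on the
same chromosome within a maximum separation; LPs play the role of "words"
and cells the role of "documents".
"""

import hictopics as ht

# hg19 autosomes at 500 kb with a 10 Mb cutoff -- the standard configuration
bins = ht.make_bins(ht.ChromSizes.hg19_autosomes(), resolution=500_000, extra_bin=True)
vocab = ht.build_lp_vocabulary(bins, max_distance=10_000_000)
print(f"hg19 chr1-22, 500 kb bins, <=10 Mb separation: {len(vocab):,} locus pairs")
# -> 111,340: the vocabulary size of the reference configuration

# distances are multiples of the bin width
d = vocab.distances()
print(f"separations span {d.min():,} .. {d.max():,} bp "
      f"({vocab.max_bin_distance} bins max)")

# a small toy genome used throughout the synthetic experiments
_, toy_bins, toy_vocab = ht.synthdata.make_toy_genome(
    n_chroms=2, chrom_length=20_000_000, resolution=500_000, max_distance=5_000_000
)
print(f"toy genome (2 x 20 Mb, <=5 Mb): {len(toy_vocab)} locus pairs")
# -> 690 = 2 * sum_{d=1..10} (40 - d); each column of the cell-LP matrix
#    corresponds to one of these pairs
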