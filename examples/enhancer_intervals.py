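"""Define candidate enhancers from histone-mark peaks.

Applies the three-rule filter to toy ChIP-seq peaks: keep H3K4me1 peaks
that (1) do not overlap any H3K4me3 peak, (2) lie at least 2 kbp from every
transcription start site, and (3) are not contained in a gene body. Read
coverage over the survivors can then be interpreted as eRNA transcription.
"""

from cellpile import GenomicRegion, define_enhancers
from cellpile.genome import FeatureInterval, GeneModel

peaks_me1 = [
    FeatureInterval(GenomicRegion("chr1", s, e), name=n)
    for n, s, e in [("p1", 1000, 1200), ("p2", 5000, 5200),
                    ("p3", 10000, 10200), ("p4", 20000, 20200),
                    ("p5", 40000, 40200)]
]
peaks_me3 = [FeatureInterval(GenomicRegion("chr1", 5100, 5300))]
gene = GeneModel("geneA", "geneA.1", "+",
                 exons=(GenomicRegion("chr1", 11699, 25000),))

enhancers = define_enhancers(peaks_me1, peaks_me3, [gene],
                             min_tss_distance=2000)
print("H3K4me1 peaks:", [p.name for p in peaks_me1])
print("surviving enhancers:", [p.name for p in enhancers])
# p2 overlaps the promoter mark, p3 is only 1.5 kbp from the TSS, and p4
# lies inside the gene body, so p1 and p5 remain as candidate enhancers.
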