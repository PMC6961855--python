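"""Small shared constructors for hand-built hits."""

from invstab.regions import GenomicInterval
from invstab.scanner import RevCompHit
from invstab.sequence import AlignmentScore


def mk_hit(start, end, m, gapped=False, k=15, distance=1000, chrom="chrT"):
    matched = (k - 1 if gapped else k) - max(0, m - (2 if gapped else 0))
    return RevCompHit(
        interval=GenomicInterval(chrom, start, end),
        score=AlignmentScore(m, matched, gapped, k),
        distance=distance,
        within_reactive=True,
    )
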