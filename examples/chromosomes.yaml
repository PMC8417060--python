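# Chromosome and centromere definitions (bp, half-open centromere interval).
#
# Chr19: centromere 5.3-6.7 Mbp (methylation/repeat-based placement reported
# for the P. trichocarpa reference).
# Chr01/Chr04: centromere coordinates are NOT published as numbers; the values
# below are illustrative placeholders inferred from methylation-peak position
# and must be replaced by the user for any real analysis.
Chr19:
  length_bp: 15900000
  centromere: [5300000, 6700000]
Chr01:
  length_bp: 50500000
  centromere: [24000000, 27000000]   # non-authoritative placeholder
Chr04:
  length_bp: 24300000
  centromere: [9500000, 11500000]    # non-authoritative placeholder
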