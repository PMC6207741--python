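# Default twintron-scan configuration.
#
# The 5'/3' patterns below are illustrative IUPAC transcriptions of the
# canonical group II/III boundary descriptions (a GUGYG-like 5' boundary and
# a pyrimidine-rich ...YAG 3' terminus); curated consensus patterns for a
# specific study system should be supplied by the user.  Thresholds: an
# internal group III intron must be at least min_internal nt (the lower end
# of the group III length range); external introns shorter than
# putative_below nt are flagged putative (Y*); the final terminal_exclusion
# nt of the external intron hold its own 3' motif and are never counted as
# internal.
motif5:
  iupac: GTGYG
  max_mismatches: 1
motif3:
  iupac: YRNYAG
  max_mismatches: 1
min_internal: 73
putative_below: 88
terminal_exclusion: 20
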