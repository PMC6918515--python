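# US DHHS poverty guidelines effective January 2016 (Federal Register
# 81 FR 4036): base = one-person household, increment = dollars per each
# additional household member.
region,year,base_dollars,increment_dollars
contiguous_and_DC,2016,11880,4160
alaska,2016,14840,5200
hawaii,2016,13670,4780
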