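# Default 15-column TATA-box position frequency matrix (probabilities).
# Columns 4-11 carry the TATAWAWR core (consensus base 0.85, off-consensus
# 0.05; W = A/T at 0.45 each; R = A/G at 0.45 each); flanking columns are
# uniform.  Rows are per-base probabilities across the 15 positions.
A  0.25 0.25 0.25 0.05 0.85 0.05 0.85 0.45 0.85 0.45 0.45 0.25 0.25 0.25 0.25
C  0.25 0.25 0.25 0.05 0.05 0.05 0.05 0.05 0.05 0.05 0.05 0.25 0.25 0.25 0.25
G  0.25 0.25 0.25 0.05 0.05 0.05 0.05 0.05 0.05 0.05 0.45 0.25 0.25 0.25 0.25
T  0.25 0.25 0.25 0.85 0.05 0.85 0.05 0.45 0.05 0.45 0.05 0.25 0.25 0.25 0.25
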