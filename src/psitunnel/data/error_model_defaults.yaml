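# Default execution-error model: per-group, per-ligament quartiles
# (median, Q1, Q3) of the angular deviation (degrees) and entry-point
# distance (mm) observed for freehand (control) and PSI-guided drilling.
# Each quartile triple identifies one log-normal magnitude distribution
# exactly (mu = ln median, sigma = ln(Q3/Q1)/1.349).
freehand:
  LCL:
    angular: {median: 17.4, q1: 12.7, q3: 23.8}
    entry: {median: 2.5, q1: 2.2, q3: 5.9}
  PT:
    angular: {median: 20.7, q1: 16.5, q3: 25.2}
    entry: {median: 4.9, q1: 2.5, q3: 5.4}
  MCL:
    angular: {median: 23.8, q1: 17.8, q3: 25.8}
    entry: {median: 6.6, q1: 3.5, q3: 9.0}
  POL:
    angular: {median: 24.7, q1: 21.6, q3: 27.8}
    entry: {median: 10.7, q1: 7.2, q3: 11.3}
psi:
  LCL:
    angular: {median: 5.7, q1: 3.3, q3: 6.6}
    entry: {median: 4.4, q1: 3.5, q3: 6.3}
  PT:
    angular: {median: 4.4, q1: 2.6, q3: 8.3}
    entry: {median: 5.6, q1: 4.1, q3: 6.8}
  MCL:
    angular: {median: 7.5, q1: 5.4, q3: 8.7}
    entry: {median: 3.8, q1: 3.5, q3: 5.0}
  POL:
    angular: {median: 4.8, q1: 3.2, q3: 10.3}
    entry: {median: 3.9, q1: 3.3, q3: 5.1}
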