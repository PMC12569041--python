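# Default intracellular conformational-state regions for KOR.
#
# Feature space: d = distance Calpha(S153^3.47) - Czeta(Y330^7.53) in Angstrom,
# chi = dihedral C-CA-CG-CZ of Y330^7.53 in degrees, half-open rectangles
# [min, max). The published analysis shows the four base states only as
# heatmap clusters; these rectangles were read qualitatively from those
# clusters and are a declared configuration, not printed values. Base states
# 2 and 3 split into A/B sub-states by the R156^3.50 downward flag.

[[state]]
base = 1
d_min = 5.0
d_max = 10.0
chi_min = -130.0
chi_max = -50.0
split_by_r = false

[[state]]
base = 2
d_min = 5.0
d_max = 10.0
chi_min = 40.0
chi_max = 130.0
split_by_r = true

[[state]]
base = 3
d_min = 11.0
d_max = 17.0
chi_min = 40.0
chi_max = 130.0
split_by_r = true

[[state]]
base = 4
d_min = 11.0
d_max = 17.0
chi_min = -130.0
chi_max = -50.0
split_by_r = false
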