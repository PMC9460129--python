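# Piecewise log-linear vibrotactile firing-threshold model for the four
# glabrous-skin mechanoreceptors.  Threshold value at frequency f (Hz) is
# slope * log10(f) + intercept, in dB re 1 um peak displacement.
# Domains: FAI [0.5, 67], FAII (20, 800], SAI [0.5, 120], SAII [0.5, 400] Hz.
FAI:
  - {slope: -17.22, intercept: 53.91, f_lo: 0.5, f_hi: 10.13}
  - {slope: -12.12, intercept: 48.78, f_lo: 10.13, f_hi: 14.73}
  - {slope: 0.2373, intercept: 34.34, f_lo: 14.73, f_hi: 67.0}
FAII:
  - {slope: -38.64, intercept: 64.57, f_lo: 20.0, f_hi: 237.64}
  - {slope: 24.93, intercept: -86.48, f_lo: 237.64, f_hi: 800.0}
SAI:
  - {slope: -10.90, intercept: 32.77, f_lo: 0.5, f_hi: 20.55}
  - {slope: 9.195, intercept: 6.390, f_lo: 20.55, f_hi: 120.0}
SAII:
  - {slope: -17.22, intercept: 53.90, f_lo: 0.5, f_hi: 10.13}
  - {slope: -12.12, intercept: 48.78, f_lo: 10.13, f_hi: 128.51}
  - {slope: -0.6747, intercept: 24.64, f_lo: 128.51, f_hi: 400.0}
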