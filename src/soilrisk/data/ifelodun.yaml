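# Synthetic-site specification for the Ifelodun beryllium-mining field:
# per-metal summary targets (mean/SD/min/max, mg/kg dry weight) for
# 36 soil samples.  Metals default to independence; marginals are
# truncated normal.
site_id: Ifelodun
n_samples: 36
family: truncated-normal
metals:
  Ni: {mean: 10.03, sd: 2.43, min: 6.00, max: 14.09}
  Cu: {mean: 5.67, sd: 2.83, min: 2.00, max: 12.00}
  Pb: {mean: 10.83, sd: 2.85, min: 6.01, max: 15.01}
  Mn: {mean: 14.00, sd: 5.53, min: 6.01, max: 24.09}
  Mg: {mean: 127.77, sd: 38.69, min: 72.01, max: 235.01}
  As: {mean: 25.01, sd: 9.27, min: 5.01, max: 43.34}
  Zn: {mean: 147.50, sd: 10.96, min: 128.00, max: 160.01}
  Cd: {mean: 30.01, sd: 11.30, min: 12.00, max: 60.37}
  Cr: {mean: 46.13, sd: 28.58, min: 6.80, max: 76.80}
  Fe: {mean: 65.67, sd: 28.70, min: 21.10, max: 151.07}
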