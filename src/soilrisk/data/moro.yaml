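# Synthetic-site specification for the Moro gold-mining field:
# per-metal summary targets (mean/SD/min/max, mg/kg dry weight) for
# 36 soil samples.  Metals default to independence; marginals are
# truncated normal.
site_id: Moro
n_samples: 36
family: truncated-normal
metals:
  Ni: {mean: 6.37, sd: 2.33, min: 4.00, max: 10.01}
  Cu: {mean: 24.61, sd: 15.68, min: 6.01, max: 58.01}
  Pb: {mean: 448.75, sd: 159.10, min: 215.00, max: 643.01}
  Mn: {mean: 15.86, sd: 3.82, min: 10.00, max: 21.00}
  Mg: {mean: 174.56, sd: 38.39, min: 122.00, max: 252.00}
  As: {mean: 23.17, sd: 8.17, min: 10.00, max: 30.00}
  Zn: {mean: 202.63, sd: 31.53, min: 141.81, max: 260.00}
  Cd: {mean: 46.37, sd: 18.26, min: 20.00, max: 92.24}
  Cr: {mean: 62.45, sd: 27.99, min: 11.50, max: 91.20}
  Fe: {mean: 127.58, sd: 16.79, min: 109.80, max: 152.80}
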