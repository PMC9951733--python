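# Per-cycle mean equations for the physico-chemical litter variables,
# as polynomials in the reuse cycle C: value = c0 + c1*C + c2*C**2.
# One equation per (bed type, variable, condition), where condition is the
# pre-treatment "initial" state or one of the four chamber air temperatures
# (deg C). `see` is the residual standard error of the fitted equation in the
# variable's own units; the synthetic generator scales its Gaussian noise to it.
#
# Units: moisture % (dry basis), ph unitless, total_n g/kg, ammoniacal_n g/kg.
wood_shavings:
  max_cycle: 4
  moisture:
    initial: {coef: [42.91, -8.69, 1.22], see: 1.29, r2: 0.96}
    25: {coef: [38.81, -6.95, 1.07], see: 0.14, r2: 0.99}
    30: {coef: [41.89, -8.24, 1.19], see: 1.48, r2: 0.93}
    35: {coef: [37.88, -7.08, 1.17], see: 0.79, r2: 0.95}
    40: {coef: [39.32, -8.43, 1.34], see: 1.41, r2: 0.91}
  ph:
    initial: {coef: [8.43, 0.08, -0.03], see: 0.06, r2: 0.92}
    25: {coef: [8.93, 0.07, -0.04], see: 0.03, r2: 0.99}
    30: {coef: [8.80, 0.16, -0.06], see: 0.06, r2: 0.96}
    35: {coef: [8.61, 0.34, -0.08], see: 0.08, r2: 0.92}
    40: {coef: [8.66, 0.27, -0.07], see: 0.07, r2: 0.93}
  total_n:
    initial: {coef: [4.41, 18.12, -2.52], see: 2.96, r2: 0.95}
    25: {coef: [4.59, 20.22, -3.01], see: 3.98, r2: 0.91}
    30: {coef: [2.69, 20.11, -2.97], see: 0.37, r2: 0.99}
    35: {coef: [4.39, 20.26, -3.07], see: 4.20, r2: 0.90}
    40: {coef: [11.57, 11.46, -1.36], see: 5.01, r2: 0.82}
  ammoniacal_n:
    initial: {coef: [2.50, 4.28, -0.64], see: 0.17, r2: 0.99}
    25: {coef: [5.17, 2.08, -0.29], see: 0.25, r2: 0.97}
    30: {coef: [3.51, 3.96, -0.59], see: 0.41, r2: 0.97}
    35: {coef: [4.43, 2.93, -0.43], see: 0.72, r2: 0.87}
    40: {coef: [4.69, 3.20, -0.46], see: 0.63, r2: 0.92}
coffee_husks:
  max_cycle: 6
  moisture:
    initial: {coef: [32.84, -1.22], see: 1.14, r2: 0.83}
    25: {coef: [31.90, -1.17], see: 0.75, r2: 0.91}
    30: {coef: [29.71, -0.74], see: 0.73, r2: 0.82}
    35: {coef: [31.74, -1.09], see: 1.05, r2: 0.82}
    40: {coef: [31.08, -1.05], see: 0.92, r2: 0.85}
  ph:
    initial: {coef: [8.67, 0.08, -0.02], see: 0.03, r2: 0.94}
    25: {coef: [8.67, 0.18, -0.03], see: 0.03, r2: 0.89}
    30: {coef: [8.74, 0.16, -0.03], see: 0.05, r2: 0.86}
    35: {coef: [8.90, 0.11, -0.02], see: 0.07, r2: 0.73}
    40: {coef: [8.82, 0.14, -0.02], see: 0.04, r2: 0.83}
  total_n:
    initial: {coef: [34.95, -2.86, 0.73], see: 2.71, r2: 0.83}
    25: {coef: [40.97, -5.92, 1.16], see: 1.61, r2: 0.91}
    30: {coef: [37.22, -5.74, 1.18], see: 2.56, r2: 0.82}
    35: {coef: [37.69, -5.19, 1.05], see: 2.73, r2: 0.74}
    40: {coef: [36.64, -4.57, 0.99], see: 2.78, r2: 0.76}
  ammoniacal_n:
    initial: {coef: [6.36, 0.95, -0.09], see: 0.29, r2: 0.89}
    25: {coef: [5.87, 1.33, -0.14], see: 0.30, r2: 0.91}
    30: {coef: [5.56, 1.41, -0.14], see: 0.39, r2: 0.89}
    35: {coef: [5.32, 1.61, -0.17], see: 0.49, r2: 0.86}
    40: {coef: [6.07, 1.36, -0.13], see: 0.57, r2: 0.81}
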