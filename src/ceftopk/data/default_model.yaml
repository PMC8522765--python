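# Final pediatric population PK model for ceftobiprole.
# CL (L/h) = cl_gfr_slope * GFR_Rhodin,FFM (ml/min) + cl_nr
# volumes scale as (weight/ref_weight)^vol_exponent,
# distributional clearances as (weight/ref_weight)^q_exponent.
cl_gfr_slope: 0.0548   # L/h per ml/min
v1_ref: 16.1           # L at 70 kg
q1_ref: 0.545          # L/h at 70 kg
vp1_ref: 49.5          # L at 70 kg
q2_ref: 3.46           # L/h at 70 kg
vp2_ref: 6.13          # L at 70 kg
vol_exponent: 0.911
q_exponent: 0.75       # fixed, allometric theory
cl_nr: 0.0             # nonrenal clearance fixed to zero
ref_weight: 70.0       # kg
omega2_cl: 0.0547      # log-scale IIV variance on CL (23.4 %CV)
omega2_v1: 0.0711      # log-scale IIV variance on V1 (26.7 %CV)
sigma2_prop: 0.0701    # proportional residual variance (26.5 %CV)
sigma2_add: 0.000156   # additive residual variance, (ug/ml)^2 (SD 0.0125)
rhodin:
  gfr_std: 121.2       # ml/min, mature GFR at reference FFM
  tm50: 47.7           # weeks PMA at half-maturation
  hill: 3.40
  ffm_ref: 56.1        # kg, standard adult fat-free mass
  size_exponent: 0.75
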