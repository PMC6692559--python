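# Calibration constants for the surrogate crop-soil simulator.
#
# Every constant used by the surrogate lives in this file. The functional
# forms are deliberately simple (saturating yield response, super-linear
# N2O response, linear SOC recurrence); they are tuned to reproduce the
# qualitative response structure expected of a crop-soil process model,
# not to predict absolute field values.

[yield]
# Mitscherlich response: y = y_pot * (1 - exp(-(N_eff + n_background) / n_scale))
n_background = 30.0      # kg N/ha supplied by soil mineralisation each season
n_scale = 120.0          # kg N/ha e-folding scale of the response

[n2o]
# e = texture_factor * (e0 + e1 * N^alpha + e2 * fym), texture_factor
# strictly increasing in clay fraction so fine-textured soils emit more.
e0 = 0.3                 # baseline emission, t CO2-eq/ha/yr
e1 = 0.004               # coefficient on N^alpha
alpha = 1.4              # super-linear exponent (> 1 => convex in N)
e2 = 0.15                # t CO2-eq per t FYM applied
texture_base = 0.8
texture_clay = 0.6       # texture_factor = texture_base + texture_clay * clay_frac

[soc]
# soc_next = soc_prev + h_fym * fym + h_res * residue_c - decay * soc_prev
h_fym = 0.03             # % SOC per t FYM applied
h_res = 0.006            # % SOC per t residue carbon returned
decay = 0.01             # fractional decay of SOC per season
residue_c_per_yield = 0.4  # t residue C per t grain yield

[nitrogen]
deposition = 25.0        # kg N/ha/yr atmospheric deposition (constant)
fym_n_per_t = 6.0        # kg N per t farm-yard manure
fym_avail_base = 0.30    # fraction of FYM N crop-available when spread at sowing
fym_avail_week = 0.02    # extra availability per week of pre-sowing incorporation
leach_base = 0.05        # leaching fraction at sand_frac = 0
leach_sand = 0.25        # leaching fraction increment per unit sand fraction
timing_bonus = 0.02      # uptake-efficiency bonus per later application slot

[crop]
grain_n_per_t = 19.0     # kg N removed per t grain
straw_ratio = 0.5        # t straw per t grain
straw_n_per_t = 6.0      # kg N removed per t straw

[weather]
rain_prob = 0.4          # daily Bernoulli rain probability
n_days = 160             # days simulated per season from 1 March
yield_wetness_sens = 0.15  # yield penalty scale for seasons wetter/drier than rain_prob

[economics]
# Documented placeholder prices; no authoritative values exist for the
# scenario, so analyses must either be invariant to these or fix them.
crop_price = 150.0       # GBP per t grain
n_price_mineral = 0.79   # GBP per kg mineral N
n_price_fym = 0.40       # GBP per kg FYM N
p_cost_total = 360.0     # GBP per ha, total P fertiliser cost over the simulation
application_cost = 10.0  # GBP per application event
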