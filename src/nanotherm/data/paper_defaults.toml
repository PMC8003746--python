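# Packaged end-to-end characterization scenario ("paper-defaults").
# Every value is editable; units are embedded in the key names.
# Stages run in order; omit entries from `stages` to skip them.

[scenario]
name = "paper-defaults"
seed = 0
stages = ["mie", "heat", "photothermal", "mri", "ct", "size", "plan"]

[particle]
# magnetite core / gold shell / polymer coat, outer radius per layer (nm).
# Radii give the 142 nm TEM diameter with a thin polymer coat.
layer_radii_nm = [55.0, 65.0, 71.0]
# either a named packaged material or an explicit [n, k] pair
materials = ["magnetite", "gold", "polymer"]
medium_index = 1.33
wavelength_nm = 1064.0

[thermal]
# W m^-1 K^-1: magnetite, gold, polymer coat
layer_conductivity = [7.0, 317.0, 0.2]
medium_conductivity = 0.6
medium_diffusivity = 1.43e-7
source_layer = 1          # light is absorbed in the gold shell
irradiance_W_per_cm2 = 1.22

[lumped]
# operating point of the simulated ensemble experiment
eta = 0.426
laser_power = 1.22        # W at 1064 nm
absorbance_1064 = 1.0
total_heat_capacity = 4.186   # J/K (1 mL water)
ambient = 20.5            # deg C
# hS and q_s default to the paper operating point (26 K plateau, 1.3 K water)

[photothermal]
on_s = 1800.0             # irradiation long enough to reach the plateau
off_s = 2400.0
dt_s = 1.0
noise_sd_K = 0.0
# trace_csv / control_csv may point to measured time_s,temperature_C,laser_on files

[sample]
volume_mL = 1.0
np_mass_g = 1e-3          # 1 g/L suspension in 1 mL

[mri]
r2_high = 61.5            # mM^-1 s^-1 at 9.4 T
r2_low = 14.0             # mM^-1 s^-1 at 1.44 T
intercept_s = 2.0         # matrix relaxation rate, s^-1
noise_sd = 0.0

[ct]
slope = 30.0              # HU per mM Au
intercept = 0.0
noise_sd = 0.0

[size]
mean_nm = 142.0
sd_nm = 26.0
n = 100

[grid]
nx = 8
ny = 5
field_size_x = 1412.5     # um; 8 x 1412.5 um = 11.3 mm
field_size_y = 1434.0     # um; 5 x 1434 um = 7.17 mm
n_planes = 38
plane_interval = 20.0     # um; 38 x 20 um = 0.76 mm
time_per_field = 1.725    # min; 40 fields -> 69 min
wavelength = 720.0        # nm
power = 1.75              # W
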