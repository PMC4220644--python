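# cbmorph default configuration.  Every analysis default is explicit here;
# pass an edited copy via --config to override any subset.

[segmentation]
threshold_method = "otsu"      # "otsu" | "manual"
manual_threshold = 128         # used only when threshold_method = "manual"
polarity = "dark_foreground"   # blue stain appears dark in the red channel
min_area = 20                  # px; components below this are artifacts
max_area = 0                   # 0 = unbounded
min_circularity = 0.0          # 4*pi*area/perimeter^2, clipped at 1
max_circularity = 1.0
connectivity = 8               # foreground connectivity: 4 or 8

[morisita]
grid_rows = 0                  # 0 = auto: 3x4 (landscape) / 4x3 (portrait)
grid_cols = 0

[glcm]
distance = 1
angle = 0                      # degrees: 0, 45, 90, 135
levels = 256
symmetric = false
log_base = "e"                 # "e" | "2"
use_mask = false               # restrict pixel pairs to the segmented foreground
enabled = true

[fractal]
sizes = []                     # empty = powers of 2 from 2 to min(dims)/4
n_origins = 10
seed = 0
lacunarity_mode = "cv"         # "cv" | "cv_squared" (FracLac-style)
use_skeleton = true            # analyze the skeleton, not the raw mask

[stats]
alpha = 0.05
control_group = ""             # empty = first group in manifest order
comparison_pair = []           # empty = last two groups in manifest order
dunnett_n_mc = 100000
seed = 0

[stats.roc_direction]
# per-feature override; unlisted features use greater_is_positive
lacunarity = "lesser_is_positive"

[synthetic]
# consumed by the `simulate` CLI verb
width = 256
height = 256
n_lobules = 12
septum_thickness = 6.0
branch_length_mean = 25.0
branch_width = 2.0
stain_noise_sd = 6.0
branch_density_a = 0.0         # cohort A: septa only
branch_density_b = 8.0         # cohort B: dense intralobular branching
match_area = true              # calibrate cohort A's area fraction to cohort B's
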