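# Example run configuration for `oxalipk run --config examples/config.yaml`.
# Any omitted key keeps its default; unknown keys are rejected.

seed: 1
output_dir: runs/example

# study design
n_per_arm: 5
doses: [3.0, 8.0]
renal_effect: true          # generator ties true clearance to creatinine

# generator truth (defaults are the final-model estimates)
# truth_theta: [0.44, 2.26, 1.76, 1.0]   # V1, V2, CL, CL2
# truth_iiv_pct: [37.5, 30.5, 31.5]      # on V1, CL, CL2
# truth_sigma_pct: 14.9

# estimation
n_terminal: 3               # or "auto"
se_method: hessian          # or "sandwich"

# qualification (1000 reproduces the conventional full size)
bootstrap_n: 200
vpc_n: 1000

# renal-impairment exposure simulation
cr_grid: [0.3, 0.5, 1.0, 1.5, 2.5]
mc_n: 1000
sim_dose: 8.0
use_anchor_regression: false

plots: false
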