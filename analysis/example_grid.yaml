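# Example scenario grid for analysis/01_design_grid.py --config
# Each key is a scenario field; lists are crossed into the full grid.
omega1: [0.3, 0.5]
mu1: 0.1
p1: [0.5, 0.7]
p2: 0.7
N: 5000
tail_fraction: 0.1
alpha: 0.05
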