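; N = 12 Lennard-Jones particles; lowering kappa stellates the vesicle
[mesh]
level = 3

[particles]
n = 12
potential = lennard_jones
epsilon = 0.1
re = 1.3
seed = 0

[physics]
kappa = 3.0

[penalties]
lambda_g = 2.0

[solver]
tol = 1e-4
max_iter = 8000
continuation = kappa: 3.0, 2.0, 1.0, 0.5

[output]
dir = out/stellation
refine = 1
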