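; Twelve Coulomb charges on a stiff vesicle: Thomson validation (Ih symmetry)
[mesh]
level = 3

[particles]
n = 12
potential = coulomb
seed = 32

[physics]
kappa = 1.0

[penalties]
lambda_g = 10.0

[solver]
tol = 1e-6
max_iter = 20000

[output]
dir = out/thomson12
refine = 1
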