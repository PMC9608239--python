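; N = 200 Lennard-Jones particles spread from a half sphere and envelope
; the substrate as the preferred distance re grows from 0.15 to 0.31
[mesh]
level = 2

[particles]
n = 200
potential = lennard_jones
epsilon = 0.1
re = 0.15
seed = 3
hemisphere = true

[physics]
kappa = 2.0

[penalties]
lambda_g = 10.0

[solver]
tol = 1e-4
max_iter = 4000
continuation = re: 0.15, 0.16, 0.17, 0.18, 0.19, 0.20, 0.21, 0.22, 0.23, 0.24, 0.25, 0.26, 0.27, 0.28, 0.29, 0.30, 0.31

[output]
dir = out/enveloping
refine = 1
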