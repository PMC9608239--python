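; N = 40 harmonic particles; volume reduction to v = 0.90 pinches a bud
[mesh]
level = 3

[particles]
n = 40
potential = harmonic
re = 0.8
seed = 5

[physics]
reduced_volume = 0.9

[penalties]
lambda_g = 5.0

[solver]
tol = 1e-4
max_iter = 8000
continuation = reduced_volume: 1.0, 0.95, 0.90

[output]
dir = out/budding
refine = 1
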