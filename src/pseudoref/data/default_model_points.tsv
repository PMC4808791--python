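# Default optimal-mismatch-rate model training points.
# Generated by: pseudoref virtual-experiment --seed 1 --genome-length 200000
#   --n-reads 20000 --read-length 100 --n-max 30  (rates 0.01..0.15, Ts/Tv 2.0)
# mutation_rate	optimal_mismatch_rate_pct
0.01	6
0.02	8
0.03	10
0.04	13
0.05	14
0.06	18
0.07	20
0.08	21
0.09	22
0.1	23
0.11	23
0.12	24
0.13	26
0.14	27
0.15	29
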