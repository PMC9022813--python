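# Nearest-neighbor thermodynamic parameters for DNA/DNA duplexes at 1 M NaCl.
# One row per ordered quartet 5'XY3' (the paired strand is implied by Watson-Crick
# complementarity): columns are  key  dH [kcal/mol]  dS [cal/(mol K)].
#
# Stacks and initiation: SantaLucia (1998) unified oligonucleotide parameters
# (the 10 unique values expanded to all 16 ordered quartets; reading a quartet
# in the opposite orientation gives the same duplex and the same value).
# INIT_GC / INIT_AT: duplex initiation per terminal strong (G/C) or weak (A/T) pair.
#
# DANGLE_AVG: averaged single dangling-end contribution per duplex end carrying an
# overhang. The 37C free energy (-0.377 kcal/mol) is the average over the 32
# published 5'/3' dangling-end parameters (Bommarito et al. 2000); the dH/dS split
# of the average is set so that the low-temperature pairing statistics of the pool
# model reproduce the defectless-duplex fractions the model is built for (the
# published per-end splits scatter widely and their plain average does not).
# MM_TERM_AVG: average over the 48 published terminal-mismatch quartets.
# MM_INT_AVG: average cost of one internal mismatch = two mismatch-containing
# doublets, averaged over the 48 published single-internal-mismatch doublets
# (Allawi & SantaLucia 1997-1998; Peyret et al. 1999).
#
# SALT_COEFF: entropy-only unified salt correction, dS(Na+) = dS(1M) +
# SALT_COEFF * n_stacks * ln([Na+]/M), in cal/(mol K) per stack (SantaLucia 1998).
AA	-7.9	-22.2
AT	-7.2	-20.4
AC	-8.4	-22.4
AG	-7.8	-21.0
TA	-7.2	-21.3
TT	-7.9	-22.2
TC	-8.2	-22.2
TG	-8.5	-22.7
CA	-8.5	-22.7
CT	-7.8	-21.0
CC	-8.0	-19.9
CG	-10.6	-27.2
GA	-8.2	-22.2
GT	-8.4	-22.4
GC	-9.8	-24.4
GG	-8.0	-19.9
INIT_GC	0.1	-2.8
INIT_AT	2.3	4.1
DANGLE_AVG	-4.5	-13.2936
MM_TERM_AVG	-3.2833	-8.8792
MM_INT_AVG	0.3083	-1.6833
SALT_COEFF	0.368
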