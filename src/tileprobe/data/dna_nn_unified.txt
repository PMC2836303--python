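# DNA secondary-structure energy parameters, delta-G at 37 C in kcal/mol.
#
# Watson-Crick helix stacks are the SantaLucia (1998) "unified" duplex
# nearest-neighbor delta-G(37) values, keyed by the top-strand step 5'-XY-3'
# (the bottom strand is the Watson-Crick complement).  Hairpin, bulge and
# internal loop penalties are representative DNA loop-initiation values,
# tabulated by loop size and extended beyond the table by the
# Jacobson-Stockmayer logarithmic form.  The multiloop term is the usual
# affine model: a (closing) + b per branch + c per unpaired base.
#
# The folding energy computed from this table is used by the probe-design
# pipeline purely as a self-annealing ranking key (less negative = better
# probe), not as a calibrated physical prediction.
stack AA -1.00
stack AC -1.44
stack AG -1.28
stack AT -0.88
stack CA -1.45
stack CC -1.84
stack CG -2.17
stack CT -1.28
stack GA -1.30
stack GC -2.24
stack GG -1.84
stack GT -1.44
stack TA -0.58
stack TC -1.30
stack TG -1.45
stack TT -1.00
hairpin 3 3.5
hairpin 4 3.5
hairpin 5 3.3
hairpin 6 4.0
hairpin 7 4.2
hairpin 8 4.3
hairpin 9 4.5
hairpin 10 4.6
bulge 1 4.0
bulge 2 2.9
bulge 3 3.1
bulge 4 3.2
bulge 5 3.3
bulge 6 3.5
bulge 7 3.7
bulge 8 3.9
bulge 9 4.1
bulge 10 4.3
internal 2 3.2
internal 3 3.6
internal 4 4.0
internal 5 4.4
internal 6 4.6
internal 7 4.8
internal 8 4.9
internal 9 5.0
internal 10 5.1
multiloop 3.4 0.4 0.0
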