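# Single-Gaussian bead scattering parameters (synthetic).
# Fitted by voxfit.cgfit grid scan (A 0-8 step 0.1; B 0-40 A^2 step 0.5)
# against the atomistic forward model on ideal-geometry polyalanine
# fixtures under a representative B-factor blur of 40 A^2;
# NOT a published parameter set.
type	A1	B1
BB	7.6000	40.0000
SC1	2.3000	10.0000
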