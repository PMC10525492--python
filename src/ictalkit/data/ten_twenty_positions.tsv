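# 10/20 electrode positions on a unit sphere.
# azimuth_deg: measured from the nasion direction, positive toward the right ear.
# inclination_deg: angle from the vertex (Cz = 0); the ear plane sits at 90.
# A1/A2 (earlobes) lie slightly below the equatorial plane.
label	azimuth_deg	inclination_deg
Fp1	-18	72
Fp2	18	72
F7	-54	72
F8	54	72
T3	-90	72
T4	90	72
T5	-126	72
T6	126	72
O1	-162	72
O2	162	72
F3	-43	48
F4	43	48
C3	-90	36
C4	90	36
P3	-137	48
P4	137	48
Fz	0	36
Cz	0	0
Pz	180	36
A1	-90	100
A2	90	100
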