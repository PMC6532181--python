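residue	mass	kd	pka	acid_or_base	polarity
A	89.09	1.8	NA	none	nonpolar
R	174.20	-4.5	12.48	base	polar
N	132.12	-3.5	NA	none	polar
D	133.10	-3.5	3.65	acid	polar
C	121.16	2.5	8.30	acid	nonpolar
Q	146.15	-3.5	NA	none	polar
E	147.13	-3.5	4.25	acid	polar
G	75.07	-0.4	NA	none	nonpolar
H	155.15	-3.2	6.00	base	polar
I	131.17	4.5	NA	none	nonpolar
L	131.17	3.8	NA	none	nonpolar
K	146.19	-3.9	10.53	base	polar
M	149.21	1.9	NA	none	nonpolar
F	165.19	2.8	NA	none	nonpolar
P	115.13	-1.6	NA	none	nonpolar
S	105.09	-0.8	NA	none	polar
T	119.12	-0.7	NA	none	polar
W	204.23	-0.9	NA	none	nonpolar
Y	181.19	-1.3	10.07	acid	polar
V	117.15	4.2	NA	none	nonpolar
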