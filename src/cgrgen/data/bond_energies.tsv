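# Mean bond enthalpies (kJ/mol), standard physical-chemistry compilations
# (Cottrell, The Strengths of Chemical Bonds; CRC Handbook tables).
# element1	element2	order	kJ_per_mol
H	H	-	436
H	F	-	567
H	Cl	-	431
H	Br	-	366
H	I	-	298
F	F	-	159
Cl	Cl	-	243
Br	Br	-	193
I	I	-	151
C	H	-	413
C	C	-	347
C	C	=	614
C	C	#	839
C	C	:	518
C	N	-	305
C	N	=	615
C	N	#	891
C	N	:	509
C	O	-	358
C	O	=	745
C	F	-	485
C	Cl	-	339
C	Br	-	276
C	I	-	240
C	S	-	259
C	S	=	573
C	Si	-	318
C	B	-	356
C	P	-	264
C	Se	-	244
N	H	-	391
N	N	-	163
N	N	=	418
N	N	#	941
N	O	-	201
N	O	=	607
N	B	-	446
N	F	-	272
N	Cl	-	200
N	Br	-	243
O	H	-	463
O	O	-	146
O	O	=	495
O	Si	-	452
O	B	-	536
O	P	-	335
O	I	-	201
S	H	-	363
S	S	-	266
S	O	-	364
S	O	=	522
S	F	-	327
S	Cl	-	253
S	Br	-	218
S	B	-	363
S	Si	-	293
Si	H	-	318
Si	Si	-	222
Si	F	-	565
Si	Cl	-	381
Si	Br	-	310
B	H	-	389
B	B	-	293
B	F	-	613
B	Cl	-	456
B	Br	-	377
B	I	-	272
P	H	-	322
P	Cl	-	326
P	Br	-	264
Se	H	-	276
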