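superfamily	signal_peptide	propeptide	framework	families
I	MKASMFLAFAGLVLLFVVCYA	SELEEESQLMEVGMPDTELEAVDEER	I	HWTX-I,HWTX-III,HWTX-IV,HWTX-V,SHL
II	MKVTLIAILTCAAVLVLHTTAA		II	HWTX-II,HWTX-VII
X	MNMKILVLVAVLCLVVSTHA		I	HWTX-X
XI	MGIARILSAVLFLSVLFVVTFPALLSAD		II	HWTX-XI
XIII	MKYAIVLCVIVIVVTVVRA		I	HWTX-XIII
XIV	MKVVLLVCLVWMMAMMELVSC		VI	HWTX-XIV
XV	MKHFASCIFSVLTVAICGVSQT		III	HWTX-XV,HWTX-XXVIII
XVI	MNTVRVTFLLVFVLAVSLGQA		I	HWTX-XVI
XVII	MKIATFLGLSFLLIASYVLICEA		III	HWTX-XVII
XVIII	MKLSLIIIATSLVIAVVA		IV	HWTX-XVIII
XX	MKLSNFAVVLVGILFVSVPLFA		VII	HWTX-XX,HWTX-XIX
XXI	MLATFIVLFVPIFRNPLCCFQCQVYG		X	HWTX-XXI
XXII	MTWLLMVPLMLLSPLLQIAC		IX	HWTX-XXII
XXIII	MIVLGGMAFSVTSMVVACVV		VIII	HWTX-XXIII
XXIV	MVCATRRLIRLLSSSG		II	HWTX-XXIV
XXV		MTREETQSLGEHEKDEEVTGSEER	XI	HWTX-XXV,HWTX-XXVI
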