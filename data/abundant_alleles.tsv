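sample_id	peptide	abundance_pct	novel
H1	KIISSLSKNTIHNNNYKYNYNNNNNYNNNYKKLQYYNINYIEQIP	53.4	no
H1	KIISSLSNKTIHNNNNYKKLYYNINYIEQIP	9.7	no
H1	KIISSLSNNYNYSNYNNYNNNYNNYKKLYYNINYIEQIP	8.9	no
H2	KIISSLSNSCNYSNNYYNKKLYYNIINIEQIP	53.7	no
H2	KIISSLSNNYNYSNYNNYNNNYNNYKKLYYNINYIEQIP	30.2	no
H2	KIISSLSNKTIHNNNNYKPYYNINYIEQIP	7.7	no
H3	KIISSLSNNYKYSNYNNYNNYNNKKLYYNIINIEQIP	40.0	yes
H3	KIISSLSNKTIHNNNNYNNYKKLYYNIINIEQIP	12.4	yes
H3	KIISSLSNKTIHNNNYKYNYNNNNNYKKLQYYNIINIEQIP	6.3	no
H4	KIISSLSNKTIHNNNNYKPYYNINYIEQIP	83.6	no
H5	KIISSLSSNYNSNNYNNYNNYKQLCYNINYIEQIP	39.6	no
H5	KIISSLSNNYKYSNYNNYNNYNKKLYYKNYIINIEQIP	12.0	no
H5	KIISSLSNNYNYNNKYNYNNNYNKKLYYNIINIEQIP	8.5	no
H6	KIISSLSNKTIHNNNNYKPYYNINYIEQIP	93.1	no
H7	KIISSLSNNYNYNNKYNYNNNYNKKLYYNIINIEQIP	38.2	no
H7	KIISSLSNKTIHNNNKYNYNNNYNNNCKKLYYNINYIEQIP	8.9	yes
H8	KIISSLSNKTIHNNNNYKPYYNINYIEQIP	33.3	no
H8	KIISSLSSNYNSNNYNNYNNYKQLCYNINYIEQIP	25.9	no
H8	KITSSLSNNYNSNNYNKYNYNNSKKLYYNINYIEQIP	13.2	no
H8	KIISSLSNKTIHNNNNYKYNYNNNNYKNYNNYKKLYYNINYIEQIP	5.8	no
H9	KIISSLSNKTIHNNNNYKYNYNNNNYKPYYNINYIEQIP	45.0	no
H9	KIISSLSNKTIHNNNNYKYNYNNNYNNNNYSKKLYYNINYIEQIP	10.3	yes
H9	KIISSLSNNYISNISNYNNNNNSKKLYYNINYIEQIP	5.2	no
H10	KIISSLSNSCNYSNNYYNKKLYYNIINIEQIP	17.6	no
H11	KIISSLSSNYNSNNYNNYNNYKQLCYNINYIEQIP	43.8	no
H11	KIISSLSNKTIHNNNNYKPYYNINYIEQIP	32.5	no
H11	KIISSLSNNYNYNNKYNYNNNYNKKLYYNIINIEQIP	6.7	no
H12	KITSSLSNNYNSNSYNNYNNNYKKLQYYNIINIEQIP	37.5	no
H12	KIISSLSNNYNYSNYNNYNNYNNNYNNYNNNYNNYKKLYYNINYIEQIP	31.5	no
H12	KIISSLSNKTIHNNNNYKYNYNNNNYNNNNYNNNYNNNCKKLYYNINYIEQIP	5.4	no
H12	KIISSLSNNYKYSNYNNYNNYNNNSKKLYKNYIINIEQIP	5.3	no
H12	KIISSLSNSCNYSNNYYNKKLYYNIINIEQIP	5.1	no
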