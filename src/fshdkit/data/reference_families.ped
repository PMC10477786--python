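FSHD1	FSHD1A	FSHD1D	FSHD1B	1	2
FSHD1	FSHD1B	0	0	2	2
FSHD1	FSHD1C	FSHD1D	FSHD1B	1	1
FSHD1	FSHD1D	0	0	1	1
FSHD2	FSHD2A	0	0	2	2
FSHD2	FSHD2B	FSHD2E	FSHD2A	1	1
FSHD2	FSHD2C	FSHD2E	FSHD2A	1	1
FSHD2	FSHD2D	FSHD2E	FSHD2A	1	2
FSHD2	FSHD2E	0	0	1	1
FSHD3	FSHD3A	0	0	2	2
FSHD3	FSHD3B	FSHD3D	FSHD3A	2	1
FSHD3	FSHD3C	FSHD3D	FSHD3A	2	2
FSHD3	FSHD3D	0	0	1	1
FSHD4	FSHD4A	0	0	1	2
FSHD4	FSHD4B	FSHD4A	0	1	0
FSHD4	FSHD4C	FSHD4A	0	2	1
FSHD5	FSHD5A	0	0	1	2
FSHD5	FSHD5B	FSHD5A	0	2	1
FSHD6	FSHD6A	0	0	2	2
FSHD6	FSHD6B	FSHD6D	FSHD6A	1	2
FSHD6	FSHD6C	FSHD6D	FSHD6A	2	1
FSHD6	FSHD6D	0	0	1	1
FSHD7	FSHD7A	0	0	1	2
FSHD7	FSHD7B	FSHD7A	0	2	1
FSHD8	FSHD8A	0	0	2	2
FSHD9	FSHD9A	0	0	2	2
FSHD10	FSHD10A	FSHD10B	FSHD10C	1	2
FSHD10	FSHD10B	0	0	1	0
FSHD10	FSHD10C	0	0	2	0
FSHD11	FSHD11A	0	0	2	2
FSHD12	FSHD12A	0	0	1	2
FSHD13	FSHD13A	FSHD13B	FSHD13C	2	2
FSHD13	FSHD13B	0	0	1	0
FSHD13	FSHD13C	0	0	2	1
FSHD14	FSHD14A	FSHD14B	0	1	2
FSHD14	FSHD14B	0	0	1	2
FSHD15	FSHD15A	FSHD15C	FSHD15B	1	2
FSHD15	FSHD15B	0	0	2	1
FSHD15	FSHD15C	0	0	1	1
FSHD16	FSHD16A	0	0	2	2
FSHD17	FSHD17A	0	0	1	2
FSHD18	FSHD18A	0	0	1	2
FSHD19	FSHD19A	0	0	2	2
FSHD19	FSHD19B	0	FSHD19A	1	2
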