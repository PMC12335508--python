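# synthetic reconstruction: a connected simple graph reproducing the
# published carvedilol index row (M1=154, M2=180, NM1=360, NM2=1029,
# NSS=53.58, NH=6.41); the published polynomial for this drug is not
# realizable by any graph, so this fixture is index-matched, not the
# chemical skeleton.
name carvedilol
edge 1 5
edge 1 22
edge 2 9
edge 2 21
edge 2 28
edge 3 11
edge 4 6
edge 4 30
edge 5 11
edge 6 18
edge 7 17
edge 7 29
edge 8 12
edge 8 22
edge 9 14
edge 10 24
edge 10 26
edge 11 13
edge 12 20
edge 13 18
edge 13 23
edge 14 27
edge 15 16
edge 15 24
edge 16 27
edge 17 20
edge 18 28
edge 19 21
edge 19 22
edge 23 25
edge 23 28
edge 26 27
edge 29 30
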