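# hydrogen-suppressed skeleton of flecainide
name flecainide
atom 1 O
atom 2 C
atom 3 N
atom 4 C
atom 5 C
atom 6 C
atom 7 C
atom 8 C
atom 9 C
atom 10 N
atom 11 C
atom 12 C
atom 13 C
atom 14 O
atom 15 C
atom 16 C
atom 17 F
atom 18 F
atom 19 F
atom 20 C
atom 21 C
atom 22 C
atom 23 O
atom 24 C
atom 25 C
atom 26 F
atom 27 F
atom 28 F
edge 1 2
edge 2 3
edge 3 4
edge 4 5
edge 5 6
edge 6 7
edge 7 8
edge 8 9
edge 9 10
edge 2 11
edge 11 12
edge 12 13
edge 13 14
edge 14 15
edge 15 16
edge 16 17
edge 16 18
edge 16 19
edge 13 20
edge 20 21
edge 21 22
edge 22 23
edge 23 24
edge 24 25
edge 25 26
edge 25 27
edge 25 28
edge 10 5
edge 22 11
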