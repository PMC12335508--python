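# hydrogen-suppressed skeleton of metoprolol
name metoprolol
atom 1 C
atom 2 C
atom 3 C
atom 4 N
atom 5 C
atom 6 C
atom 7 O
atom 8 C
atom 9 O
atom 10 C
atom 11 C
atom 12 C
atom 13 C
atom 14 C
atom 15 C
atom 16 O
atom 17 C
atom 18 C
atom 19 C
edge 1 2
edge 2 3
edge 2 4
edge 4 5
edge 5 6
edge 6 7
edge 6 8
edge 8 9
edge 9 10
edge 10 11
edge 11 12
edge 12 13
edge 13 14
edge 14 15
edge 15 16
edge 16 17
edge 13 18
edge 18 19
edge 19 10
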