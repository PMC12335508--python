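# hydrogen-suppressed skeleton of timolol
name timolol
atom 1 C
atom 2 C
atom 3 C
atom 4 C
atom 5 N
atom 6 C
atom 7 C
atom 8 O
atom 9 C
atom 10 O
atom 11 C
atom 12 N
atom 13 S
atom 14 N
atom 15 C
atom 16 N
atom 17 C
atom 18 C
atom 19 O
atom 20 C
atom 21 C
edge 1 2
edge 2 3
edge 2 4
edge 2 5
edge 5 6
edge 6 7
edge 7 8
edge 7 9
edge 9 10
edge 10 11
edge 11 12
edge 12 13
edge 13 14
edge 14 15
edge 15 16
edge 16 17
edge 17 18
edge 18 19
edge 19 20
edge 20 21
edge 15 11
edge 21 16
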