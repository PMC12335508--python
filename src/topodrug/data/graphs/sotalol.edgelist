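# hydrogen-suppressed skeleton of sotalol
name sotalol
atom 1 C
atom 2 C
atom 3 C
atom 4 N
atom 5 C
atom 6 C
atom 7 O
atom 8 C
atom 9 C
atom 10 C
atom 11 C
atom 12 N
atom 13 S
atom 14 C
atom 15 O
atom 16 O
atom 17 C
atom 18 C
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
edge 13 15
edge 13 16
edge 11 17
edge 17 18
edge 18 8
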