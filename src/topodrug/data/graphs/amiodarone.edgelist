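# hydrogen-suppressed skeleton of amiodarone
name amiodarone
atom 1 C
atom 2 C
atom 3 C
atom 4 C
atom 5 C
atom 6 O
atom 7 C
atom 8 C
atom 9 C
atom 10 C
atom 11 C
atom 12 C
atom 13 C
atom 14 C
atom 15 O
atom 16 C
atom 17 C
atom 18 C
atom 19 I
atom 20 C
atom 21 O
atom 22 C
atom 23 C
atom 24 N
atom 25 C
atom 26 C
atom 27 C
atom 28 C
atom 29 C
atom 30 I
atom 31 C
edge 1 2
edge 2 3
edge 3 4
edge 4 5
edge 5 6
edge 6 7
edge 7 8
edge 8 9
edge 9 10
edge 10 11
edge 11 12
edge 12 13
edge 13 14
edge 14 15
edge 14 16
edge 16 17
edge 17 18
edge 18 19
edge 18 20
edge 20 21
edge 21 22
edge 22 23
edge 23 24
edge 24 25
edge 25 26
edge 24 27
edge 27 28
edge 20 29
edge 29 30
edge 29 31
edge 13 5
edge 31 16
edge 12 7
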