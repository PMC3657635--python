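######################
#....................#
#.########.#########.#
#.########.#########.#
#.########.#########.#
#.###............###.#
#.###.####.#####.###.#
#.###.####.#####.###.#
#.###.####.#####.###.#
#.###.####.#####.###.#
#....................#
#.###.####.#####.###.#
#.###.####.#####.###.#
#.###.####.#####.###.#
#.###.####.#####.###.#
#.###.####.#####.###.#
#.###............###.#
#.########.#########.#
#.########.#########.#
#.########.#########.#
#....................#
######################
# seven door pairs: one of each pair is open on every trial
door 1 (10,3) (10,8)
door 2 (10,13) (10,18)
door 3 (3,10) (8,10)
door 4 (13,10) (18,10)
door 5 (5,7) (5,13)
door 6 (16,7) (16,13)
door 7 (7,5) (13,5)
# nine pictures: id, wall cell, face it hangs on, texture id
picture 1 (2,3) N 1
picture 2 (2,14) N 2
picture 3 (19,6) S 3
picture 4 (19,17) S 4
picture 5 (6,2) W 5
picture 6 (14,19) E 6
picture 7 (4,9) E 7
picture 8 (12,11) W 8
picture 9 (6,6) N 9
# four fixed rewards (collected in per-trial order) and bonus candidate sites
reward 1 (1,4)
reward 2 (1,17)
reward 3 (20,4)
reward 4 (20,17)
bonus (5,1) (16,1) (5,20) (16,20)
start (1,1) 0
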