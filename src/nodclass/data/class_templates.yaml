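# Versioned nodule expression-class level templates (v1).
# One representative per-condition level vector per class, in the fixed
# condition order WT4, WT10, WT14, NN, exoA, bacA, fixJ.
# Levels: down | none | weak | max.
repressed:   [down, down, down, down, down, down, down]
zone1_2:     [max, weak, weak, none, none, weak, none]
bacA:        [weak, none, none, none, none, max, none]
fixJ:        [none, none, none, none, none, weak, max]
diff1:       [none, max, max, none, none, weak, max]
diff2:       [none, max, max, none, none, none, max]
fix_plus:    [none, max, max, down, none, none, none]
all_star:    [weak, max, max, none, none, weak, weak]
all:         [weak, max, max, none, weak, weak, weak]
NN:          [none, weak, weak, max, none, none, none]
exo1:        [weak, weak, weak, none, max, weak, weak]
exo2:        [none, none, none, none, max, none, none]
N4:          [max, weak, weak, none, weak, none, none]
fix_plus_NN: [none, max, max, weak, none, none, none]
wt_nodules:  [weak, max, max, none, none, none, none]
unclear:     [max, none, none, none, none, down, none]
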