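"""Extract ranked-pattern candidates from one labeled sentence tree.

The sentence "I arrived to my appointment on time and waited in his
waiting room for over an hour" expresses a long wait. Given four seed
words, extraction prunes the tree to those words (wildcarding connective
structure) and enumerates subtree patterns; each would be labeled "y"
(long wait) and later scored on a training corpus.
"""

from deptc import WordSet, extract, parse_bracketed_tree

tree = parse_bracketed_tree(
    "[arrived/VBD nsubj>I/PRP nmod>[appointment/NN case>to/TO poss>my/PRP$] "
    "nmod>[time/NN case>on/IN] cc>and/CC conj>[waited/VBD "
    "nmod>[room/NN case>in/IN poss>his/PRP$ compound>waiting/NN] "
    "nmod>[hour/NN case>for/IN advmod>over/RB det>an/DT]]]"
)
seeds = WordSet(words=("arrived", "time", "room", "hour"), cap=4)
pairs = extract(seeds, tree, label="y", m=4)

print(f"{len(pairs)} patterns extracted; each matches the source tree:")
for pattern, label in sorted(pairs, key=lambda pl: pl[0].source_text):
    print(f"  [{label}] {pattern}")
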