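"""Parse a dependency tree and test semgrex patterns against it.

The tree encodes "there are never long wait times": the verb "are"
governs a negation ("never") and the noun phrase "long wait times".
"""

from deptc import matches, parse_bracketed_tree, parse_pattern

tree = parse_bracketed_tree(
    "[are/VBP expl>there/EX neg>never/RB nsubj>[times/NNS compound>[wait/NN amod>long/JJ]]]"
)
print("words (tree order):", tree.text)
print("nodes:", len(tree))

# a node with a direct negation dependent and, somewhere below, "wait"
# directly governing "long" — the signature of a negated long-wait phrase
pattern = parse_pattern("{} >neg {} >> ({word:wait} > {word:long})")
print("pattern:", pattern)
print("matches:", matches(pattern, tree))

# an unrelated word does not appear in the tree
print("zebra matches:", matches(parse_pattern("{word:zebra}"), tree))
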