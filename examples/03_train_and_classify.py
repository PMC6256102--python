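"""Train on a synthetic corpus and classify a new sentence.

The generator plants a negated "wait long" construction in short-wait
("x") sentences and a "waited ... hour" construction in long-wait ("y")
sentences of the wait_time class; everything else is filler. The trained
model's top patterns should recover those constructions at score 1.0.
"""

from deptc import classify, default_config, generate, parse_bracketed_tree, train

corpus = generate(default_config(seed=0, n_per_label=30))
print(f"corpus: {len(corpus)} sentences, classes {corpus.class_ids}")

model = train(corpus, "wait_time")
print(f"{len(model.ranked)} ranked patterns; top 3:")
for rp in model.ranked[:3]:
    print(f"  score={rp.score:.3f} label={rp.label}  {rp.pattern}")

# a fresh sentence containing the planted negation construction
tree = parse_bracketed_tree(
    "[are/VBP expl>there/EX neg>never/RB nsubj>[times/NNS compound>[wait/NN amod>long/JJ]]]"
)
pred = classify(model, tree)
print("new sentence words:", tree.text)
print(f"predicted: {pred.predicted_label} (fallback: {pred.via_fallback})")
print("matched:", pred.matched_pattern.pattern if pred.matched_pattern else None)
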