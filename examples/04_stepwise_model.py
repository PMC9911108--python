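"""Grow a compact mixed linear/B-spline SVM by stepwise forward selection.

Candidates enter with a fixed encoding — linear if the penalized stage chose
them, an order-s B-spline block if only the nonlinear screen did — and the
greedy search adds whichever candidate raises the leave-one-out accuracy
most, stopping when nothing improves.  The fitted model serializes to JSON
and scores raw (unstandardized) subject rows.
"""

from hingeselect.model_builder import TrainedModel, predict, stepwise_forward
from hingeselect.synthetic import generate, presets

table, truth = generate(presets()["mixed8"], seed=3)
candidates = ["N_pct", "Vcl", "ESR", "CHOL", "AST"]
encodings = {
    "N_pct": "linear", "Vcl": "linear",
    "ESR": ("bspline", 4), "CHOL": ("bspline", 4), "AST": ("bspline", 4),
}

model, trace = stepwise_forward(table, candidates, encodings, max_vars=4)
print("stepwise trace (LOO-CV accuracy after each addition):")
print(trace.to_string(index=False))

row = {v: table.data[v].iloc[0] for v in model.feature_map.variables}
score, cls = predict(model, row)
label = model.positive_class if cls == 1 else model.negative_class
print(f"\nfirst subject: score={score:+.3f} -> predicted {label} "
      f"(true: {'SRNS' if table.labels.iloc[0] == 1 else 'SSNS'})")

clone = TrainedModel.from_json(model.to_json())
assert clone.predict(row) == model.predict(row)
print("model JSON round-trip verified: identical predictions")
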