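"""Render a functional diagram (radar chart with risk zones) to SVG."""

from periorisk import (AxisScoreVector, build_model_spec, classify,
                       render_diagram)

spec = build_model_spec("modified8")
# a high-risk exemplar: generalized BOP, many deep pockets, 10-19/day smoker
vector = AxisScoreVector("modified8", [5, 5, 0, 3, 0, 0, 0, 0],
                         axis_names=spec.axis_names)
path = render_diagram(vector, output_path="high_risk.svg")
print(f"wrote {path}; category = {classify(vector).category}")

# The SVG shows the three concentric risk zones (low inside radius 1.5,
# moderate to 3.5, high beyond) with the patient's score polygon overlaid.
# Output is byte-identical across runs for the same vector and style.
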