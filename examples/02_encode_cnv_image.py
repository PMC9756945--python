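"""Encode one candidate CNV as a 224x224 RGB image.

Selects the depth-correlated reference panel for a carrier sample (excluding
its family), renders the case polyline in blue over the panel in gray and
writes the PNG the classifier would see.
"""


import cnvconfirm as cc

cohort = cc.simulate_cohort(cc.SimulationConfig(n_families=5, seed=0))
normalized, _ = cc.gc_normalize(cohort.matrix)
call = max(cohort.truth_calls, key=lambda c: c.num_targets)
print(f"candidate: {call.cnv_type} {call.chrom}:{call.start}-{call.end} "
      f"({call.num_targets} targets) in {call.sample_id}")

panel = cc.select_references(
    normalized, call.sample_id, k=100,
    exclude=cohort.pedigree.family_members(call.sample_id),
)
print(f"reference panel: {len(panel.reference_ids)} samples, "
      f"top correlation {panel.correlations[0]:.3f}")

image = cc.encode_cnv_image(call, normalized, panel)
blue = int((image.pixels == (0, 0, 255)).all(axis=-1).sum())
gray = int((image.pixels == (128, 128, 128)).all(axis=-1).sum())
print(f"image {image.pixels.shape}: {blue} case-blue pixels, {gray} reference-gray pixels")
image.save_png("cnv_example.png")
direction = "dips below" if call.cnv_type == "DEL" else "rises above"
print(f"wrote cnv_example.png — the case line {direction} the gray band over the {call.cnv_type}")
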