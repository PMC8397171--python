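"""Annotation arithmetic on a packaged mitogenome table.

Loads the transcribed H. persimilis annotation, checks its internal
consistency, and builds the signed junction ledger: positive values are
intergenic spacers, negative values gene overlaps, and the whole circle
must close exactly (sizes + signed gaps = genome length).
"""

import mitolepi as ml

ann = ml.packaged_annotation("hestina_persimilis")
print(f"{ann.species}: {len(ann.features)} features, {ann.genome_length} bp")
print(f"  canonical lepidopteran gene order: {ann.has_canonical_order()}")
print(f"  13 PCGs total {sum(f.size for f in ann.by_category('PCG'))} bp; "
      f"rrnL {ann.feature('rrnL').size} bp, rrnS {ann.feature('rrnS').size} bp, "
      f"control region {ann.feature('control_region').size} bp")

for issue in ml.validate_annotation(ann):
    print(f"  table typo surfaced -> {issue.gene}: {issue.message}")

ledger = ml.build_ledger(ann)
s = ledger.summary
print(f"  {s.spacer_count} spacers ({s.spacer_min}-{s.spacer_max} bp, "
      f"{s.spacer_total} bp total), excluding the control region")
print(f"  {s.overlap_count} overlaps ({s.overlap_min}-{s.overlap_max} bp, "
      f"{s.overlap_total} bp total)")
print(f"  largest spacer trnQ-nad2: {ledger.junction('trnQ', 'nad2').ign} bp; "
      f"conserved trnS2-nad1 spacer: {ledger.junction('trnS2', 'nad1').ign} bp")

closure = sum(f.size for f in ann.features) + sum(j.ign for j in ledger.junctions)
print(f"  circle closure: sizes + signed gaps = {closure} bp (= genome length)")
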