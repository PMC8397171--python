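"""Dissecting the A+T-rich control region.

The generator plants the four conserved lepidopteran control-region
structures (ATAGA origin motif + poly-T, an (AT)n microsatellite, a tandem
repeat, and a poly-A before trnM); the dissector must find each one at its
planted position.  Offsets are 0-based within the control region, read
from the rrnS-proximal end.
"""

import mitolepi as ml

rec, truth = ml.simulate_mitogenome(ml.default_template(), seed=42)
report = ml.dissect_control_region(rec)
ce = truth.control_elements

print(f"control region {report.start}-{report.end} ({report.length} bp), "
      f"AT {report.pct_at:.1f}%")
print(f"  ATAGA origin motif at offset {report.origin_motif} "
      f"(planted at {ce['origin_motif_offset']})")
print(f"  poly-T: {report.poly_t.length} bp at offset {report.poly_t.start} "
      f"(planted {ce['poly_t_length']} bp)")
micro = report.microsatellites[0]
print(f"  microsatellite ({micro.motif})n: {micro.copies} copies at offset {micro.start}")
planted = next(a for a in report.tandem_repeats
               if a.unit_length == ce["tandem_unit_length"])
print(f"  tandem repeat: {planted.unit_length} bp unit x {planted.copies} copies, "
      f"identity {planted.identity:.2f}")
print(f"  poly-A: {report.poly_a.length} bp ending at the trnM boundary")
print(f"  ({len(report.tandem_repeats) - 1} short-unit background arrays also "
      "reported - expected in sequence this AT-rich)")
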