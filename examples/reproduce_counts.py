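"""Diff the pipeline's outcome against the published profiling counts.

Runs on the built-in constructed fixture (a synthetic stand-in whose
pipeline outcome is known by construction); point ``reproduce`` at a
locally downloaded copy of the deposited table to check the real data the
same way (see also ``panelfish reproduce --cq ...`` on the command line).
"""

import panelfish as pf
from panelfish.synthetic_data import REFERENCE_TARGET_ID

panel, annotation, _ = pf.synthetic_reference_panel()
report = pf.reproduce(panel, annotation, target_mirna=REFERENCE_TARGET_ID)

print(f"t-test variant used: {report.variant_used}")
for item in report.items:
    status = "PASS" if item["passed"] else "FAIL"
    print(f"{status}  {item['item']}: expected {item['expected']}, "
          f"obtained {item['obtained']}")
print("all items pass" if report.all_pass else "some items FAILED")
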