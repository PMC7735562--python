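"""Assay-quality check: Z' factor between vehicle and positive wells.

Runs a reduced version of the QC protocol (4 + 4 wells, 3 fields each) and
prints the per-feature Z' factors.  Z' = 1 - 3(sd+ + sd-)/|mean+ - mean-|;
values above 0.5 indicate a screening window wide enough for single-replicate
hit calling.  The full-scale protocol (8 + 8 wells, 6 fields) is what
scripts/acceptance.py reports.
"""

from npcscreen.protocols import run_qc_protocol

result = run_qc_protocol(seed=1, n_vehicle=4, n_positive=4, n_fields=3)
print("Z' factors (vehicle vs. saturating-dose positive wells):")
for feature, zp in result.z_prime_by_feature.items():
    verdict = "excellent" if zp >= 0.5 else "marginal" if zp > 0 else "unusable"
    print(f"  {feature:16s} {zp:6.3f}  ({verdict} screening window)")
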