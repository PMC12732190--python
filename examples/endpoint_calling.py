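"""Endpoint calling with the mean + 3 SD rule and edge-effect filtering.

Area measurements (mm^2) from a high-titer dilution row: the first five
wells show the edge-effect artifact (the agglutinated mat rolled into small
polygons, so their thresholded areas are deceptively small), wells 6-14 are
clearly agglutinated, and the series goes negative from well 15.  The
caller flags the artifact wells and places the endpoint at well 14.
"""

from hemaquant import call_endpoint, negative_stats

pbs_row = [1.10, 1.19, 1.07, 1.15, 1.21, 1.09, 1.13, 1.18, 1.06, 1.16, 1.12, 1.20]
stats = negative_stats(pbs_row)
print(
    f"negative controls: mean {stats.mean_area_mm2:.3f} mm^2, "
    f"SD {stats.sd_area_mm2:.3f}, threshold {stats.threshold_area_mm2:.3f} mm^2"
)

areas = [0.5, 0.6, 0.4, 0.5, 0.6] + [22.0, 21.5, 20.0, 18.0, 15.0, 12.0, 9.0, 6.0, 4.0] + [1.1] * 10
call = call_endpoint(areas, stats)
print(f"last positive well : {call.last_positive}")
print(f"first negative well: {call.first_negative}")
print(f"titer              : {call.hau_display} HAU")
print(f"edge-effect flags  : wells {call.artifact_wells} (ignored, not endpoints)")
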