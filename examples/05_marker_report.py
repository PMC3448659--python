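"""Find which features co-cluster with progression markers.

Marker vectors are appended to the analysis matrix as ordinary nodes;
after clustering, each marker's co-members are candidate biomarkers,
ranked by Spearman correlation with the marker.  Probes recurring in
the clusters of two or more distinct markers are 'robust'.
"""

import pandas as pd

from mstknn import (
    assemble_analysis_matrix,
    cluster,
    find_marker_clusters,
    planted_expression,
    planted_marker,
    rank_members,
    robust_markers,
)

ds = planted_expression(n_blocks=4, features_per_block=15, n_samples=17, seed=0)
# two markers tracking the same block: its features should be 'robust'
m1 = planted_marker(ds, 1, rho_target=0.9, seed=1, name="cognitive_score")
m2 = planted_marker(ds, 1, rho_target=0.9, seed=2, name="pathology_count")
table = pd.DataFrame(ds.markers, index=ds.X.columns)

analysis = assemble_analysis_matrix(ds.X, None, table)
result = cluster(analysis)
found = find_marker_clusters(result, list(table.columns))

reports = []
for name, members in found.items():
    report = rank_members(members, analysis, table[name].to_numpy(), marker_id=name)
    reports.append(report)
    top = report.members[:3]
    print(f"{name}: {len(members)} co-clustered features; top correlations:")
    for fid, rho in top:
        print(f"   {fid}  {rho:+.6f}")

robust = robust_markers(reports)
print(f"\n{len(robust)} probes cluster with both markers "
      f"(all from planted block 1): {sorted(robust)[:5]} ...")
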