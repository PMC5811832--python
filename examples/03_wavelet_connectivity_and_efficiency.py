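"""Wavelet correlation at scale 2 and density-thresholded efficiency.

Decomposes ROI series with the MODWT, forms the scale-2 wavelet
correlation matrix (0.0625-0.125 Hz at TR = 2 s), binarizes at 5% edge
density and computes global/local efficiency.
"""

from wavegraph import (
    CohortSpec,
    WaveletSpec,
    binarize_density,
    efficiency_metrics,
    generate_cohort,
    scale_band,
    wavelet_correlation_matrix,
)

wspec = WaveletSpec()  # D(4) filter, 4 levels, scale 2, periodic boundary
lo, hi = scale_band(wspec, tr=2.0)
print(f"scale-{wspec.scale} band at TR = 2 s: {lo:.4f}-{hi:.3f} Hz")

spec = CohortSpec(groups=(("HV", 2), ("AD", 2)), sessions=("placebo",), seed=4)
series, _ = generate_cohort(spec)

for (subj, _), ts in sorted(series.items()):
    mat = wavelet_correlation_matrix(ts, wspec)
    graph = binarize_density(mat, density=0.05)
    res = efficiency_metrics(graph)
    print(
        f"{subj}: {graph.n_edges} edges "
        f"E_glob = {res.global_efficiency:.3f}  E_loc = {res.local_efficiency:.3f}"
    )
# Every 90-ROI graph keeps exactly floor(0.05 * 4005) = 200 edges, so group
# differences in efficiency cannot be driven by edge count.  The AD
# subjects were generated with stronger modular coupling, which shows up
# as higher local efficiency (more clustered, segregated topology).
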