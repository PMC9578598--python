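"""Build a synthetic mucin cluster and rediscover its genes by criteria.

Generates a three-gene cluster between two marker genes, then scans the
inter-marker interval for genes satisfying the membrane-mucin criteria
(ATG-initiated ORF, long PTS-rich segment, downstream SEA-like domain) and
reports cluster metrics. The recovered coordinates should match the planted
truth, and the intergenic distances should equal the planted values.
"""

from mucloc.cluster_scanner import call_mucin_genes, cluster_metrics, locate_marker
from mucloc.synthetic_data import ClusterSpec, build_cluster_genome

spec = ClusterSpec(seed=7)
contig, truth = build_cluster_genome(spec)
print(f"synthetic genome: {len(contig):,} bp, {spec.n_genes} planted genes")

m5 = truth.marker_intervals["marker5"]
m3 = truth.marker_intervals["marker3"]
anchors = (
    locate_marker(contig, contig.seq[m5.start:m5.end], "marker5"),
    locate_marker(contig, contig.seq[m3.start:m3.end], "marker3"),
)
print(f"anchors located at {anchors[0].interval.start:,} and "
      f"{anchors[1].interval.start:,} (identity "
      f"{anchors[0].identity:.0f}%/{anchors[1].identity:.0f}%)")

candidates = call_mucin_genes(contig, anchors)
print(f"\ncandidates called: {len(candidates)}")
for cand, model in zip(candidates, truth.gene_models):
    pts = cand.pts_exon
    print(f"  {model.gene_id}: [{cand.start:,}, {cand.end:,})  "
          f"PTS exon {pts.length:,} nt  SEA identity "
          f"{cand.sea_hit.identity:.0f}%  TM={cand.tm_segment is not None}  "
          f"PDZ={cand.pdz}")

metrics = cluster_metrics(candidates)
print(f"\ncluster span: {metrics.span_kbp} kbp")
print(f"intergenic distances: {metrics.intergenic_bp} bp "
      f"(planted: {truth.intergenic_lengths})")
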