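#!/usr/bin/env python
"""Link-level group comparison and restriction to node-level findings.

Regenerates the default cohort (FA, streamline count and mean fiber length
connectomes), tests every sufficiently present link for FND < HC adjusted
for age and sex, and keeps the significant FA links that touch a region
already flagged by the weighted-degree analysis — the edge list a
connectogram would display — with per-region altered-link counts out of 83.
Writes under results/links/.
"""

from pathlib import Path

from fndconn.graph_metrics import link_values, wd_table
from fndconn.group_stats import DesignSpec, restrict_links_to_nodes, test_links, test_nodes
from fndconn.synthetic import default_scenarios, generate_cohort

OUT = Path("results/links")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    connectomes, cohort, _ = generate_cohort(default_scenarios()["paper_like"], seed=SEED)
    design = DesignSpec(covariates=("age", "sex"), direction="fnd_lower")

    node_res = test_nodes(wd_table(connectomes["fa"]), cohort, design)
    wd_nodes = set(node_res.loc[node_res["significant"], "node"])

    fa_results = None
    for kind in ("fa", "nstreamlines", "mean_length_mm"):
        res = test_links(link_values(connectomes[kind]), cohort, design,
                         presence_threshold=0.5)
        res[res["tested"]].to_csv(OUT / f"link_results_{kind}.tsv", sep="\t",
                                  index=False, float_format="%.10g")
        print(f"{kind:15s}: {int(res['tested'].sum())} links tested, "
              f"{int(res['significant'].sum())} significant (FND lower)")
        if kind == "fa":
            fa_results = res

    kept, counts = restrict_links_to_nodes(fa_results, wd_nodes)
    kept[["region_a", "region_b", "t_stat", "p_adj"]].to_csv(
        OUT / "connectogram_edges.tsv", sep="\t", index=False, float_format="%.10g")
    counts.rename("n_altered_links_of_83").rename_axis("node").reset_index().to_csv(
        OUT / "node_link_counts.tsv", sep="\t", index=False)
    print(f"\n{len(kept)} significant FA links touch one of the {len(wd_nodes)} "
          f"WD-flagged regions; busiest regions:")
    print(counts.sort_values(ascending=False).head(5).to_string())


if __name__ == "__main__":
    main()
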