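#!/usr/bin/env python
"""Node-level group comparison of weighted degree under three covariate models.

Regenerates the default cohort (same seed as 01), computes each subject's
84 weighted-degree values, and tests FND < HC per region under age+sex,
age+sex+medication, and age+sex+BDI+STAI-T adjustment, with BH-FDR at
q = 0.05. Writes per-model result tables under results/nodes/ and reports
how many of the planted regions each model recovers.
"""

from pathlib import Path

from fndconn.group_stats import DesignSpec, test_nodes
from fndconn.pipeline import COVARIATE_MODELS
from fndconn.synthetic import default_scenarios, generate_tables

OUT = Path("results/nodes")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    wd, _, _, cohort, truth = generate_tables(default_scenarios()["paper_like"], seed=SEED)
    planted = set(truth.planted_nodes)
    for model, covs in COVARIATE_MODELS.items():
        for direction in ("fnd_lower", "fnd_higher"):
            res = test_nodes(wd, cohort, DesignSpec(covariates=covs, direction=direction))
            res.to_csv(OUT / f"node_results_{model}_{direction}.tsv", sep="\t",
                       index=False, float_format="%.10g")
            found = set(res.loc[res["significant"], "node"])
            line = f"{model:22s} {direction:10s}: {len(found):2d}/84 significant"
            if direction == "fnd_lower":
                line += (f", recovers {len(found & planted)}/{len(planted)} planted"
                         f" (sensitivity {len(found & planted) / len(planted):.2f})")
            print(line)
    print("\nMood adjustment removes the mediated (group->mood->FA) share of the"
          " deficit, so the age+sex+BDI+STAI-T model keeps fewer regions —"
          " chiefly those carrying the planted direct effect.")


if __name__ == "__main__":
    main()
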