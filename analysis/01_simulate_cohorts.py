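#!/usr/bin/env python
"""Generate the discovery and validation cohorts used by the analysis.

Writes a discovery cohort (n=120, three planted expression subtypes with
distinct survival hazards) and an independent validation cohort (n=200,
same generative process, new draws) to ``results/data/`` as plain TSV/GMT
files, together with the planted truth for later comparison.
"""

from pathlib import Path

from aktsubtypes import CohortConfig, generate_cohort
from aktsubtypes import io as aio

OUT = Path("results/data")
DISCOVERY_SEED, VALIDATION_SEED = 20, 21


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    discovery = generate_cohort(CohortConfig(n_samples=120, seed=DISCOVERY_SEED))
    validation = generate_cohort(CohortConfig(n_samples=200, seed=VALIDATION_SEED))

    for name, cohort in [("discovery", discovery), ("validation", validation)]:
        aio.write_expression(cohort.expression, OUT / f"{name}_expression.tsv")
        aio.write_clinical(cohort.clinical, OUT / f"{name}_clinical.tsv")
        cohort.truth_labels.rename("subtype").to_csv(
            OUT / f"{name}_truth_labels.tsv", sep="\t", header=True,
            index_label="sample_id",
        )
    aio.write_gene_list(discovery.truth_panel, OUT / "panel_candidates.txt")
    aio.write_gmt(discovery.gene_sets, OUT / "gene_sets.gmt")
    for subtype, track in discovery.qtracks.items():
        aio.write_qtrack(track, OUT / f"qtrack_subtype{subtype}.tsv")

    print(f"discovery cohort: {discovery.expression.data.shape[1]} samples, "
          f"{discovery.expression.data.shape[0]} genes, "
          f"panel of {len(discovery.truth_panel)} candidates")
    print(f"validation cohort: {validation.expression.data.shape[1]} samples")
    print(f"wrote inputs to {OUT}/")


if __name__ == "__main__":
    main()
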