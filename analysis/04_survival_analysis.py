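#!/usr/bin/env python
"""Survival characterization of the discovered subgroups.

One-vs-rest Kaplan-Meier medians and log-rank tests per subgroup, a Cox
check that the long-surviving subgroup's effect survives age adjustment,
and the within-subgroup treatment contrast after removing patients younger
than 45 (so age no longer confounds the treated/untreated comparison).
Writes tables to ``results/survival/``.
"""

from pathlib import Path

import pandas as pd

from aktsubtypes import cox_age_adjust, one_vs_rest_survival, treatment_contrast
from aktsubtypes import io as aio

DATA = Path("results/data")
DISC = Path("results/discovery")
OUT = Path("results/survival")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    clinical = aio.read_clinical(DATA / "discovery_clinical.tsv")
    labels_table = pd.read_csv(DISC / "labels.tsv", sep="\t")
    labels = labels_table[labels_table["kept"]].set_index("sample_id")["label"]

    ovr = one_vs_rest_survival(labels, clinical)
    ovr.to_csv(OUT / "one_vs_rest.tsv", sep="\t", index=False)
    print("one-vs-rest survival:")
    print(ovr.to_string(index=False))

    best = ovr.loc[ovr["p"].idxmin(), "subgroup"]
    cox = cox_age_adjust(labels, clinical, target=best)
    cox.to_csv(OUT / f"cox_age_adjusted_subgroup{best}.tsv", sep="\t")
    print(f"\nCox age-adjusted model for subgroup {best}:")
    print(cox.to_string())

    try:
        contrast = treatment_contrast(clinical, labels, subgroup=best,
                                      treatment_col="alkylator", age_floor=45.0)
        pd.DataFrame([contrast]).to_csv(OUT / "treatment_contrast.tsv",
                                        sep="\t", index=False)
        print(f"\ntreatment contrast in subgroup {best} (age >= 45): "
              f"treated median {contrast['median_treated']}, "
              f"untreated median {contrast['median_untreated']}, "
              f"log-rank p = {contrast['p']:.3g} "
              f"(n = {contrast['n_treated']}/{contrast['n_untreated']})")
    except ValueError as err:
        print(f"\ntreatment contrast unavailable: {err}")


if __name__ == "__main__":
    main()
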