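#!/usr/bin/env python
"""Clinical/molecular feature enrichment per subgroup.

For each subgroup versus the pooled rest: F test for age, likelihood-ratio
(G) test for binary molecular flags, both Bonferroni-corrected over the
full family. Tukey HSD localizes pairwise age differences, and the
Monte-Carlo Pearson goodness-of-fit test asks whether flag-positive tumors
distribute across subgroups in proportion to subgroup sizes, with
standardized residuals pointing at the deviating subgroup. Tables go to
``results/enrichment/``.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from aktsubtypes import (
    f_test_one_vs_rest,
    lr_test_categorical,
    mc_goodness_of_fit,
    tukey_hsd_pairwise,
)
from aktsubtypes import io as aio

DATA = Path("results/data")
DISC = Path("results/discovery")
OUT = Path("results/enrichment")
FLAGS = ("idh1_like", "gcimp", "recurrent")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    clinical = aio.read_clinical(DATA / "discovery_clinical.tsv").set_index("sample_id")
    labels_table = pd.read_csv(DISC / "labels.tsv", sep="\t")
    labels = labels_table[labels_table["kept"]].set_index("sample_id")["label"]
    clinical = clinical.loc[labels.index]

    subgroups = sorted(labels.unique())
    n_hyp = len(subgroups) * (1 + len(FLAGS))
    rows = []
    for target in subgroups:
        r = f_test_one_vs_rest(clinical["age"], labels, target, feature="age",
                               n_hypotheses=n_hyp)
        rows.append({"feature": "age", "subgroup": target, "kind": "F",
                     "statistic": r.statistic, "p": r.p,
                     "p_bonferroni": r.p_bonferroni, "direction": r.direction})
        for flag in FLAGS:
            r = lr_test_categorical(clinical[flag], labels, target, feature=flag,
                                    n_hypotheses=n_hyp)
            rows.append({"feature": flag, "subgroup": target, "kind": "G",
                         "statistic": r.statistic, "p": r.p,
                         "p_bonferroni": r.p_bonferroni, "direction": r.direction})
    report = pd.DataFrame(rows)
    report.to_csv(OUT / "feature_enrichment.tsv", sep="\t", index=False)
    sig = report[report["p_bonferroni"] < 0.05]
    print(f"{len(sig)} of {len(report)} feature x subgroup tests significant "
          f"after Bonferroni (family = {n_hyp}):")
    print(sig.to_string(index=False))

    tukey = tukey_hsd_pairwise(clinical["age"], labels)
    tukey.to_csv(OUT / "age_tukey_hsd.tsv", sep="\t", index=False)
    print("\nTukey HSD on age:")
    print(tukey.to_string(index=False))

    # do flag-positive tumors follow overall subgroup proportions?
    sizes = labels.value_counts().sort_index()
    null_props = (sizes / sizes.sum()).to_numpy()
    gof_rows = []
    for flag in FLAGS:
        observed = [int(clinical.loc[labels == g, flag].sum()) for g in subgroups]
        res = mc_goodness_of_fit(observed, null_props, n_sim=10_000, seed=SEED)
        gof_rows.append({"feature": flag, "statistic": res["statistic"],
                         "p": res["p"],
                         "residuals": ";".join(f"{r:.2f}" for r in res["residuals"]),
                         "deviating": ";".join(
                             str(g) for g, f in zip(subgroups, res["flagged"]) if f)})
    gof = pd.DataFrame(gof_rows)
    gof.to_csv(OUT / "mc_goodness_of_fit.tsv", sep="\t", index=False)
    print("\nMonte-Carlo goodness of fit of flag counts vs subgroup proportions:")
    print(gof.to_string(index=False))


if __name__ == "__main__":
    main()
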