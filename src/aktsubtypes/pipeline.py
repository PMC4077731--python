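"""End-to-end orchestration of the subtyping analysis.

``run_pipeline`` wires the stages together on a synthetic (or supplied)
cohort: median centering, panel selection, consensus discovery across a
range of k, CDF-based model selection, silhouette filtering, boundary-model
fitting, optional validation-cohort assignment, one-vs-rest survival, and
per-subgroup feature enrichment. Outputs are tidy TSV tables plus a JSON
manifest recording the seed, chosen parameters and a checksum per written
file, so a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as aio
from .classifier import assign_cohort, fit_boundaries
from .consensus import (
    ConsensusParams,
    build_consensus,
    consensus_cdf_summary,
    silhouette_filter,
    survival_k_scan,
)
from .enrichment import f_test_one_vs_rest, lr_test_categorical
from .preprocessing import median_center, select_panel, subset_to_panel
from .survival import one_vs_rest_survival
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of a full pipeline run.

    When ``expression_path`` is unset a synthetic cohort is generated from
    ``cohort``; otherwise expression/clinical/candidate files are read from
    the given paths.
    """

    out_dir: str = "results/pipeline"
    seed: int = 0
    cohort: CohortConfig | None = None
    expression_path: str | None = None
    clinical_path: str | None = None
    candidates_path: str | None = None
    validation_expression_path: str | None = None
    k_min: int = 2
    k_max: int = 5
    n_iter: int = 500
    subsample_frac: float = 0.8
    n_panel: int = 69
    delta_threshold: float = 0.15
    continuous_features: tuple[str, ...] = ("age",)
    categorical_features: tuple[str, ...] = ("idh1_like", "gcimp", "recurrent")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            cohort = CohortConfig(**cohort)
        return cls(cohort=cohort, **raw)

    def validate(self) -> None:
        for p in (self.expression_path, self.clinical_path, self.candidates_path,
                  self.validation_expression_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if self.expression_path is not None and self.clinical_path is None:
            raise ValueError("survival stages need a clinical table alongside expression")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return a results bundle and write tables + manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    # --- inputs -----------------------------------------------------------
    if config.expression_path is None:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
        expr, clinical = cohort.expression, cohort.clinical
        candidates = list(cohort.truth_panel)
        truth = cohort.truth_labels
    else:
        expr = aio.read_expression(config.expression_path)
        clinical = aio.read_clinical(config.clinical_path)
        candidates = aio.read_gene_list(config.candidates_path)
        truth = None

    # --- preprocessing ----------------------------------------------------
    centered = median_center(expr)
    panel = select_panel(centered, candidates, n_keep=min(config.n_panel, len(candidates)))
    panel_m = subset_to_panel(centered, panel)

    # --- consensus discovery ---------------------------------------------
    params = ConsensusParams(
        n_iter=config.n_iter, subsample_frac=config.subsample_frac, seed=config.seed
    )
    results = [
        build_consensus(panel_m, k, params)
        for k in range(config.k_min, config.k_max + 1)
    ]
    cdf = consensus_cdf_summary(results, delta_threshold=config.delta_threshold)
    save(cdf, "cdf_summary.tsv")
    chosen_k = int(cdf.attrs["suggested_k"])
    chosen = next(r for r in results if r.k == chosen_k)

    kept, dropped = silhouette_filter(chosen)
    labels = chosen.labels.loc[kept]
    save(
        pd.DataFrame({
            "sample_id": list(chosen.sample_ids),
            "label": chosen.labels.values,
            "silhouette": chosen.silhouette.values,
            "kept": [s in set(kept) for s in chosen.sample_ids],
        }),
        "labels.tsv",
    )

    scan = survival_k_scan(results, clinical)
    save(scan, "survival_k_scan.tsv")

    # --- boundary model and optional validation ---------------------------
    model = fit_boundaries(labels, subset_to_panel(centered, panel))
    save(
        pd.DataFrame({
            "cluster": model.labels,
            "lower_boundary": [model.boundaries[c] for c in model.labels],
            "n_members": [model.members[c].shape[1] for c in model.labels],
        }),
        "boundaries.tsv",
    )
    assignment_summary = None
    if config.validation_expression_path is not None:
        vexpr = median_center(aio.read_expression(config.validation_expression_path))
        vpanel = subset_to_panel(vexpr, panel)
        _, assignment_summary = assign_cohort(vpanel, model)
        save(assignment_summary, "validation_assignment.tsv")

    # --- characterization -------------------------------------------------
    surv = one_vs_rest_survival(labels, clinical)
    save(surv, "survival_one_vs_rest.tsv")

    clin_idx = clinical.set_index("sample_id")
    feats = []
    n_hyp = len(labels.unique()) * (
        len(config.continuous_features) + len(config.categorical_features)
    )
    for target in sorted(labels.unique()):
        for feat in config.continuous_features:
            if feat not in clin_idx.columns:
                continue
            r = f_test_one_vs_rest(
                clin_idx.loc[labels.index, feat], labels, target,
                feature=feat, n_hypotheses=n_hyp,
            )
            feats.append({"feature": feat, "subgroup": target, "kind": "F",
                          "statistic": r.statistic, "p": r.p,
                          "p_bonferroni": r.p_bonferroni, "direction": r.direction})
        for feat in config.categorical_features:
            if feat not in clin_idx.columns:
                continue
            r = lr_test_categorical(
                clin_idx.loc[labels.index, feat], labels, target,
                feature=feat, n_hypotheses=n_hyp,
            )
            feats.append({"feature": feat, "subgroup": target, "kind": "G",
                          "statistic": r.statistic, "p": r.p,
                          "p_bonferroni": r.p_bonferroni, "direction": r.direction})
    save(pd.DataFrame(feats), "feature_enrichment.tsv")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "k_range": [config.k_min, config.k_max],
        "n_iter": config.n_iter,
        "chosen_k": chosen_k,
        "n_kept": len(kept),
        "n_dropped": len(dropped),
        "files": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    bundle = {
        "panel": panel,
        "results": results,
        "cdf": cdf,
        "chosen_k": chosen_k,
        "labels": labels,
        "dropped": dropped,
        "model": model,
        "survival": surv,
        "features": pd.DataFrame(feats),
        "k_scan": scan,
        "manifest": manifest,
    }
    if truth is not None:
        bundle["truth_labels"] = truth
    if assignment_summary is not None:
        bundle["assignment_summary"] = assignment_summary
    return bundle
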