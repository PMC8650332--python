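"""Pipeline configuration and end-to-end orchestration.

One :class:`PipelineConfig` (YAML-serializable) drives the whole analysis:
simulate a cohort, preprocess and match it, run the nested cross-validation
for the CNN and the linear-SVM baseline, compare them with McNemar's test,
train a final model, check it on the functional-gait-only cohorts, compute
relevance maps and group attributions, and write every artifact plus a
manifest. One master seed fans out to per-stage seeds through a fixed
counter scheme (stage index appended to the seed sequence), so stages are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, lrp, preprocessing, synthetic
from .model import DEFAULT_SPACE, GaitCycleCNN, Hyperparameters, LinearSVMBaseline

log = logging.getLogger("prefog")

# stage indices of the master-seed fan-out
STAGE_SEEDS = {"simulate": 1, "match": 2, "cv": 3, "final_fit": 4, "attribution": 5}


def stage_seed(master: int, stage: str) -> int:
    """Derive a stage seed from the master seed (documented counter scheme)."""
    ss = np.random.SeedSequence([int(master), STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    sampling_rate: float = 100.0
    filter_cutoff: float = 7.0
    filter_order: int = 4
    n_samples: int = 101
    space: dict = field(default_factory=lambda: dict(DEFAULT_SPACE))
    budget: int = 4
    base_hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)
    epsilon: float = lrp.DEFAULT_EPSILON
    attribution_per_subject: int = 3
    output_dir: str = "prefog_output"
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            c = dict(self.cohort)
            if "duration_range" in c:
                c["duration_range"] = tuple(c["duration_range"])
            self.cohort = synthetic.CohortConfig(**c)
        if isinstance(self.base_hyperparameters, dict):
            self.base_hyperparameters = Hyperparameters(**self.base_hyperparameters)
        self.space = {k: (v[0], *[tuple(x) if isinstance(x, list) else x for x in v[1:]])
                      if isinstance(v, (list, tuple)) else v
                      for k, v in self.space.items()}
        self.cohort = dataclasses.replace(self.cohort, seed=self.cohort.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["duration_range"] = list(self.cohort.duration_range)
        d["space"] = {k: [v[0]] + [list(x) if isinstance(x, tuple) else x for x in v[1:]]
                      for k, v in self.space.items()}
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
        data["space"] = {
            k: tuple([v[0]] + [tuple(x) if isinstance(x, list) else x for x in v[1:]])
            for k, v in data.get("space", {}).items()
        }
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def cmd_simulate(config: PipelineConfig, out_dir=None):
    """Generate the synthetic cohort and write CSV + roster JSON."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=stage_seed(config.seed, "simulate")
    )
    cohort = synthetic.generate_cohort(cohort_cfg)
    csv_path = out / "cohort.csv"
    roster_path = out / "roster.json"
    synthetic.write_cohort(cohort, csv_path, roster_path)
    log.info("wrote %s (%d cycles) and %s", csv_path, len(cohort.cycles), roster_path)
    return cohort, {"cohort_csv": str(csv_path), "roster_json": str(roster_path)}


def preprocess_and_match(cohort: synthetic.Cohort, config: PipelineConfig):
    """Preprocess every cycle and assemble the matched freezer dataset.

    Returns ``(matched, eval_cycles, extra)`` where ``matched`` is the
    MatchedDataset over the freezer group (pre-FOG plus its FGC pool),
    ``eval_cycles`` is the balanced per-subject evaluation set (each pre-FOG
    cycle plus its same-subject matched FGC), and ``extra`` maps the
    non-freezer / control groups to their preprocessed FGC cycles.
    """
    processed = {c.cycle_id: preprocessing.preprocess_cycle(c) for c in cohort.cycles}
    freezer_subjects = set(cohort.subjects_in_group("freezer"))
    nolab_subjects = set(cohort.subjects_in_group("nolab_freezer"))
    prefog = [processed[c.cycle_id] for c in cohort.cycles
              if c.label == synthetic.CLASS_PREFOG]
    fgc_pool = [processed[c.cycle_id] for c in cohort.cycles
                if c.label == synthetic.CLASS_FGC
                and c.subject_id in freezer_subjects | nolab_subjects]
    matched = preprocessing.match_and_balance(
        prefog, fgc_pool, cohort.roster, seed=stage_seed(config.seed, "match")
    )
    eval_ids = {t.prefog_id for t in matched.triples}
    eval_ids |= {t.same_subject_fgc_id for t in matched.triples
                 if t.same_subject_fgc_id is not None}
    eval_cycles = [matched.cycle(i) for i in sorted(eval_ids)]
    extra = {
        group: [processed[c.cycle_id] for c in cohort.cycles
                if c.subject_id in set(cohort.subjects_in_group(group))]
        for group in ("nonfreezer", "control")
    }
    return matched, eval_cycles, extra


def cmd_run(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full pipeline; returns the manifest dict (also written to disk)."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_digest": config.digest(), "stages": {}, "outputs": {}}
    manifest_path = out / "manifest.json"

    def checkpoint(stage, **outputs):
        manifest["stages"][stage] = "done"
        manifest["outputs"].update({k: str(v) for k, v in outputs.items()})
        manifest_path.write_text(json.dumps(manifest, indent=2))

    config.to_yaml(out / "config.yaml")
    cohort, files = cmd_simulate(config, out)
    checkpoint("simulate", **files)

    matched, eval_cycles, extra = preprocess_and_match(cohort, config)
    matched.write_manifest(out / "matched.json")
    checkpoint("match", matched_json=out / "matched.json")

    X, y, subjects = preprocessing.dataset_arrays(eval_cycles)
    cv_seed = stage_seed(config.seed, "cv")
    cv_cnn = evaluation.nested_loso_cv(
        X, y, subjects, space=config.space, budget=config.budget, seed=cv_seed,
        base=config.base_hyperparameters, estimator="cnn",
    )
    cv_svm = evaluation.nested_loso_cv(
        X, y, subjects, seed=cv_seed, estimator="svm",
    )
    mcnemar = evaluation.mcnemar_test(
        cv_cnn.predictions["pred"], cv_svm.predictions["pred"],
        cv_cnn.predictions["truth"],
    )
    cv_cnn.per_subject_table().to_csv(out / "per_subject_cnn.csv", index=False)
    cv_svm.per_subject_table().to_csv(out / "per_subject_svm.csv", index=False)
    checkpoint("cv", per_subject_cnn=out / "per_subject_cnn.csv",
               per_subject_svm=out / "per_subject_svm.csv")

    # final model on the full matched training set (all cycles, incl. unmatched FGC)
    Xf, yf, _ = preprocessing.dataset_arrays(matched.cycles)
    final_h = dataclasses.replace(
        config.base_hyperparameters, seed=stage_seed(config.seed, "final_fit")
    )
    final = GaitCycleCNN(Xf, yf, hyperparameters=final_h).fit()
    final.network.save(out / "model.json")
    final.history.to_csv(out / "history.csv", index=False)
    checkpoint("final_fit", model_json=out / "model.json", history_csv=out / "history.csv")

    cross = {
        group: evaluation.cross_cohort_evaluate(final, cycles).rounded()
        for group, cycles in extra.items() if cycles
    }

    # attribution over matched pairs only
    att_cycles = [c for c in matched.matched_cycles()]
    maps = [final.relevance(c, "pre-FOG", config.epsilon) for c in att_cycles]
    for m, c in zip(maps, att_cycles):
        m.cycle_id = c.cycle_id
    lrp.relevance_to_frame(maps, att_cycles).to_csv(out / "relevance.csv", index=False)
    att_seed = stage_seed(config.seed, "attribution")
    groups = []
    for label, name in ((synthetic.CLASS_PREFOG, "pre-FOG"), (synthetic.CLASS_FGC, "FGC")):
        sel = [(m, c) for m, c in zip(maps, att_cycles) if c.label == label]
        if sel:
            groups.append(lrp.aggregate_group_relevance(
                [m for m, _ in sel], [c for _, c in sel], name=name,
                per_subject=config.attribution_per_subject, seed=att_seed,
            ))
    lrp.plot_group_attribution(groups, out / "attribution.png")
    checkpoint("attribution", relevance_csv=out / "relevance.csv",
               attribution_png=out / "attribution.png")

    mean_cnn, sd_cnn = cv_cnn.macro_accuracy()
    mean_svm, sd_svm = cv_svm.macro_accuracy()
    report = {
        "cnn": {"macro_accuracy": round(mean_cnn, 1), "macro_sd": round(sd_cnn, 1),
                "metrics": cv_cnn.overall_metrics().rounded(),
                "per_subject": {k: round(v, 1)
                                for k, v in cv_cnn.per_subject_accuracy.items()}},
        "svm": {"macro_accuracy": round(mean_svm, 1), "macro_sd": round(sd_svm, 1),
                "metrics": cv_svm.overall_metrics().rounded()},
        "mcnemar_cnn_vs_svm": mcnemar,
        "cross_cohort": cross,
        "n_matched_triples": len(matched.triples),
        "n_unmatched_fgc": len(matched.unmatched_fgc_ids),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    checkpoint("report", report_json=out / "report.json")
    return manifest
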