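"""End-to-end orchestration of the two-step self-regulation analysis.

Stages: simulate a cohort -> invert the step-1 model space on every
subject -> family-level RFX-BMS (driving-input families) -> fix the
winning architecture -> invert the step-2 modulation space -> family
RFX-BMS -> Bayesian model averaging (including a fully-modulated model
for the parameter-level contrast) -> learner vs non-learner t-tests ->
Wasserstein learning ranking.

Every stage consumes the run seed deterministically and writes its
outputs (JSON/TSV) plus a manifest with content hashes, so re-running an
identical configuration reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nfio
from .bms import bma_cohort, family_inference
from .group_inference import compare_groups
from .inversion import InversionConfig, log_evidence_matrix
from .learning_ranking import rank_cohort
from .model_space import (
    FamilyPartition,
    build_first_step_space,
    build_second_step_space,
    full_modulation_spec,
    winning_architecture,
)
from .synthetic_cohort import sample_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_all"]


@dataclass
class PipelineConfig:
    """Fully serializable configuration of one pipeline run.

    Defaults describe a small desk-scale demonstration (4 subjects, 2
    runs, 2 models per step-1 family); the full protocol is obtained
    with ``n_learners=9, n_non_learners=9, n_training_runs=8,
    step1_per_family=None``.
    """

    seed: int = 0
    n_learners: int = 2
    n_non_learners: int = 2
    n_training_runs: int = 2
    block_duration_s: float = 30.0
    snr: float = 1.0
    step1_per_family: int | None = 2  # None = all 7 variants per family
    step2_reduced: bool = False
    max_iter: int = 128
    include_hemo: bool = False
    bms_alpha0: float = 1.0
    bms_samples: int = 1_000_000
    group_alpha: float = 0.05
    ranking_rule: str = "sign"
    outdir: str = "nfdcm_out"

    def content_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Per-stage record of outputs, hashes, timing and seeds."""

    config_hash: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, seed: int | None = None, **outputs: str) -> None:
        entry = {"stage": name, "seed": seed, "time": time.time(), "outputs": {}}
        for key, path in outputs.items():
            p = Path(path)
            entry["outputs"][key] = {
                "path": str(path),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None,
            }
        self.stages.append(entry)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"config_hash": self.config_hash, "stages": self.stages}, indent=1)
        )


def _reduced_step1(per_family: int | None):
    specs, partition = build_first_step_space()
    if per_family is None:
        return specs, partition
    keep: list[int] = []
    fam_map: dict[str, list[int]] = {}
    for fam, members in partition.families.items():
        # keep the last `per_family` variants of each family (they include
        # the bilateral architectures, among them the generating one)
        chosen = members[-per_family:]
        fam_map[fam] = list(range(len(keep), len(keep) + len(chosen)))
        keep.extend(chosen)
    return [specs[i] for i in keep], FamilyPartition(families=fam_map, level="first_step")


class StageError(RuntimeError):
    def __init__(self, stage: str, artifact: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed (artifact: {artifact}): {cause}")
        self.stage = stage


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest of stage outputs."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=1))
    manifest = RunManifest(config_hash=config.content_hash())
    rng = np.random.default_rng(config.seed)
    inv_cfg = InversionConfig(max_iter=config.max_iter, include_hemo=config.include_hemo)

    # --- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        cohort = sample_cohort(
            n_learners=config.n_learners,
            n_non_learners=config.n_non_learners,
            seed=config.seed,
            n_training_runs=config.n_training_runs,
            block_duration_s=config.block_duration_s,
            snr=config.snr,
        )
        nfio.write_cohort(cohort, out / "cohort")
        manifest.add(stage, seed=config.seed, manifest=str(out / "cohort" / "cohort_manifest.json"))
    except Exception as exc:
        raise StageError(stage, str(out / "cohort"), exc) from exc

    # --- step-1 space + inversion + family BMS --------------------------
    stage = "step1"
    try:
        specs1, part1 = _reduced_step1(config.step1_per_family)
        from .model_space import write_space

        write_space(out / "space_step1.json", specs1, part1)
        lev1 = log_evidence_matrix(cohort, specs1, inv_cfg)
        nfio.write_logev(lev1, out / "logev_step1.tsv")
        bms1 = family_inference(
            lev1.to_numpy(), part1, alpha0=config.bms_alpha0,
            n_samples=config.bms_samples, seed=int(rng.integers(2**31 - 1)),
        )
        (out / "bms_step1.json").write_text(json.dumps(bms1.to_dict(), indent=1))
        manifest.add(stage, logev=str(out / "logev_step1.tsv"), bms=str(out / "bms_step1.json"))
    except Exception as exc:
        raise StageError(stage, str(out / "logev_step1.tsv"), exc) from exc

    # --- step-2 space + inversion + family BMS --------------------------
    stage = "step2"
    try:
        base = winning_architecture()
        specs2, part2 = build_second_step_space(base)
        if config.step2_reduced:
            keep = [members[0] for members in part2.families.values()]
            fam_map = {f: [i] for i, f in enumerate(part2.families)}
            specs2 = [specs2[i] for i in keep]
            part2 = FamilyPartition(families=fam_map, level="second_step")
        full_spec = full_modulation_spec(base)
        specs2_all = specs2 + [full_spec]
        from .model_space import write_space

        write_space(out / "space_step2.json", specs2, part2)
        lev2_all = log_evidence_matrix(cohort, specs2_all, inv_cfg)
        lev2 = lev2_all[[s.name for s in specs2]]
        nfio.write_logev(lev2_all, out / "logev_step2.tsv")
        bms2 = family_inference(
            lev2.to_numpy(), part2, alpha0=config.bms_alpha0,
            n_samples=config.bms_samples, seed=int(rng.integers(2**31 - 1)),
        )
        (out / "bms_step2.json").write_text(json.dumps(bms2.to_dict(), indent=1))
        manifest.add(stage, logev=str(out / "logev_step2.tsv"), bms=str(out / "bms_step2.json"))
    except Exception as exc:
        raise StageError(stage, str(out / "logev_step2.tsv"), exc) from exc

    # --- BMA + group comparison -----------------------------------------
    stage = "group"
    try:
        results = lev2_all.attrs["results"]
        # parameter-level contrast on the fully modulated model's BMA
        # (scope = that single model), per the group-analysis convention
        full_idx = [len(specs2_all) - 1]
        bma_res = bma_cohort(results, lev2_all, [s.name for s in specs2_all], scope=full_idx)
        bma_table = bma_res.table()
        bma_table.to_csv(out / "bma_parameters.tsv", sep="\t", index_label="subject")
        comparison = compare_groups(bma_table, cohort.labels(), alpha=config.group_alpha)
        comparison.table.to_csv(out / "group_comparison.tsv", sep="\t", index=False)
        (out / "group_comparison.json").write_text(json.dumps(comparison.to_dict(), indent=1))
        manifest.add(stage, table=str(out / "group_comparison.tsv"))
    except Exception as exc:
        raise StageError(stage, str(out / "group_comparison.tsv"), exc) from exc

    # --- Wasserstein learning ranking -----------------------------------
    stage = "ranking"
    try:
        records = rank_cohort(
            cohort.baseline_runs, cohort.transfer_runs, rule=config.ranking_rule
        )
        rank_df = pd.DataFrame(
            [
                {
                    "subject": r.subject_id,
                    "wd": r.wd,
                    "signed_wd": r.signed_wd,
                    "rank": r.rank,
                    "label": r.label,
                    "true_group": cohort.labels()[r.subject_id],
                }
                for r in records
            ]
        )
        rank_df.to_csv(out / "learning_ranking.tsv", sep="\t", index=False)
        manifest.add(stage, ranking=str(out / "learning_ranking.tsv"))
    except Exception as exc:
        raise StageError(stage, str(out / "learning_ranking.tsv"), exc) from exc

    manifest.write(out / "manifest.json")
    return manifest
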