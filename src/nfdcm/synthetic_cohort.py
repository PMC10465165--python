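"""Synthetic neurofeedback cohorts with known ground truth.

Emulates the training protocol of the neurofeedback study the package
models: each subject completes 8 training runs (2 sessions x 4 runs), each
alternating 4 baseline (rest) and 3 up-regulation blocks, plus a transfer
run (self-regulation without visual feedback).  The cohort splits into 9
learners and 9 non-learners; learners carry a stronger up-regulation
modulation of the F->SMA connection (default population means 0.4 vs 0.0
1/s, SD 0.1, truncated to the stability region).

What the generator emulates and what it does not: block timing, the
learner/non-learner effect on F->SMA, i.i.d. Gaussian observation noise
and optional slow cosine drift.  It does not simulate the closed feedback
loop, reward magnitudes, habituation or physiological noise.

For the learning-ranking contrast each subject additionally gets a
*baseline-reference* run — the pre-training response, i.e. the same
feedback-driven design with the learned modulation switched off — while
the transfer run is driven by the subject's volitional engagement of the
up-regulation blocks (full engagement for learners, none for non-learners,
so non-learners lose the feedback-driven target activity after training,
mirroring the down-regulation the study observed in its non-learners).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .generative_model import (
    DCMParameters,
    DEFAULT_TR,
    DEFAULT_BINS_PER_TR,
    InputSet,
    RoiTimeSeries,
    SELF_INHIBITION,
    integrate_dcm,
)
from .model_space import ModelSpec, full_modulation_spec, winning_architecture
from .regions import F, SMA

__all__ = [
    "BlockDesign",
    "SubjectProfile",
    "CohortDataset",
    "EffectConfig",
    "make_block_design",
    "design_events",
    "condition_labels",
    "sample_subject_params",
    "simulate_run",
    "sample_cohort",
    "DEFAULT_BLOCK_S",
]

#: Default block duration in seconds (the protocol text does not state it).
DEFAULT_BLOCK_S = 30.0

N_BASELINE_BLOCKS = 4
N_UPREG_BLOCKS = 3


@dataclass(frozen=True)
class BlockDesign:
    """Ordered block list for one run."""

    blocks: tuple[tuple[str, float, float], ...]  # (condition, onset, duration)
    run_type: str  # "training" | "transfer"

    def __post_init__(self) -> None:
        conds = [b[0] for b in self.blocks]
        if conds != ["baseline", "up-regulation"] * (len(conds) // 2) + ["baseline"]:
            raise ValueError("blocks must strictly alternate starting with baseline")
        onsets = [b[1] for b in self.blocks]
        ends = [b[1] + b[2] for b in self.blocks]
        if any(o2 < e1 - 1e-9 for e1, o2 in zip(ends, onsets[1:])):
            raise ValueError("blocks overlap")

    @property
    def total_duration(self) -> float:
        last = self.blocks[-1]
        return last[1] + last[2]

    def n_blocks(self, condition: str) -> int:
        return sum(1 for b in self.blocks if b[0] == condition)


def make_block_design(
    block_duration_s: float = DEFAULT_BLOCK_S, run_type: str = "training"
) -> BlockDesign:
    """4 baseline + 3 up-regulation blocks, strictly alternating from rest.

    Transfer runs use the same alternation but are flagged so that the
    feedback driving input is silenced downstream.
    """
    if block_duration_s <= 0:
        raise ValueError("block duration must be positive")
    if run_type not in ("training", "transfer"):
        raise ValueError(f"unknown run_type {run_type!r}")
    blocks = []
    t = 0.0
    for i in range(N_BASELINE_BLOCKS + N_UPREG_BLOCKS):
        cond = "baseline" if i % 2 == 0 else "up-regulation"
        blocks.append((cond, t, block_duration_s))
        t += block_duration_s
    return BlockDesign(blocks=tuple(blocks), run_type=run_type)


def design_events(design: BlockDesign) -> pd.DataFrame:
    """BIDS-events-style table (onset, duration, trial_type)."""
    return pd.DataFrame(
        [{"onset": o, "duration": d, "trial_type": c} for c, o, d in design.blocks]
    )


def condition_labels(design: BlockDesign, TR: float, n_volumes: int) -> list[str]:
    """Per-volume block condition, by the volume's acquisition end time."""
    labels = []
    for v in range(n_volumes):
        t = (v + 1) * TR  # sample time at end of volume
        lab = design.blocks[-1][0]
        for cond, onset, dur in design.blocks:
            if onset < t <= onset + dur + 1e-9:
                lab = cond
                break
        labels.append(lab)
    return labels


@dataclass
class EffectConfig:
    """Population means / SDs for every free parameter of the cohort model.

    Values are on the 1/s coupling scale.  ``b_learner_mean`` applies to
    the F->SMA modulation entry for learners; all other modulation entries
    share ``b_other_mean``/``b_sd`` in both groups.
    """

    a_mean: float = 0.15
    a_sd: float = 0.05
    b_learner_mean: float = 0.4
    b_nonlearner_mean: float = 0.0
    b_sd: float = 0.1  # SD of the target F->SMA modulation
    b_other_mean: float = 0.0
    b_other_sd: float = 0.05  # idiosyncratic modulation of non-target edges
    c_mean: float = 0.06
    c_sd: float = 0.02
    max_tries: int = 200  # truncation to the stability region


def _stable(params: DCMParameters) -> bool:
    for M in (params.A, params.A + params.B[0]):
        if np.max(np.linalg.eigvals(M).real) >= -1e-6:
            return False
    return True


def sample_subject_params(
    group_label: str,
    seed: int | np.random.Generator,
    effect_config: EffectConfig | None = None,
    spec: ModelSpec | None = None,
) -> DCMParameters:
    """Draw one subject's ground-truth parameters.

    Gaussian draws per free entry, truncated (by redrawing) to the region
    where both A and A+B are stable and every driving gain is positive
    (a subject whose feedback display evokes no response at all has no
    usable data).  With all SDs at zero the draw equals the group means
    exactly.
    """
    if group_label not in ("learner", "non_learner"):
        raise ValueError(f"unknown group label {group_label!r}")
    cfg = effect_config or EffectConfig()
    if spec is None:
        spec = full_modulation_spec(winning_architecture())
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    Rn = spec.n_regions
    off = ~np.eye(Rn, dtype=bool)
    a_free = spec.a_mask & off
    b_free = spec.b_masks[0]
    c_free = spec.c_mask[:, 0]
    b_mean = np.full((Rn, Rn), cfg.b_other_mean)
    b_sd = np.full((Rn, Rn), cfg.b_other_sd)
    if b_free[SMA, F]:
        b_mean[SMA, F] = (
            cfg.b_learner_mean if group_label == "learner" else cfg.b_nonlearner_mean
        )
        b_sd[SMA, F] = cfg.b_sd
    for _ in range(cfg.max_tries):
        A = np.zeros((Rn, Rn))
        A[a_free] = rng.normal(cfg.a_mean, cfg.a_sd, size=int(a_free.sum()))
        np.fill_diagonal(A, SELF_INHIBITION)
        B = np.zeros((Rn, Rn))
        B[b_free] = rng.normal(b_mean[b_free], b_sd[b_free])
        C = np.zeros(Rn)
        C[c_free] = rng.normal(cfg.c_mean, cfg.c_sd, size=int(c_free.sum()))
        if cfg.c_sd > 0 and np.any(C[c_free] <= max(0.0, cfg.c_mean - 2 * cfg.c_sd)):
            continue  # truncate non-responsive drive gains
        params = DCMParameters(A=A, B=B[None], C=C[:, None])
        if _stable(params):
            return params
    raise RuntimeError("could not draw stable parameters; check effect_config")


def _signal_sd(data: np.ndarray) -> float:
    """Temporal SD of a clean response, pooled over regions."""
    centered = data - data.mean(axis=1, keepdims=True)
    return float(np.sqrt(np.mean(centered**2)))


def _design_inputs(
    design: BlockDesign,
    TR: float,
    bins_per_tr: int,
    drive_on: bool,
) -> InputSet:
    ev = design_events(design)
    return InputSet.from_events(
        ev,
        TR=TR,
        bins_per_tr=bins_per_tr,
        drive_conditions="sustained" if drive_on else (),
    )


def simulate_run(
    profile: "SubjectProfile",
    design: BlockDesign,
    noise_sd: float | None = None,
    drift_config: dict | None = None,
    seed: int | np.random.Generator = 0,
    TR: float = DEFAULT_TR,
    bins_per_tr: int = DEFAULT_BINS_PER_TR,
    run_id: str = "run-01",
    snr: float = 1.0,
    modulation_on: bool = True,
    engagement: float | None = None,
) -> RoiTimeSeries:
    """One run: deterministic DCM output + observation noise (+ drift).

    noise_sd
        Absolute noise SD in percent-signal units.  When None, the SD is
        set so that the temporal SD of this subject's noise-free
        *training* response (pooled over regions, per-region mean
        removed) over the noise SD equals ``snr`` — the usual definition
        of simulation SNR in the DCM literature; default SNR 1.
    modulation_on
        Switched off for the baseline-reference (pre-training) run.
    engagement
        Drive scaling for transfer runs (volitional self-regulation in the
        absence of feedback); defaults to 1 for learners, 0 otherwise.
    """
    if noise_sd is not None and noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    params = profile.true_params
    if not modulation_on:
        params = replace(params, B=np.zeros_like(params.B))
    transfer = design.run_type == "transfer"
    inputs = _design_inputs(design, TR, bins_per_tr, drive_on=not transfer)
    if transfer:
        if engagement is None:
            engagement = 1.0 if profile.group_label == "learner" else 0.0
        # volitional drive: sustained self-initiated regulation replacing
        # the absent feedback display, scaled by the subject's engagement
        inputs = InputSet(
            times=inputs.times,
            u_drive=np.ones_like(inputs.u_mod),
            u_mod=inputs.u_mod,
            TR=TR,
            n_volumes=inputs.n_volumes,
        )
        params = replace(params, C=params.C * engagement)
    labels = condition_labels(design, TR, inputs.n_volumes)
    clean = integrate_dcm(None, params, inputs, run_id=run_id, condition_labels=labels)
    if noise_sd is None:
        ref_inputs = _design_inputs(design, TR, bins_per_tr, drive_on=True)
        ref = integrate_dcm(None, profile.true_params, ref_inputs)
        noise_sd = _signal_sd(ref.data) / snr
    data = clean.data + rng.normal(0.0, noise_sd, size=clean.data.shape)
    if drift_config:
        n_cos = int(drift_config.get("order", 0))
        amp = float(drift_config.get("amplitude", 0.0))
        t = np.arange(clean.n_volumes) / clean.n_volumes
        for k in range(1, n_cos + 1):
            phase = rng.uniform(0, 2 * np.pi, size=(clean.data.shape[0], 1))
            data = data + amp * np.cos(np.pi * k * t[None, :] + phase)
    return RoiTimeSeries(
        data=data,
        TR=TR,
        run_id=run_id,
        condition_labels=labels,
        stable=clean.stable,
    )


@dataclass
class SubjectProfile:
    """Ground-truth description of one simulated subject."""

    subject_id: str
    group_label: str  # "learner" | "non_learner"
    true_params: DCMParameters
    training_group: str = "F"  # annotation only: F | F+I | F+R | F+I+R


@dataclass
class CohortDataset:
    """Complete simulated cohort with ground truth retained."""

    subjects: list[SubjectProfile]
    training_runs: dict[str, list[RoiTimeSeries]]
    baseline_runs: dict[str, RoiTimeSeries]
    transfer_runs: dict[str, RoiTimeSeries]
    design: BlockDesign
    seed: int
    noise_sd: dict[str, float] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def labels(self) -> dict[str, str]:
        return {s.subject_id: s.group_label for s in self.subjects}

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "block_duration_s": self.design.blocks[0][2],
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "group_label": s.group_label,
                    "training_group": s.training_group,
                    "noise_sd": self.noise_sd.get(s.subject_id),
                    "true_A": s.true_params.A.tolist(),
                    "true_B": s.true_params.B[0].tolist(),
                    "true_C": s.true_params.C[:, 0].tolist(),
                }
                for s in self.subjects
            ],
        }


_TRAINING_GROUPS = ("F", "F+I", "F+R", "F+I+R")


def sample_cohort(
    n_learners: int = 9,
    n_non_learners: int = 9,
    seed: int = 0,
    effect_config: EffectConfig | None = None,
    spec: ModelSpec | None = None,
    n_training_runs: int = 8,
    block_duration_s: float = DEFAULT_BLOCK_S,
    TR: float = DEFAULT_TR,
    bins_per_tr: int = DEFAULT_BINS_PER_TR,
    snr: float = 1.0,
    noise_sd: float | None = None,
    drift_config: dict | None = None,
) -> CohortDataset:
    """Simulate a full cohort (default 9 learners + 9 non-learners).

    Each subject receives ``n_training_runs`` feedback runs (default 8,
    i.e. 2 sessions x 4 runs), one baseline-reference run and one transfer
    run.  Identical (seed, config) yields a bit-identical dataset.
    """
    if n_learners < 1 or n_non_learners < 1:
        raise ValueError("need at least one subject per group")
    rng = np.random.default_rng(seed)
    design = make_block_design(block_duration_s, "training")
    transfer_design = make_block_design(block_duration_s, "transfer")
    subjects: list[SubjectProfile] = []
    training_runs: dict[str, list[RoiTimeSeries]] = {}
    baseline_runs: dict[str, RoiTimeSeries] = {}
    transfer_runs: dict[str, RoiTimeSeries] = {}
    noise_used: dict[str, float] = {}
    groups = ["learner"] * n_learners + ["non_learner"] * n_non_learners
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:02d}"
        params = sample_subject_params(group, rng, effect_config, spec)
        profile = SubjectProfile(
            subject_id=sid,
            group_label=group,
            true_params=params,
            training_group=_TRAINING_GROUPS[i % len(_TRAINING_GROUPS)],
        )
        subjects.append(profile)
        if noise_sd is None:
            ref_inputs = _design_inputs(design, TR, bins_per_tr, drive_on=True)
            ref = integrate_dcm(None, params, ref_inputs)
            sd = _signal_sd(ref.data) / snr
        else:
            sd = noise_sd
        noise_used[sid] = sd
        training_runs[sid] = [
            simulate_run(
                profile,
                design,
                noise_sd=sd,
                drift_config=drift_config,
                seed=rng,
                TR=TR,
                bins_per_tr=bins_per_tr,
                run_id=f"{sid}_task-training_run-{r + 1:02d}",
            )
            for r in range(n_training_runs)
        ]
        baseline_runs[sid] = simulate_run(
            profile,
            design,
            noise_sd=sd,
            drift_config=drift_config,
            seed=rng,
            TR=TR,
            bins_per_tr=bins_per_tr,
            run_id=f"{sid}_task-baselineref",
            modulation_on=False,
        )
        transfer_runs[sid] = simulate_run(
            profile,
            transfer_design,
            noise_sd=sd,
            drift_config=drift_config,
            seed=rng,
            TR=TR,
            bins_per_tr=bins_per_tr,
            run_id=f"{sid}_task-transfer",
        )
    return CohortDataset(
        subjects=subjects,
        training_runs=training_runs,
        baseline_runs=baseline_runs,
        transfer_runs=transfer_runs,
        design=design,
        seed=seed if isinstance(seed, int) else -1,
        noise_sd=noise_used,
    )
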