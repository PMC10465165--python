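"""Candidate network hypotheses for the two-step family-level inference.

Step 1 asks where the visual feedback enters the network (driving input at
the frontal node — the "top-down" hypothesis — or at the striatum, the
"bottom-up" hypothesis) and which baseline coupling architecture along the
F–ACC–S axis and towards the SMA target best explains the data: 7 coupling
variants x 2 input locations = 14 models in 2 families.

Step 2 fixes the winning architecture and asks which connections the
up-regulation condition modulates, grouped by the origin of the modulation:
3 frontal-origin, 5 ACC-origin and 5 striatal-origin variants = 13 models
in 3 families.  Striatal-origin variants may recruit the ACC relay edge
(S -> ACC -> SMA) because the striatum reaches the target only directly or
through that relay.

The published figures show the exact masks only graphically, so the
enumeration here is a documented canonical one honouring every textual
constraint (axis directionality variants, node-to-target links, exactly one
direct S–F bypass variant; family sizes 3/5/5 by origin node).  The masks
are exposed via :func:`space_manifest` so alternative enumerations can be
substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .regions import ACC, F, REGION_LABELS, S, SMA

__all__ = [
    "ModelSpec",
    "FamilyPartition",
    "build_first_step_space",
    "build_second_step_space",
    "winning_architecture",
    "full_modulation_spec",
    "validate_spec",
    "space_manifest",
    "write_space",
    "read_space",
]

_R = len(REGION_LABELS)


@dataclass(frozen=True)
class ModelSpec:
    """Boolean structure masks defining one candidate model.

    ``a_mask`` marks the free off-diagonal coupling entries (the diagonal
    self-inhibitions are always present but fixed, never estimated);
    ``b_masks`` has one region-by-region layer per modulatory input and may
    only switch on entries that exist in ``a_mask``; ``c_mask`` marks which
    region receives each driving input.
    """

    name: str
    a_mask: np.ndarray
    b_masks: np.ndarray
    c_mask: np.ndarray
    family_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "a_mask", np.asarray(self.a_mask, dtype=bool))
        bm = np.asarray(self.b_masks, dtype=bool)
        if bm.ndim == 2:
            bm = bm[None]
        object.__setattr__(self, "b_masks", bm)
        cm = np.asarray(self.c_mask, dtype=bool)
        if cm.ndim == 1:
            cm = cm[:, None]
        object.__setattr__(self, "c_mask", cm)

    @property
    def n_regions(self) -> int:
        return self.a_mask.shape[0]

    def free_counts(self) -> dict[str, int]:
        off = ~np.eye(self.n_regions, dtype=bool)
        return {
            "A": int((self.a_mask & off).sum()),
            "B": int(self.b_masks.sum()),
            "C": int(self.c_mask.sum()),
        }


@dataclass(frozen=True)
class FamilyPartition:
    """Disjoint, exhaustive grouping of model indices into families."""

    families: dict[str, list[int]]
    level: str  # "first_step" | "second_step"
    n_models: int = field(default=0)

    def __post_init__(self) -> None:
        idx = sorted(i for members in self.families.values() for i in members)
        n = self.n_models or (max(idx) + 1 if idx else 0)
        object.__setattr__(self, "n_models", n)
        if idx != list(range(n)):
            raise ValueError("families must be disjoint and cover all models")

    def family_of(self, model_index: int) -> str:
        for fam, members in self.families.items():
            if model_index in members:
                return fam
        raise KeyError(model_index)

    def sizes(self) -> dict[str, int]:
        return {fam: len(m) for fam, m in self.families.items()}


def _mask(edges: list[tuple[int, int]]) -> np.ndarray:
    m = np.zeros((_R, _R), dtype=bool)
    for tgt, src in edges:
        m[tgt, src] = True
    return m


def _bilateral(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for a, b in pairs:
        out.extend([(a, b), (b, a)])
    return out


# Edge notation below: (target, source), matching matrix convention
# A[target, source].

# The seven baseline-coupling (Ae) variants.  Variants 1-3 vary the axis
# directionality with forward node->SMA links; 4-6 repeat them with
# bilateral node<->SMA links; variant 7 is the direct S-F bypass (no
# S-ACC mediation).
_TO_SMA = [(SMA, F), (SMA, ACC), (SMA, S)]
_AE_VARIANTS: list[tuple[str, list[tuple[int, int]]]] = [
    ("axis-down_sma-in", [(ACC, F), (S, ACC)] + _TO_SMA),
    ("axis-up_sma-in", [(ACC, S), (F, ACC)] + _TO_SMA),
    ("axis-bi_sma-in", _bilateral([(F, ACC), (ACC, S)]) + _TO_SMA),
    ("axis-down_sma-bi", [(ACC, F), (S, ACC)] + _bilateral([(SMA, F), (SMA, ACC), (SMA, S)])),
    ("axis-up_sma-bi", [(ACC, S), (F, ACC)] + _bilateral([(SMA, F), (SMA, ACC), (SMA, S)])),
    ("axis-bi_sma-bi", _bilateral([(F, ACC), (ACC, S), (SMA, F), (SMA, ACC), (SMA, S)])),
    ("sf-direct_sma-bi", _bilateral([(F, S), (SMA, F), (SMA, ACC), (SMA, S)])),
]

_ZERO_B = np.zeros((1, _R, _R), dtype=bool)


def _c_at(region: int) -> np.ndarray:
    c = np.zeros((_R, 1), dtype=bool)
    c[region, 0] = True
    return c


def build_first_step_space() -> tuple[list[ModelSpec], FamilyPartition]:
    """The 14-model step-1 space: 7 Ae variants x 2 driving-input families."""
    specs: list[ModelSpec] = []
    families: dict[str, list[int]] = {"top-down": [], "bottom-up": []}
    for fam, region, tag in (("top-down", F, "cF"), ("bottom-up", S, "cS")):
        for ae_name, edges in _AE_VARIANTS:
            families[fam].append(len(specs))
            specs.append(
                ModelSpec(
                    name=f"{tag}_{ae_name}",
                    a_mask=_mask(edges),
                    b_masks=_ZERO_B,
                    c_mask=_c_at(region),
                    family_id=fam,
                )
            )
    return specs, FamilyPartition(families=families, level="first_step")


def winning_architecture() -> ModelSpec:
    """The step-1 winner: bilateral F-ACC-S axis, bilateral node<->SMA
    links, feedback driving the frontal node."""
    name, edges = _AE_VARIANTS[5]
    assert name == "axis-bi_sma-bi"
    return ModelSpec(
        name="winning_cF_axis-bi_sma-bi",
        a_mask=_mask(edges),
        b_masks=_ZERO_B,
        c_mask=_c_at(F),
        family_id="top-down",
    )


def _b_subsets(base: ModelSpec, source: int) -> list[list[tuple[int, int]]]:
    """Documented modulation subsets for one origin node.

    Frontal: the 3 non-empty subsets of F's outgoing edges (F->ACC,
    F->SMA).  ACC: 5 subsets of ACC's three outgoing edges (each single
    edge, the two axis edges together, all three).  Striatal: 5 variants
    over the S-origin pathway {S->ACC, S->SMA, ACC->SMA} — each direct
    edge alone, both direct edges, the relayed route S->ACC->SMA, and the
    full pathway — because the striatum reaches the target directly or
    via the ACC relay only.
    """
    out_edges = [(tgt, source) for tgt in range(_R) if base.a_mask[tgt, source]]
    if not out_edges:
        raise ValueError(
            f"base architecture has no outgoing connection from "
            f"{REGION_LABELS[source]} to modulate"
        )
    if source == ACC:
        singles = [[e] for e in out_edges]
        axis = [e for e in out_edges if e[0] != SMA]
        return singles + [axis, out_edges]
    if source == S:
        if not (base.a_mask[ACC, S] and base.a_mask[SMA, S] and base.a_mask[SMA, ACC]):
            raise ValueError(
                "base architecture lacks the striatal pathway edges "
                "(S->ACC, S->SMA, ACC->SMA) required by the Striatal family"
            )
        s_acc, s_sma, acc_sma = (ACC, S), (SMA, S), (SMA, ACC)
        return [
            [s_acc],
            [s_sma],
            [s_acc, s_sma],
            [s_acc, acc_sma],
            [s_acc, s_sma, acc_sma],
        ]
    # frontal origin: 2 outgoing edges -> the 3 non-empty subsets
    (e1, e2) = out_edges if len(out_edges) == 2 else (out_edges[0], out_edges[-1])
    return [[e1], [e2], [e1, e2]]


def build_second_step_space(base: ModelSpec) -> tuple[list[ModelSpec], FamilyPartition]:
    """The 13-model step-2 space: modulation variants on the fixed winner.

    Families by modulation origin: Frontal (3), ACC (5), Striatal (5).
    """
    specs: list[ModelSpec] = []
    families: dict[str, list[int]] = {}
    for fam, source in (("Frontal", F), ("ACC", ACC), ("Striatal", S)):
        families[fam] = []
        for i, edges in enumerate(_b_subsets(base, source), start=1):
            families[fam].append(len(specs))
            specs.append(
                ModelSpec(
                    name=f"be_{fam.lower()}_{i}",
                    a_mask=base.a_mask.copy(),
                    b_masks=_mask(edges)[None],
                    c_mask=base.c_mask.copy(),
                    family_id=fam,
                )
            )
    return specs, FamilyPartition(families=families, level="second_step")


def full_modulation_spec(base: ModelSpec) -> ModelSpec:
    """Fully-modulated variant: every baseline connection is modulated.

    Used for the group-comparison Bayesian model average.  Idempotent.
    """
    off = ~np.eye(base.n_regions, dtype=bool)
    return ModelSpec(
        name=base.name.replace("_bfull", "") + "_bfull",
        a_mask=base.a_mask.copy(),
        b_masks=(base.a_mask & off)[None],
        c_mask=base.c_mask.copy(),
        family_id=base.family_id,
    )


def validate_spec(spec: ModelSpec, step: int | None = None) -> list[str]:
    """Check ModelSpec invariants; returns a list of violations (empty = pass)."""
    violations: list[str] = []
    off = ~np.eye(spec.n_regions, dtype=bool)
    for layer in spec.b_masks:
        if np.any(layer & ~(spec.a_mask & off)):
            violations.append("modulation-without-connection")
            break
    for layer in spec.b_masks:
        if np.any(np.diag(layer)):
            violations.append("self-modulation")
            break
    n_inputs = int((spec.c_mask.any(axis=0)).sum())
    if step == 1 and n_inputs != 1:
        violations.append("step1-requires-one-driving-input-column")
    if spec.c_mask.shape[0] != spec.n_regions:
        violations.append("c-mask-shape")
    return violations


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "name": spec.name,
        "family_id": spec.family_id,
        "a_mask": spec.a_mask.astype(int).tolist(),
        "b_masks": spec.b_masks.astype(int).tolist(),
        "c_mask": spec.c_mask.astype(int).tolist(),
    }


def _spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(
        name=d["name"],
        family_id=d.get("family_id", ""),
        a_mask=np.array(d["a_mask"], dtype=bool),
        b_masks=np.array(d["b_masks"], dtype=bool),
        c_mask=np.array(d["c_mask"], dtype=bool),
    )


def space_manifest(
    specs: list[ModelSpec], partition: FamilyPartition
) -> dict:
    """JSON-ready description of a model space (masks as 0/1 matrices)."""
    return {
        "regions": list(REGION_LABELS),
        "level": partition.level,
        "families": {k: list(v) for k, v in partition.families.items()},
        "models": [_spec_to_dict(s) for s in specs],
        "notes": (
            "Masks follow A[target, source] convention; diagonal "
            "self-inhibition is fixed at -0.5 1/s and not part of the masks. "
            "The enumeration is the package's documented canonical choice; "
            "substitute your own masks via read_space()."
        ),
    }


def write_space(path: str | Path, specs: list[ModelSpec], partition: FamilyPartition) -> None:
    Path(path).write_text(json.dumps(space_manifest(specs, partition), indent=1))


def read_space(path: str | Path) -> tuple[list[ModelSpec], FamilyPartition]:
    d = json.loads(Path(path).read_text())
    specs = [_spec_from_dict(m) for m in d["models"]]
    partition = FamilyPartition(families={k: list(v) for k, v in d["families"].items()}, level=d["level"])
    return specs, partition
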