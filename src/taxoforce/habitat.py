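"""Habitat-specific gene calling and KEGG-module completeness.

Two complementary routes identify CDS clusters tied to a habitat:

* **Ordination route** — CDS whose CCA score on a habitat's axis deviates
  from zero by more than a cutoff (default 0.15) in the habitat's direction;
  CDS inside the ±cutoff band on *every* axis are "core-like" (housekeeping
  functions behave this way).
* **Exclusivity route** — CDS present in all genomes of one habitat and in
  none outside it (strict), or in at least one genome of the habitat and
  none outside (relaxed "any" mode, useful when within-habitat diversity is
  high, as for sponge symbionts).

KEGG metabolic modules are called present when at most one component block
lacks any observed ortholog (single-component modules must be observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import HabitatDesign, PresenceAbsenceMatrix

__all__ = [
    "AxisSelectionRule",
    "HabitatCallSet",
    "KeggModuleDef",
    "select_axis_cds",
    "core_like_cds",
    "call_habitat_cds",
    "call_exclusive_cds",
    "assign_habitat_axes",
    "module_completeness",
    "build_table4",
]

DEFAULT_SCORE_CUTOFF = 0.15


@dataclass(frozen=True)
class AxisSelectionRule:
    """Select CDS on one ordination axis: sign-matching scores with
    |score| > cutoff belong to ``habitat``."""

    axis: int  # 0-based
    sign: str  # "positive" | "negative"
    habitat: str
    cutoff: float = DEFAULT_SCORE_CUTOFF

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.sign not in ("positive", "negative"):
            raise ValueError(f"sign must be positive/negative, got {self.sign!r}")


@dataclass
class HabitatCallSet:
    habitat: str
    method: str  # cca_axis | exclusive_strict | exclusive_any
    cds: set[str]
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class KeggModuleDef:
    """A KEGG module: ordered component blocks of interchangeable orthologs."""

    module_id: str
    components: tuple[frozenset[str], ...]

    @classmethod
    def from_lists(cls, module_id: str, components: Sequence[Iterable[str]]) -> "KeggModuleDef":
        return cls(module_id, tuple(frozenset(c) for c in components))


def select_axis_cds(cds_scores: pd.DataFrame, rule: AxisSelectionRule) -> HabitatCallSet:
    """Apply an axis-score selection rule to the CDS score table."""
    if not 0 <= rule.axis < cds_scores.shape[1]:
        raise ValueError(
            f"axis {rule.axis} out of range for {cds_scores.shape[1]} axes"
        )
    scores = cds_scores.iloc[:, rule.axis]
    if rule.sign == "positive":
        selected = scores[scores > rule.cutoff]
    else:
        selected = scores[scores < -rule.cutoff]
    return HabitatCallSet(
        habitat=rule.habitat,
        method="cca_axis",
        cds=set(selected.index),
        provenance={
            "axis": rule.axis,
            "sign": rule.sign,
            "cutoff": rule.cutoff,
            "n_selected": len(selected),
        },
    )


def core_like_cds(cds_scores: pd.DataFrame, cutoff: float = DEFAULT_SCORE_CUTOFF) -> set[str]:
    """CDS neutral to every axis (|score| ≤ cutoff throughout) — the
    housekeeping-like fraction the axis rules never select."""
    if cds_scores.shape[1] == 0:
        return set(cds_scores.index)
    neutral = (cds_scores.abs() <= cutoff).all(axis=1)
    return set(cds_scores.index[neutral])


def assign_habitat_axes(
    habitat_scores: pd.DataFrame, cutoff: float = DEFAULT_SCORE_CUTOFF
) -> list[AxisSelectionRule]:
    """Derive one axis-selection rule per habitat from its centroid scores.

    Each habitat gets the axis on which its centroid deviates most, with the
    centroid's sign; this mirrors reading the ordination diagram and pairing
    each habitat with the axis that separates it.
    """
    rules = []
    for habitat, row in habitat_scores.iterrows():
        if row.abs().max() == 0 or row.isna().all():
            continue
        axis = int(np.argmax(row.abs().to_numpy()))
        sign = "positive" if row.iloc[axis] >= 0 else "negative"
        rules.append(AxisSelectionRule(axis=axis, sign=sign, habitat=habitat, cutoff=cutoff))
    return rules


def call_habitat_cds(
    cds_scores: pd.DataFrame,
    habitat_scores: pd.DataFrame,
    cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> list[HabitatCallSet]:
    """Ordination-based habitat calls by nearest-centroid-direction attribution.

    Each habitat centroid defines a direction in axis space; every CDS is
    attributed to the habitat whose direction its score vector projects onto
    most strongly, and called when that signed projection exceeds the
    cutoff.  A CDS forced by one habitat thus cannot also be called for
    every habitat it incidentally co-varies with on a shared axis, which a
    plain per-axis filter (:func:`select_axis_cds`) cannot prevent.  With a
    single axis the two procedures coincide.
    """
    calls = []
    S = cds_scores.to_numpy()
    C = habitat_scores.to_numpy()
    if S.shape[1] == 0 or C.shape[0] == 0:
        return [
            HabitatCallSet(h, "cca_axis", set(), {"cutoff": cutoff})
            for h in habitat_scores.index
        ]
    norms = np.linalg.norm(C, axis=1)
    ok = norms > 0
    U = np.zeros_like(C)
    U[ok] = C[ok] / norms[ok, None]
    proj = S @ U.T  # CDS × habitats signed projections
    best = np.argmax(proj, axis=1)
    best_val = proj[np.arange(S.shape[0]), best]
    for j, habitat in enumerate(habitat_scores.index):
        sel = (best == j) & (best_val > cutoff) & ok[j]
        calls.append(
            HabitatCallSet(
                habitat=habitat,
                method="cca_axis",
                cds=set(cds_scores.index[sel]),
                provenance={
                    "cutoff": cutoff,
                    "attribution": "nearest_centroid_direction",
                    "n_selected": int(sel.sum()),
                },
            )
        )
    return calls


def call_exclusive_cds(
    pa: PresenceAbsenceMatrix, design: HabitatDesign, mode: str = "strict"
) -> list[HabitatCallSet]:
    """Habitat-exclusive CDS calls.

    ``strict``: present in every genome of the habitat and absent outside.
    ``any``: present in at least one genome of the habitat and absent outside.
    """
    if mode not in ("strict", "any"):
        raise ValueError(f"mode must be strict/any, got {mode!r}")
    design.require_covering(pa.genomes)
    df = pa.df
    calls = []
    for habitat in design.habitats:
        members = [g for g in pa.genomes if design.assignment[g] == habitat]
        if not members:
            raise ValueError(f"habitat {habitat!r} has no genomes in the matrix")
        others = [g for g in pa.genomes if g not in members]
        inside = df.loc[members]
        absent_outside = (
            (df.loc[others].sum(axis=0) == 0) if others else pd.Series(True, index=df.columns)
        )
        if mode == "strict":
            present_inside = inside.all(axis=0).astype(bool)
        else:
            present_inside = inside.any(axis=0).astype(bool)
        sel = df.columns[present_inside & absent_outside]
        calls.append(
            HabitatCallSet(
                habitat=habitat,
                method=f"exclusive_{mode}",
                cds=set(sel),
                provenance={"n_members": len(members), "n_selected": len(sel)},
            )
        )
    return calls


def module_completeness(observed_orthologs: set[str], module: KeggModuleDef) -> str:
    """KEGG module completeness with the one-missing-component allowance.

    A component block counts as satisfied when any of its orthologs is
    observed; the module is ``"present"`` iff at most one block is
    unsatisfied.  Single-component modules require their component observed
    (otherwise no evidence at all would count as present).
    """
    if not module.components:
        raise ValueError(f"module {module.module_id} has no components")
    unsatisfied = sum(1 for block in module.components if not (block & observed_orthologs))
    if len(module.components) == 1:
        return "present" if unsatisfied == 0 else "absent"
    return "present" if unsatisfied <= 1 else "absent"


def build_table4(
    calls_by_method: Mapping[str, Sequence[HabitatCallSet]],
    annotation_table: Mapping[str, str],
    unannotated_label: str = "hypothetical",
) -> pd.DataFrame:
    """Habitat × function presence table.

    ``○`` marks a function supported by the ordination route or by
    strict-exclusive calls; ``Δ`` marks support only from the relaxed
    any-mode calls; blank otherwise.  Unannotated CDS are pooled under
    ``unannotated_label``.
    """
    strong: dict[tuple[str, str], bool] = {}
    weak: dict[tuple[str, str], bool] = {}
    habitats: list[str] = []
    functions: list[str] = []

    def note(target: dict, habitat: str, function: str) -> None:
        if habitat not in habitats:
            habitats.append(habitat)
        if function not in functions:
            functions.append(function)
        target[(habitat, function)] = True

    for method, calls in calls_by_method.items():
        for call in calls:
            for cds in sorted(call.cds):
                func = annotation_table.get(cds, unannotated_label)
                if method in ("cca_axis", "exclusive_strict"):
                    note(strong, call.habitat, func)
                elif method == "exclusive_any":
                    note(weak, call.habitat, func)
                else:
                    raise ValueError(f"unknown call method {method!r}")

    table = pd.DataFrame("", index=functions, columns=habitats)
    for (h, f) in weak:
        table.loc[f, h] = "Δ"
    for (h, f) in strong:
        table.loc[f, h] = "○"
    return table
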