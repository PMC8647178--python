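"""Pipeline-variant registry and measure applicability.

A *pipeline variant* is one model-building pipeline, or an ordered pair in
which the first pipeline's model seeds the second, optionally preceded by
Parrot density modification of the starting map.  Four pipelines are
covered: ARP/wARP, Buccaneer, Phenix AutoBuild and SHELXE.

Three evaluation measures are predicted per variant: structure completeness,
R_work and R_free.  R_free only exists when the variant's final output has
been through refinement, which excludes ARP/wARP and SHELXE run on their
own (with or without Parrot), so those cells are dropped from the model
suite.

The default experimental-phasing registry (4 individual pipelines, the 12
ordered pairs, and 8 Parrot-preconditioned variants, 24 in all, yielding 69
applicable (variant, measure) cells) and the default MR registry (the 4
individual pipelines, 10 cells) are reconstructions shipped as
configuration; callers can register any variant list they like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

__all__ = [
    "PIPELINES",
    "MEASURES",
    "PipelineVariant",
    "rfree_applicable",
    "applicable_measures",
    "default_experimental_registry",
    "default_mr_registry",
    "default_registry",
    "count_suite_cells",
]

PIPELINES = ("ARP/wARP", "Buccaneer", "Phenix AutoBuild", "SHELXE")
MEASURES = ("completeness", "R_work", "R_free")

#: Pipelines whose stand-alone output is not refined (no R_free).
_UNREFINED_FINAL = frozenset({"ARP/wARP", "SHELXE"})

_SLUG = {
    "ARP/wARP": "arpwarp",
    "Buccaneer": "buccaneer",
    "Phenix AutoBuild": "autobuild",
    "SHELXE": "shelxe",
}


@dataclass(frozen=True)
class PipelineVariant:
    """An ordered recipe of one or two pipelines, optionally Parrot-first."""

    stages: tuple[str, ...]
    parrot_preconditioned: bool = False
    phasing_mode: str = "experimental"
    variant_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.stages) <= 2:
            raise ValueError("a variant has one or two stages")
        for stage in self.stages:
            if stage not in PIPELINES:
                raise ValueError(f"unknown pipeline {stage!r}")
        if len(self.stages) == 2 and self.stages[0] == self.stages[1]:
            raise ValueError("the two stages of a pair must be distinct")
        if self.phasing_mode == "MR" and len(self.stages) != 1:
            raise ValueError("MR variants are individual pipelines only")
        if not self.variant_id:
            slug = "-then-".join(_SLUG[s] for s in self.stages)
            if self.parrot_preconditioned:
                slug = "parrot-" + slug
            object.__setattr__(self, "variant_id", slug)


def rfree_applicable(variant: PipelineVariant) -> bool:
    """R_free exists only when the variant's final model is refined."""
    return not (len(variant.stages) == 1 and variant.stages[0] in _UNREFINED_FINAL)


def applicable_measures(variant: PipelineVariant) -> tuple[str, ...]:
    if rfree_applicable(variant):
        return MEASURES
    return ("completeness", "R_work")


# Parrot-preconditioned subset: the four individual pipelines plus four
# SHELXE-first pairs (SHELXE benefits most from a density-modified start).
_PARROT_RECIPES: tuple[tuple[str, ...], ...] = (
    ("Buccaneer",),
    ("Phenix AutoBuild",),
    ("SHELXE",),
    ("SHELXE", "Buccaneer"),
    ("SHELXE", "Phenix AutoBuild"),
    ("SHELXE", "ARP/wARP"),
    ("Buccaneer", "Phenix AutoBuild"),
    ("Buccaneer", "ARP/wARP"),
)


def default_experimental_registry() -> list[PipelineVariant]:
    """The 24-variant experimental-phasing registry (69 suite cells)."""
    registry = [PipelineVariant(stages=(p,)) for p in PIPELINES]
    registry += [PipelineVariant(stages=pair) for pair in permutations(PIPELINES, 2)]
    registry += [
        PipelineVariant(stages=recipe, parrot_preconditioned=True)
        for recipe in _PARROT_RECIPES
    ]
    return registry


def default_mr_registry() -> list[PipelineVariant]:
    """The 4 individual pipelines run on MR data (10 suite cells)."""
    return [PipelineVariant(stages=(p,), phasing_mode="MR") for p in PIPELINES]


def default_registry(phasing_mode: str) -> list[PipelineVariant]:
    if phasing_mode == "experimental":
        return default_experimental_registry()
    if phasing_mode == "MR":
        return default_mr_registry()
    raise ValueError(f"unknown phasing mode {phasing_mode!r}")


def count_suite_cells(registry: list[PipelineVariant]) -> int:
    return sum(len(applicable_measures(v)) for v in registry)
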