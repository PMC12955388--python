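"""Metabolic-module presence calling from gene -> KO annotations.

A module is an ordered list of steps; each step is a set of alternative
KO identifiers (any one present satisfies the step).  Coverage is the
satisfied-step fraction and a module is called present when coverage
meets the cutoff (inclusive), default 0.66.

The grammar is deliberately flat (OR within a step, AND across steps);
nested KEGG boolean expressions are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .cohort import AnnotationRecord

__all__ = [
    "ModuleDefinition",
    "parse_modules",
    "read_modules",
    "packaged_scfa_modules",
    "module_coverage",
    "detect_modules",
    "ko_sets_by_genome",
]


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    name: str
    steps: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"module {self.module_id}: needs >=1 step")
        if any(not step for step in self.steps):
            raise ValueError(f"module {self.module_id}: empty step")


def parse_modules(text: str) -> list[ModuleDefinition]:
    """Parse the flat module format.

    One module per block: a ``module_id<TAB>name`` header line, then one
    step per line as comma-separated KO alternatives; blocks separated
    by ``//``.
    """
    modules = []
    for block in text.split("//"):
        lines = [l.strip() for l in block.strip().splitlines() if l.strip()]
        if not lines:
            continue
        if "\t" not in lines[0]:
            raise ValueError(f"module header must be 'id<TAB>name': {lines[0]!r}")
        module_id, name = lines[0].split("\t", 1)
        steps = tuple(
            frozenset(ko.strip() for ko in line.split(",") if ko.strip())
            for line in lines[1:]
        )
        modules.append(ModuleDefinition(module_id, name, steps))
    if not modules:
        raise ValueError("no module definitions found")
    return modules


def read_modules(path) -> list[ModuleDefinition]:
    return parse_modules(Path(path).read_text())


def packaged_scfa_modules() -> list[ModuleDefinition]:
    """Illustrative SCFA production/synthesis modules shipped for demos."""
    text = resources.files("famshare").joinpath("data/scfa_modules.txt").read_text()
    return parse_modules(text)


def module_coverage(ko_set: set[str], module: ModuleDefinition) -> float:
    """Fraction of steps with at least one alternative KO present."""
    satisfied = sum(1 for step in module.steps if step & ko_set)
    return satisfied / len(module.steps)


def detect_modules(
    genome_ko_sets: dict[str, set[str]],
    modules: list[ModuleDefinition],
    cutoff: float = 0.66,
) -> pd.DataFrame:
    """Boolean presence matrix (genomes x modules) at the coverage cutoff."""
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0,1], got {cutoff}")
    data = {
        m.module_id: [
            module_coverage(genome_ko_sets[g], m) >= cutoff
            for g in genome_ko_sets
        ]
        for m in modules
    }
    return pd.DataFrame(data, index=list(genome_ko_sets))


def ko_sets_by_genome(
    annotations: list[AnnotationRecord],
    gene_to_genome: dict[str, str],
) -> dict[str, set[str]]:
    """Group KO annotations into per-genome KO sets."""
    out: dict[str, set[str]] = {}
    for rec in annotations:
        if rec.annotation_type != "KO":
            continue
        genome = gene_to_genome.get(rec.gene_id)
        if genome is None:
            raise KeyError(f"annotation for unknown gene {rec.gene_id!r}")
        out.setdefault(genome, set()).add(rec.label)
    return out
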