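"""Domain types shared by all pipeline stages.

Coordinates are 1-based inclusive throughout; conversion to other
conventions happens only at I/O boundaries.  Genomes may carry ``N``
bases; positions with an ``N`` reference are excluded from ANI and SNV
computations downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "Sex",
    "Sample",
    "FamilyCohort",
    "GenomeAsset",
    "DistanceMatrix",
    "SNVSite",
    "SNVProfile",
    "GeneModel",
    "AnnotationRecord",
    "AssociationResult",
    "validate_abundance",
]

_VALID_BASES = frozenset("ACGTN")


class Role(str, Enum):
    """Family role of a cohort member."""

    FATHER = "father"
    MOTHER = "mother"
    CHILD = "child"
    OTHER = "other"


class Sex(str, Enum):
    M = "M"
    F = "F"


@dataclass(frozen=True)
class Sample:
    """One enrolled subject with the metadata factors used downstream."""

    sample_id: str
    family_id: str
    role: Role
    ethnicity: str
    sex: Sex
    age: float
    region: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"sample {self.sample_id}: age must be >= 0, got {self.age}")


@dataclass
class FamilyCohort:
    """Sample metadata with the derived family -> member map.

    Families of size 1 are allowed but contribute no within-family pairs.
    """

    samples: list[Sample]
    families: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        fam: dict[str, list[str]] = {}
        for s in self.samples:
            if s.sample_id in seen:
                raise ValueError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            fam.setdefault(s.family_id, []).append(s.sample_id)
        self.families = fam

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def family_of(self, sample_id: str) -> str:
        return self.sample(sample_id).family_id

    def within_family_pairs(self) -> list[tuple[str, str]]:
        """All unordered same-family sample pairs."""
        pairs = []
        for members in self.families.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.append((members[i], members[j]))
        return pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "family_id": [s.family_id for s in self.samples],
                "role": [s.role.value for s in self.samples],
                "ethnicity": [s.ethnicity for s in self.samples],
                "sex": [s.sex.value for s in self.samples],
                "age": [s.age for s in self.samples],
                "region": [s.region for s in self.samples],
            }
        )


@dataclass
class GenomeAsset:
    """One genome (MAG analog) with its origin and quality metadata.

    ``contigs`` maps contig id -> sequence.  Multi-contig genomes keep
    contigs separate for gene coordinates but are treated as one genome
    for ANI, pi and abundance.
    """

    genome_id: str
    sample_id: str
    species_label: str
    contigs: dict[str, str]
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"{self.genome_id}: completeness out of [0,100]")
        if not 0 <= self.contamination <= 100:
            raise ValueError(f"{self.genome_id}: contamination out of [0,100]")
        for cid, seq in self.contigs.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"{self.genome_id}/{cid}: illegal characters {sorted(bad)}"
                )

    @property
    def sequence(self) -> str:
        """All contigs concatenated in insertion order."""
        return "".join(self.contigs.values())

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def quality_score(self) -> float:
        """dRep-style score used for representative choice."""
        return self.completeness - 5.0 * self.contamination


class DistanceMatrix:
    """Square symmetric dissimilarity matrix with ordered labels."""

    def __init__(self, labels, values, validate: bool = True):
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if np.any(self.values < 0):
            raise ValueError("negative dissimilarities")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix not symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def subset(self, labels) -> "DistanceMatrix":
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(list(df.index), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class SNVSite:
    """One polymorphic site: 1-based position and per-base allele counts."""

    contig: str
    position: int
    ref_allele: str
    allele_counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.allele_counts.values())

    def frequencies(self) -> dict[str, float]:
        tot = self.total
        if tot < 1:
            raise ValueError(
                f"site {self.contig}:{self.position} has zero total count"
            )
        return {b: c / tot for b, c in self.allele_counts.items() if c > 0}


@dataclass
class SNVProfile:
    """Per-genome polymorphic sites; feeds pi and pN/pS."""

    genome_id: str
    sites: list[SNVSite]

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class GeneModel:
    """Protein-coding gene span, 1-based inclusive, on one contig."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    annotation_type: str  # KO | CAZyme | resistance
    label: str

    _ALLOWED = ("KO", "CAZyme", "resistance")

    def __post_init__(self) -> None:
        if self.annotation_type not in self._ALLOWED:
            raise ValueError(
                f"annotation_type must be one of {self._ALLOWED}, "
                f"got {self.annotation_type!r}"
            )


@dataclass
class AssociationResult:
    """Factor association with a distance matrix (PERMANOVA output)."""

    factor: str
    r_squared: float
    p_value: float
    n_permutations: int
    f_statistic: float = float("nan")
    aliased: bool = False

    def __post_init__(self) -> None:
        if self.aliased:
            return
        if not 0 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")
        if not np.isnan(self.p_value):
            lower = 1.0 / (self.n_permutations + 1)
            if self.p_value < lower - 1e-12 or self.p_value > 1:
                raise ValueError(
                    f"p_value {self.p_value} outside [{lower}, 1]"
                )


def quality_filter(
    genomes: list[GenomeAsset],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> list[GenomeAsset]:
    """Keep genomes with completeness >= min and contamination <= max.

    Both comparisons are inclusive; input order is preserved.
    """
    for name, v in (("min_completeness", min_completeness),
                    ("max_contamination", max_contamination)):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} must be in [0,100], got {v}")
    return [
        g
        for g in genomes
        if g.completeness >= min_completeness and g.contamination <= max_contamination
    ]


def validate_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check AbundanceMatrix invariants: non-negative, no missing cells."""
    if matrix.isna().any().any():
        raise ValueError("abundance matrix has missing cells (absent must be 0)")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("abundance matrix has negative values")
    return matrix
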