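"""Within-family sharing inference for species populations.

Selects candidate populations (genomes from >=2 members of a family, in
at least a minimum fraction of all families), tests whether genome
genetic variation is associated with family (single-factor PERMANOVA on
the 1-ANI matrix), flags shared populations (R^2 > 0.5 and p < 0.05,
strict as printed), counts sharing events, and embeds ANI matrices by
classical MDS.

The ANI cutoff defining one "sharing" event is not fixed by the source
analysis; the default of 99.5% sits between species-level (95%) and
strain-level popANI conventions and is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ani import AniParams, ani_distance_matrix
from .cohort import DistanceMatrix, FamilyCohort, GenomeAsset, SNVProfile
from .permanova import gower_center, permanova_single

__all__ = [
    "CandidatePopulation",
    "SharingStats",
    "select_candidates",
    "population_distance_matrix",
    "family_association",
    "count_sharing",
    "analyze_population",
    "classical_mds",
    "genetic_composition_distance",
]


@dataclass
class CandidatePopulation:
    species_label: str
    genomes: list[GenomeAsset]
    families_with_pairs: list[str]


@dataclass
class SharingStats:
    species_label: str
    shared_flag: bool
    r_squared: float
    p_value: float
    sharing_times: int = 0
    family_prevalence: int = 0


def select_candidates(
    genomes: list[GenomeAsset],
    cohort: FamilyCohort,
    min_members: int = 2,
    min_family_frac: float = 0.30,
) -> list[CandidatePopulation]:
    """Populations with >=min_members same-family genome contributors in
    at least ``min_family_frac`` of all families (inclusive fractions).

    If a sample contributed several genomes of one species, only the
    highest-quality one is kept (same score as the dereplication
    representative rule).
    """
    fam_of = {s.sample_id: s.family_id for s in cohort.samples}
    n_families = len(cohort.families)
    by_species: dict[str, dict[str, GenomeAsset]] = {}
    for g in genomes:
        if g.sample_id not in fam_of:
            raise KeyError(f"genome {g.genome_id}: unknown sample {g.sample_id}")
        kept = by_species.setdefault(g.species_label, {})
        prev = kept.get(g.sample_id)
        if prev is None or (
            (-g.quality_score, -g.length, g.genome_id)
            < (-prev.quality_score, -prev.length, prev.genome_id)
        ):
            kept[g.sample_id] = g
    out: list[CandidatePopulation] = []
    for species in sorted(by_species):
        members = by_species[species]
        per_family: dict[str, int] = {}
        for sid in members:
            per_family[fam_of[sid]] = per_family.get(fam_of[sid], 0) + 1
        fams = sorted(f for f, c in per_family.items() if c >= min_members)
        if n_families and len(fams) / n_families >= min_family_frac:
            out.append(
                CandidatePopulation(
                    species_label=species,
                    genomes=sorted(members.values(), key=lambda g: g.genome_id),
                    families_with_pairs=fams,
                )
            )
    return out


def population_distance_matrix(
    population: CandidatePopulation, params: AniParams = AniParams()
) -> DistanceMatrix:
    return ani_distance_matrix(population.genomes, params)


def _family_factor(population: CandidatePopulation, cohort: FamilyCohort) -> list[str]:
    fam_of = {s.sample_id: s.family_id for s in cohort.samples}
    return [fam_of[g.sample_id] for g in population.genomes]


def family_association(
    population: CandidatePopulation,
    cohort: FamilyCohort,
    ani_params: AniParams = AniParams(),
    r2_threshold: float = 0.5,
    p_threshold: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    dist: DistanceMatrix | None = None,
) -> SharingStats:
    """Family-association test on the population's 1-ANI matrix.

    shared_flag requires R^2 strictly above ``r2_threshold`` AND p
    strictly below ``p_threshold``.
    """
    families = _family_factor(population, cohort)
    if len(set(families)) < 2:
        raise ValueError(
            f"{population.species_label}: all genomes from one family — "
            "no between-family contrast"
        )
    if dist is None:
        dist = population_distance_matrix(population, ani_params)
    res = permanova_single(
        dist, families, n_perm=n_perm, seed=seed, name="family"
    )
    return SharingStats(
        species_label=population.species_label,
        shared_flag=(res.r_squared > r2_threshold and res.p_value < p_threshold),
        r_squared=res.r_squared,
        p_value=res.p_value,
    )


def count_sharing(
    population: CandidatePopulation,
    cohort: FamilyCohort,
    dist: DistanceMatrix,
    sharing_ani: float = 99.5,
    stats: SharingStats | None = None,
) -> SharingStats:
    """Count within-family genome pairs at/above the sharing ANI.

    ``sharing_times`` counts qualifying pairs; ``family_prevalence``
    counts distinct families with at least one such pair (so times can
    exceed families).
    """
    fam_of = {s.sample_id: s.family_id for s in cohort.samples}
    sample_of = {g.genome_id: g.sample_id for g in population.genomes}
    times = 0
    fams: set[str] = set()
    labels = dist.labels
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            fa = fam_of[sample_of[labels[i]]]
            fb = fam_of[sample_of[labels[j]]]
            if fa != fb:
                continue
            ani = 100.0 * (1.0 - dist.values[i, j])
            if ani >= sharing_ani:
                times += 1
                fams.add(fa)
    if stats is None:
        stats = SharingStats(population.species_label, False, float("nan"), float("nan"))
    stats.sharing_times = times
    stats.family_prevalence = len(fams)
    return stats


def analyze_population(
    population: CandidatePopulation,
    cohort: FamilyCohort,
    ani_params: AniParams = AniParams(),
    r2_threshold: float = 0.5,
    p_threshold: float = 0.05,
    sharing_ani: float = 99.5,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[SharingStats, DistanceMatrix]:
    """Association test + sharing counts on one shared ANI matrix."""
    dist = population_distance_matrix(population, ani_params)
    stats = family_association(
        population, cohort, ani_params, r2_threshold, p_threshold,
        n_perm=n_perm, seed=seed, dist=dist,
    )
    return count_sharing(population, cohort, dist, sharing_ani, stats), dist


def classical_mds(dist: DistanceMatrix, k: int = 2) -> pd.DataFrame:
    """Torgerson scaling of a distance matrix to k coordinates.

    Axes are ordered by eigenvalue; only non-negative eigenpairs are
    used (fewer axes are returned with a warning if necessary).  Sign
    convention: the largest-magnitude loading on each axis is positive.
    """
    if len(dist) < 3:
        raise ValueError("need at least 3 points")
    g = gower_center(dist)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(abs(vals[0]), 1.0)
    positive = vals > tol
    n_pos = int(positive.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes "
            f"instead of {k}",
            stacklevel=2,
        )
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for ax in range(k):
        i = int(np.argmax(np.abs(coords[:, ax])))
        if coords[i, ax] < 0:
            coords[:, ax] = -coords[:, ax]
    return pd.DataFrame(
        coords, index=dist.labels, columns=[f"MDS{i + 1}" for i in range(k)]
    )


def genetic_composition_distance(
    snv_profiles: list[SNVProfile],
    genomes: list[GenomeAsset],
    cohort: FamilyCohort | None = None,
) -> DistanceMatrix:
    """Sample-level dissimilarity of intraspecies genetic composition.

    Convention (the source analysis leaves this undefined): per sample,
    concatenate major-allele frequencies at the union of polymorphic
    sites of each species (species absent from a sample contribute
    zeros; a monomorphic site in a profiled species contributes 1.0),
    then take Bray-Curtis over the concatenated vectors.
    """
    meta = {g.genome_id: (g.sample_id, g.species_label) for g in genomes}
    by_sample: dict[str, dict[str, dict[tuple[str, int], float]]] = {}
    site_union: dict[str, set[tuple[str, int]]] = {}
    for prof in snv_profiles:
        if prof.genome_id not in meta:
            raise KeyError(f"profile {prof.genome_id}: no matching genome")
        sample_id, species = meta[prof.genome_id]
        per_species = by_sample.setdefault(sample_id, {}).setdefault(species, {})
        for site in prof.sites:
            freqs = site.frequencies()
            per_species[(site.contig, site.position)] = max(freqs.values())
            site_union.setdefault(species, set()).add((site.contig, site.position))
    samples = sorted(by_sample)
    if len(samples) < 2:
        raise ValueError("need SNV profiles for >=2 samples")
    if cohort is not None:
        missing = [s.sample_id for s in cohort.samples if s.sample_id not in by_sample]
        if missing:
            raise ValueError(f"samples with no profiled species: {missing}")
    species_order = sorted(site_union)
    site_order = {sp: sorted(site_union[sp]) for sp in species_order}
    vectors = []
    for sid in samples:
        vec: list[float] = []
        for sp in species_order:
            per_species = by_sample[sid].get(sp)
            if per_species is None:
                vec.extend([0.0] * len(site_order[sp]))
            else:
                vec.extend(per_species.get(site, 1.0) for site in site_order[sp])
        vectors.append(vec)
    frame = pd.DataFrame(vectors, index=samples)
    from .quantify import bray_curtis

    return bray_curtis(frame)
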