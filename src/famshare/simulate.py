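"""Synthetic family cohorts with known ground truth.

Generates family-structured metadata, per-species ancestral genomes,
per-host strains derived by point mutation, planted within-family
transmission events (near-identical strain pairs), family-correlated
abundance profiles and codon-aware SNV/gene tables.  Strain evolution is
substitution-only (no indels) so an exact Hamming-identity oracle exists
for every downstream ANI check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    AnnotationRecord,
    FamilyCohort,
    GeneModel,
    GenomeAsset,
    Role,
    Sample,
    Sex,
    SNVProfile,
    SNVSite,
)
from . import io as fio

__all__ = ["SimulationConfig", "GroundTruth", "SyntheticCohort",
           "mutate_genome", "generate_cohort"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")

# KO pool for synthetic annotations: SCFA-route KOs from the packaged
# module fixture plus neutral filler identifiers.
_SCFA_KOS = [
    "K00925", "K00625", "K01034", "K01035", "K00929", "K00169", "K00170",
    "K01847", "K05606", "K03416", "K01026", "K00932", "K01652", "K00656",
]
_FILLER_KOS = [f"K9{i:04d}" for i in range(40)]
_CAZY_LABELS = ["GH13", "GH2", "GH3", "GT2", "GT4", "CE1", "PL1"]
_RESISTANCE_LABELS = ["tetW", "ermB", "vanR", "aadE", "cfxA"]


@dataclass
class SimulationConfig:
    """Knobs of the generative model; all randomness flows from ``seed``."""

    n_families: int = 25
    members_per_family: int | tuple[int, int] | list[int] = (2, 4)
    n_species: int = 3
    genome_length: int = 20_000
    substitution_rate_within_species: float = 0.02
    transmission_pairs: list[tuple[str, str]] = field(default_factory=list)
    transmission_divergence: float = 1e-4
    family_effect_size: float = 1.0
    diversity_coupling: float = 0.0
    snv_depth: int = 50
    residual_het_rate: float = 1e-4
    gene_length: int = 300
    gene_spacing: int = 450
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate_within_species", "transmission_divergence"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        if self.transmission_pairs and (
            self.transmission_divergence >= self.substitution_rate_within_species
        ):
            raise ValueError(
                "transmission_divergence must be < substitution_rate_within_species"
            )

    def family_ids(self) -> list[str]:
        return [f"F{i + 1:02d}" for i in range(self.n_families)]

    def species_labels(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery checks."""

    shared_pairs: list[tuple[str, str]]  # (family_id, species_label)
    family_effect_size: float
    substitution_rate: float
    transmission_divergence: float

    @property
    def shared_species(self) -> set[str]:
        return {sp for _, sp in self.shared_pairs}


@dataclass
class SyntheticCohort:
    cohort: FamilyCohort
    genomes: list[GenomeAsset]
    abundance: pd.DataFrame  # samples x species, RPKM scale
    snv_profiles: list[SNVProfile]
    gene_models: list[GeneModel]
    annotations: list[AnnotationRecord]
    truth: GroundTruth

    def write_bundle(self, out_dir) -> None:
        """Write the complete input bundle as plain-text files."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_genomes(self.genomes, out)
        fio.write_metadata(self.cohort, out / "metadata.tsv")
        fio.write_abundance(self.abundance, out / "abundance.tsv")
        fio.write_snv(self.snv_profiles, out / "snv.tsv")
        fio.write_genes(self.gene_models, out / "genes.tsv")
        fio.write_annotations(self.annotations, out / "annotations.tsv")
        pd.DataFrame(
            self.truth.shared_pairs, columns=["family_id", "species_label"]
        ).to_csv(out / "truth.tsv", sep="\t", index=False)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mutate_genome(sequence: str, substitution_rate: float, seed) -> str:
    """Substitute each non-N site independently with the given probability.

    A substituted site receives a uniformly chosen *different* base.
    Length-preserving and reproducible given ``seed`` (int or Generator).
    """
    if not 0 <= substitution_rate <= 0.5:
        raise ValueError(f"substitution rate must be in [0, 0.5], got {substitution_rate}")
    if not sequence:
        raise ValueError("sequence must be non-empty")
    rng = _as_rng(seed)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    eligible = arr != ord("N")
    hit = (rng.random(arr.size) < substitution_rate) & eligible
    idx = np.nonzero(hit)[0]
    if idx.size:
        # map each hit base to one of the 3 other bases
        base_idx = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _tile_genes(
    ancestor: np.ndarray,
    species: str,
    gene_length: int,
    gene_spacing: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[GeneModel]]:
    """Tile genes along the ancestor and purge in-frame stop codons.

    Returns the (possibly edited) ancestor and the gene models.  Genes
    alternate strand; tiling covers >= gene_length/gene_spacing of the
    genome.
    """
    if gene_length % 3:
        raise ValueError("gene_length must be a multiple of 3")
    seq = ancestor.copy()
    genes: list[GeneModel] = []
    pos = 0  # 0-based
    i = 0
    nonstop = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
               if a + b + c not in _STOPS]
    while pos + gene_length <= len(seq):
        strand = "+" if i % 2 == 0 else "-"
        coding = seq[pos:pos + gene_length].tobytes().decode("ascii")
        if strand == "-":
            coding = _revcomp(coding)
        codons = [coding[j:j + 3] for j in range(0, gene_length, 3)]
        for j, codon in enumerate(codons):
            if codon in _STOPS:
                codons[j] = nonstop[rng.integers(0, len(nonstop))]
        coding = "".join(codons)
        if strand == "-":
            coding = _revcomp(coding)
        seq[pos:pos + gene_length] = np.frombuffer(
            coding.encode("ascii"), dtype=np.uint8
        )
        genes.append(
            GeneModel(
                gene_id=f"{species}_g{i + 1:03d}",
                contig=species,
                start=pos + 1,
                end=pos + gene_length,
                strand=strand,
            )
        )
        pos += gene_spacing
        i += 1
    return seq, genes


def _snv_profile(
    genome_id: str,
    contig: str,
    strain: str,
    depth: int,
    het_rate: float,
    rng: np.random.Generator,
) -> SNVProfile:
    """Residual-heterogeneity SNVs at random non-N sites of the strain."""
    arr = np.frombuffer(strain.encode("ascii"), dtype=np.uint8)
    eligible = np.nonzero(arr != ord("N"))[0]
    n_sites = rng.binomial(eligible.size, het_rate)
    sites: list[SNVSite] = []
    if n_sites:
        chosen = np.sort(rng.choice(eligible, size=n_sites, replace=False))
        for p in chosen:
            ref = chr(arr[p])
            base_idx = int(np.searchsorted(_BASES, arr[p]))
            alt = chr(_BASES[(base_idx + rng.integers(1, 4)) % 4])
            minor_freq = rng.uniform(0.1, 0.5)
            minor = max(1, int(round(minor_freq * depth)))
            sites.append(
                SNVSite(
                    contig=contig,
                    position=int(p) + 1,
                    ref_allele=ref,
                    allele_counts={ref: depth - minor, alt: minor},
                )
            )
    return SNVProfile(genome_id, sites)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete cohort bundle from the configuration.

    Every sample carries one genome of every species; planted
    transmission pairs make the first two members of the named family
    near-identical for that species.
    """
    rng = np.random.default_rng(config.seed)
    family_ids = config.family_ids()
    species = config.species_labels()

    # --- family sizes
    mpf = config.members_per_family
    if isinstance(mpf, int):
        sizes = [mpf] * config.n_families
    elif isinstance(mpf, tuple):
        lo, hi = mpf
        sizes = [int(rng.integers(lo, hi + 1)) for _ in family_ids]
    else:
        if len(mpf) != config.n_families:
            raise ValueError("per-family member list length != n_families")
        sizes = list(mpf)

    transmissions = [(str(f), str(s)) for f, s in config.transmission_pairs]
    size_of = dict(zip(family_ids, sizes))
    for fam, sp in transmissions:
        if fam not in size_of:
            raise ValueError(f"transmission references unknown family {fam!r}")
        if sp not in species:
            raise ValueError(f"transmission references unknown species {sp!r}")
        if size_of[fam] < 2:
            raise ValueError(
                f"transmission planted in family {fam!r} with <2 members"
            )

    # --- samples
    ethnicities = ["Daur", "Evenki", "Buryat"]
    regions = ["R1", "R2", "R3"]
    samples: list[Sample] = []
    counter = 1
    for fam, size in zip(family_ids, sizes):
        for m in range(size):
            if m == 0:
                role, sex = Role.FATHER, Sex.M
                age = float(rng.integers(28, 56))
            elif m == 1:
                role, sex = Role.MOTHER, Sex.F
                age = float(rng.integers(25, 53))
            else:
                role = Role.CHILD
                sex = Sex.M if rng.random() < 0.5 else Sex.F
                age = float(rng.integers(1, 14))
            # ethnicity/region are independent per-sample noise factors
            samples.append(
                Sample(
                    sample_id=f"S{counter:03d}",
                    family_id=fam,
                    role=role,
                    ethnicity=ethnicities[rng.integers(0, len(ethnicities))],
                    sex=sex,
                    age=age,
                    region=regions[rng.integers(0, len(regions))],
                )
            )
            counter += 1
    cohort = FamilyCohort(samples)

    # --- ancestors with codon-aware gene tiling
    ancestors: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    for sp in species:
        anc = _random_genome(rng, config.genome_length)
        anc, genes = _tile_genes(
            anc, sp, config.gene_length, config.gene_spacing, rng
        )
        ancestors[sp] = anc.tobytes().decode("ascii")
        gene_models.extend(genes)

    # --- strains: donors for planted transmissions, independent otherwise
    genomes: list[GenomeAsset] = []
    snv_profiles: list[SNVProfile] = []
    rate = config.substitution_rate_within_species
    donors = {
        (fam, sp): mutate_genome(ancestors[sp], rate, rng)
        for fam, sp in transmissions
    }
    recipients = {
        (fam, sp): set(cohort.families[fam][:2]) for fam, sp in transmissions
    }
    for s in samples:
        for sp in species:
            key = (s.family_id, sp)
            if key in donors and s.sample_id in recipients[key]:
                strain = mutate_genome(
                    donors[key], config.transmission_divergence, rng
                )
            else:
                strain = mutate_genome(ancestors[sp], rate, rng)
            gid = f"{s.sample_id}.{sp}"
            genomes.append(
                GenomeAsset(
                    genome_id=gid,
                    sample_id=s.sample_id,
                    species_label=sp,
                    contigs={sp: strain},
                    completeness=float(np.round(rng.uniform(80, 100), 2)),
                    contamination=float(np.round(rng.uniform(0, 5), 2)),
                )
            )
            snv_profiles.append(
                _snv_profile(
                    gid, sp, strain, config.snv_depth,
                    config.residual_het_rate, rng,
                )
            )

    # --- abundance: log-normal with additive per-family/species effect
    n, k = len(samples), len(species)
    baseline = rng.normal(0.0, 1.0, size=k)
    u = rng.normal(0.0, 1.0, size=(config.n_families, k))
    fam_index = {f: i for i, f in enumerate(family_ids)}
    eps = rng.normal(0.0, 0.5, size=(n, k))
    if config.diversity_coupling > 0:
        # high-evenness families: flatter composition AND less member noise
        evenness = rng.uniform(0.0, 1.0, size=config.n_families)
        spread = 1.0 + 2.0 * (1.0 - evenness)
        noise_scale = 1.0 - config.diversity_coupling * evenness
    else:
        spread = np.ones(config.n_families)
        noise_scale = np.ones(config.n_families)
    log_abund = np.empty((n, k))
    for i, s in enumerate(samples):
        fi = fam_index[s.family_id]
        log_abund[i] = (
            spread[fi] * baseline
            + config.family_effect_size * u[fi]
            + noise_scale[fi] * eps[i]
        )
    abundance = pd.DataFrame(
        10.0 * np.exp(log_abund),
        index=[s.sample_id for s in samples],
        columns=species,
    )

    # --- annotations
    annotations: list[AnnotationRecord] = []
    ko_pool = _SCFA_KOS + _FILLER_KOS
    for g in gene_models:
        annotations.append(
            AnnotationRecord(g.gene_id, "KO", ko_pool[rng.integers(0, len(ko_pool))])
        )
        r = rng.random()
        if r < 0.15:
            annotations.append(
                AnnotationRecord(
                    g.gene_id, "CAZyme",
                    _CAZY_LABELS[rng.integers(0, len(_CAZY_LABELS))],
                )
            )
        elif r < 0.22:
            annotations.append(
                AnnotationRecord(
                    g.gene_id, "resistance",
                    _RESISTANCE_LABELS[rng.integers(0, len(_RESISTANCE_LABELS))],
                )
            )

    truth = GroundTruth(
        shared_pairs=transmissions,
        family_effect_size=config.family_effect_size,
        substitution_rate=rate,
        transmission_divergence=config.transmission_divergence,
    )
    return SyntheticCohort(
        cohort=cohort,
        genomes=genomes,
        abundance=abundance,
        snv_profiles=snv_profiles,
        gene_models=gene_models,
        annotations=annotations,
        truth=truth,
    )
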