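"""Calibration and recovery experiments for the pipeline's statistics.

Each function recomputes a property from scratch at run time — null
type-I error of the PERMANOVA, recovery of planted family effects and
transmissions, agreement of fragment ANI with the exact Hamming oracle,
neutrality of pooled pN/pS — and returns the measured quantity.  They
back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .ani import AniParams, fragment_ani
from .cohort import DistanceMatrix, GeneModel, SNVProfile, SNVSite
from .microdiversity import count_sites, pnps
from .permanova import permanova_marginal, permanova_single
from .quantify import bray_curtis
from .sharing import analyze_population, classical_mds, select_candidates
from .simulate import SimulationConfig, generate_cohort, mutate_genome

__all__ = [
    "permanova_type1_error",
    "family_dominance_rate",
    "sharing_recovery_rate",
    "ani_oracle_max_gap",
    "neutral_pnps",
    "all_synonymous_pnps",
    "closed_form_checks",
    "demo_determinism",
]

_MARGINAL_FACTORS = ["family_id", "role", "ethnicity", "sex", "age", "region"]


def permanova_type1_error(
    n_samples: int = 30,
    n_perm: int = 199,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate when the factor is independent noise."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        pts = rng.normal(size=(n_samples, 5))
        dm = DistanceMatrix(
            [f"s{i}" for i in range(n_samples)], squareform(pdist(pts))
        )
        factor = list(rng.choice(["a", "b", "c"], size=n_samples))
        while len(set(factor)) < 2:  # vanishingly rare, but be safe
            factor = list(rng.choice(["a", "b", "c"], size=n_samples))
        res = permanova_single(
            dm, factor, n_perm=n_perm, seed=int(rng.integers(1 << 31))
        )
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_reps


def family_dominance_rate(
    n_reps: int = 50,
    seed: int = 0,
    n_families: int = 25,
    family_effect_size: float = 1.0,
    n_perm: int = 99,
) -> float:
    """Fraction of cohorts where family attains the top marginal R^2."""
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_reps):
        cfg = SimulationConfig(
            n_families=n_families,
            members_per_family=(2, 4),
            n_species=3,
            genome_length=2001,
            family_effect_size=family_effect_size,
            seed=int(rng.integers(1 << 31)),
        )
        cohort = generate_cohort(cfg)
        bc = bray_curtis(cohort.abundance)
        meta = cohort.cohort.to_frame().set_index("sample_id")
        factors = meta.loc[bc.labels, _MARGINAL_FACTORS].copy()
        factors["age"] = factors["age"].astype(float)
        results = permanova_marginal(
            bc, factors, n_perm=n_perm, seed=int(rng.integers(1 << 31))
        )
        best = max(results, key=lambda r: r.r_squared)
        if best.factor == "family_id":
            wins += 1
    return wins / n_reps


def sharing_recovery_rate(
    n_reps: int = 50,
    seed: int = 0,
    n_families: int = 6,
    genome_length: int = 5000,
    within_divergence: float = 1e-4,
    background_rate: float = 2e-2,
    n_perm: int = 199,
) -> float:
    """Fraction of cohorts where flagged populations == planted set.

    Requires sensitivity = specificity = 1 per replicate: the planted
    species (transmissions in every family) is flagged and no
    unplanted species is.
    """
    rng = np.random.default_rng(seed)
    params = AniParams(fragment_len=500)
    exact = 0
    for _ in range(n_reps):
        cfg = SimulationConfig(
            n_families=n_families,
            members_per_family=2,
            n_species=3,
            genome_length=genome_length,
            substitution_rate_within_species=background_rate,
            transmission_pairs=[
                (f"F{i + 1:02d}", "sp1") for i in range(n_families)
            ],
            transmission_divergence=within_divergence,
            residual_het_rate=2e-3,
            seed=int(rng.integers(1 << 31)),
        )
        cohort = generate_cohort(cfg)
        flagged = set()
        for pop in select_candidates(cohort.genomes, cohort.cohort):
            stats, _ = analyze_population(
                pop, cohort.cohort, params, n_perm=n_perm,
                seed=int(rng.integers(1 << 31)),
            )
            if stats.shared_flag:
                flagged.add(pop.species_label)
        if flagged == cohort.truth.shared_species:
            exact += 1
    return exact / n_reps


def ani_oracle_max_gap(
    genome_length: int = 100_000,
    divergences: tuple[float, ...] = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05),
    seed: int = 0,
) -> float:
    """Max |fragment ANI - exact Hamming identity| over a divergence grid."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    anc = "".join(bases[rng.integers(0, 4, genome_length)])
    gap = 0.0
    for rate in divergences:
        mut = mutate_genome(anc, rate, int(rng.integers(1 << 31)))
        a = np.frombuffer(anc.encode(), dtype=np.uint8)
        b = np.frombuffer(mut.encode(), dtype=np.uint8)
        exact = 100.0 * (a == b).mean()
        sim = fragment_ani(mut, anc)
        gap = max(gap, abs(sim.ani - exact))
    return gap


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < n_codons:
        c = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3)])
        if c not in stops:
            codons.append(c)
    return "".join(codons)


def _neutral_pnps_once(
    rng: np.random.Generator,
    n_genes: int,
    gene_codons: int,
    mutations_per_gene: int,
) -> float:
    total_n = total_s = sites_n = sites_s = 0.0
    for gi in range(n_genes):
        coding = _random_coding(rng, gene_codons)
        gene_len = 3 * gene_codons
        gene = GeneModel(f"g{gi}", "c", 1, gene_len, "+")
        positions = rng.choice(gene_len, size=mutations_per_gene, replace=False)
        sites = []
        for pos in positions:
            ref = coding[pos]
            alt_choices = [b for b in "ACGT" if b != ref]
            alt = alt_choices[rng.integers(0, 3)]
            sites.append(SNVSite("c", int(pos) + 1, ref, {ref: 35, alt: 15}))
        (sel,) = pnps(
            SNVProfile(f"g{gi}", sites), [gene], {"c": coding}
        ).selections
        ns, ss = count_sites(coding)
        total_n += sel.pn * ns
        total_s += sel.ps * ss
        sites_n += ns
        sites_s += ss
    return float((total_n / sites_n) / (total_s / sites_s))


def neutral_pnps(
    n_genes: int = 200,
    gene_codons: int = 100,
    mutations_per_gene: int = 25,
    seed: int = 0,
    n_mc: int = 12,
) -> tuple[float, float]:
    """Pooled pN/pS of uniformly planted mutations, with Monte-Carlo sigma.

    Returns (pooled_ratio, sigma_mc): the pooled ratio of the primary
    experiment and the standard deviation of the same statistic over
    ``n_mc`` independent replicates — the acceptance band is
    |pooled - 1| <= 3 * sigma_mc.
    """
    rng = np.random.default_rng(seed)
    pooled = _neutral_pnps_once(rng, n_genes, gene_codons, mutations_per_gene)
    replicates = [
        _neutral_pnps_once(rng, n_genes, gene_codons, mutations_per_gene)
        for _ in range(n_mc)
    ]
    sigma_mc = float(np.std(replicates, ddof=1))
    return pooled, sigma_mc


def all_synonymous_pnps() -> float:
    """pN/pS of a profile containing only synonymous changes (exactly 0)."""
    coding = "GGGGGGGGGGGG"  # glycine codons: position 3 is fourfold
    gene = GeneModel("g", "c", 1, len(coding), "+")
    sites = [
        SNVSite("c", pos, "G", {"G": 30, "A": 20})
        for pos in (3, 6, 9, 12)
    ]
    (sel,) = pnps(SNVProfile("g", sites), [gene], {"c": coding}).selections
    return sel.pnps


def closed_form_checks() -> dict[str, float]:
    """Deltas of the closed-form examples (all should be ~0, bools 1)."""
    from .funcmodules import ModuleDefinition, detect_modules, module_coverage
    from .quantify import shannon

    out: dict[str, float] = {}
    out["shannon_uniform_delta"] = abs(
        shannon(np.ones(7)).shannon - np.log(7)
    )
    bc = bray_curtis(pd.DataFrame([[6.0, 2.0], [2.0, 2.0]], index=["a", "b"]))
    out["bray_curtis_delta"] = abs(bc.get("a", "b") - 1.0 / 3.0)
    m = ModuleDefinition(
        "M", "m", (frozenset({"K1"}), frozenset({"K2"}), frozenset({"K3"}))
    )
    cov = module_coverage({"K1", "K2"}, m)
    out["module_coverage_delta"] = abs(cov - 2.0 / 3.0)
    present = detect_modules({"g": {"K1", "K2"}}, [m], cutoff=0.66).loc["g", "M"]
    out["module_present_at_cutoff"] = float(bool(present))
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(12, 3))
    d = squareform(pdist(pts))
    dm = DistanceMatrix([f"p{i}" for i in range(12)], d)
    coords = classical_mds(dm, k=3)
    rec = squareform(pdist(coords.to_numpy()))
    out["mds_reconstruction_error"] = float(np.abs(rec - d).max())
    return out


def demo_determinism(work_dir, seed: int = 0) -> bool:
    """Run the demo twice with one seed; True iff bundles byte-match."""
    from click.testing import CliRunner

    from .cli import main

    work = Path(work_dir)
    runner = CliRunner()
    for name in ("run1", "run2"):
        res = runner.invoke(
            main,
            ["demo", "--out", str(work / name), "--seed", str(seed),
             "--nperm", "99"],
        )
        if res.exit_code != 0:
            raise RuntimeError(f"demo failed: {res.output}")
    files = sorted(
        p.relative_to(work / "run1")
        for p in (work / "run1").rglob("*")
        if p.is_file()
    )
    for rel in files:
        if not filecmp.cmp(work / "run1" / rel, work / "run2" / rel,
                           shallow=False):
            return False
    return bool(files)
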