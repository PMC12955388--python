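"""End-to-end orchestration: input bundle -> per-stage report tables.

Every run writes a manifest recording the seed, all thresholds and the
SHA-256 of each input file, so a run is reproducible from the manifest
alone.  Outputs are deterministic byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as fio
from .ani import AniParams, dereplicate
from .cohort import quality_filter
from .funcmodules import detect_modules, packaged_scfa_modules, read_modules
from .microdiversity import nucleotide_diversity, pnps, rank_selection
from .network import core_nodes, correlation_network
from .permanova import permanova_marginal
from .quantify import (
    bray_curtis,
    child_parent_trend,
    diversity_similarity_trend,
    shannon_table,
    within_between_test,
)
from .sharing import (
    analyze_population,
    classical_mds,
    genetic_composition_distance,
    select_candidates,
)

log = logging.getLogger("famshare")

_FACTORS = ["family_id", "role", "ethnicity", "sex", "age", "region"]
_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    bundle_dir: str
    out_dir: str
    seed: int = 0
    min_completeness: float = 50.0
    max_contamination: float = 10.0
    min_members: int = 2
    min_family_frac: float = 0.30
    r2_threshold: float = 0.5
    p_threshold: float = 0.05
    sharing_ani: float = 99.5
    module_cutoff: float = 0.66
    rho_min: float = 0.6
    p_max: float = 0.05
    n_perm: int = 999
    fragment_len: int = 1000
    kmer: int = 16
    min_af: float = 0.3
    primary: float = 0.90
    secondary: float = 0.95
    modules_file: str | None = None
    run_dereplication: bool = True

    @property
    def ani_params(self) -> AniParams:
        return AniParams(
            fragment_len=self.fragment_len, k=self.kmer, min_af=self.min_af,
            primary=self.primary, secondary=self.secondary,
        )


def load_config(path) -> dict:
    """Flat key: value config file (YAML subset) mirroring CLI flags."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat mapping")
    return data


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False, index_label=None):
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=_FLOAT_FMT)


def _genome_ko_sets(genomes, gene_models, annotations) -> dict[str, set[str]]:
    genes_by_contig: dict[str, list[str]] = {}
    for g in gene_models:
        genes_by_contig.setdefault(g.contig, []).append(g.gene_id)
    ko_by_gene: dict[str, set[str]] = {}
    for rec in annotations:
        if rec.annotation_type == "KO":
            ko_by_gene.setdefault(rec.gene_id, set()).add(rec.label)
    out = {}
    for genome in genomes:
        kos: set[str] = set()
        for contig in genome.contigs:
            for gid in genes_by_contig.get(contig, ()):
                kos |= ko_by_gene.get(gid, set())
        out[genome.genome_id] = kos
    return out


def _marginal_with_df_guard(dist, factors, n_perm, seed):
    """Marginal PERMANOVA, shedding trailing factors while the full
    model leaves no residual degrees of freedom (small cohorts)."""
    cols = list(factors.columns)
    while True:
        try:
            results = permanova_marginal(
                dist, factors[cols], n_perm=n_perm, seed=seed
            )
        except ValueError as e:
            if "residual degrees" in str(e) and len(cols) > 1:
                dropped = cols.pop()
                log.info("permanova: dropped factor %r (no residual df)", dropped)
                continue
            raise
        return results


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the output directory.

    On a stage failure, a ``FAILED`` marker naming the stage is written
    next to any partial outputs and the error is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = Path(config.bundle_dir)
    stage = "load_inputs"
    try:
        cohort = fio.read_metadata(bundle / "metadata.tsv")
        genomes = fio.read_genomes(bundle)
        abundance = fio.read_abundance(bundle / "abundance.tsv")
        snv_profiles = fio.read_snv(bundle / "snv.tsv")
        gene_models = fio.read_genes(bundle / "genes.tsv")
        annotations = fio.read_annotations(bundle / "annotations.tsv")
        log.info("load_inputs: %d samples, %d genomes", len(cohort), len(genomes))

        stage = "quality_filter"
        kept = quality_filter(
            genomes, config.min_completeness, config.max_contamination
        )
        log.info("quality_filter: %d -> %d genomes", len(genomes), len(kept))

        stage = "dereplicate"
        if config.run_dereplication:
            clusters = dereplicate(
                kept, config.primary, config.secondary, config.ani_params
            )
            _write(
                pd.DataFrame(
                    {
                        "cluster_id": [c.cluster_id for c in clusters],
                        "representative": [c.representative for c in clusters],
                        "members": [",".join(c.members) for c in clusters],
                    }
                ),
                out / "clusters.tsv",
            )
            log.info("dereplicate: %d clusters", len(clusters))

        stage = "diversity"
        shannon = shannon_table(abundance)
        _write(shannon, out / "shannon.tsv")
        bc = bray_curtis(abundance)
        fio.write_distance_matrix(bc, out / "bray_curtis.tsv")
        within, between, wb_p = within_between_test(bc, cohort)
        trend_rows = [
            {
                "analysis": "within_between",
                "statistic": float(pd.Series(within).median()),
                "statistic2": float(pd.Series(between).median()),
                "p_value": wb_p,
                "n": len(within) + len(between),
            }
        ]
        try:
            t = child_parent_trend(bc, cohort)
            trend_rows.append(
                {"analysis": "child_parent_age", "statistic": t.spearman_rho,
                 "statistic2": float("nan"), "p_value": t.p_value, "n": t.n_pairs}
            )
        except ValueError:
            log.info("diversity: too few child-parent pairs for the age trend")
        t = diversity_similarity_trend(bc, shannon, cohort)
        trend_rows.append(
            {"analysis": "diversity_similarity", "statistic": t.spearman_rho,
             "statistic2": float("nan"), "p_value": t.p_value, "n": t.n_pairs}
        )
        _write(pd.DataFrame(trend_rows), out / "trends.tsv")

        stage = "genetic_distance"
        gdist = genetic_composition_distance(snv_profiles, genomes)
        fio.write_distance_matrix(gdist, out / "genetic_distance.tsv")

        stage = "permanova"
        meta = cohort.to_frame().set_index("sample_id")
        rows = []
        for level, dist in (("composition", bc), ("genetic", gdist)):
            factors = meta.loc[dist.labels, _FACTORS].copy()
            factors["age"] = factors["age"].astype(float)
            results = _marginal_with_df_guard(
                dist, factors, n_perm=config.n_perm, seed=config.seed
            )
            for r in results:
                rows.append(
                    {"level": level, "factor": r.factor, "r_squared": r.r_squared,
                     "f_statistic": r.f_statistic, "p_value": r.p_value,
                     "aliased": r.aliased}
                )
        _write(pd.DataFrame(rows), out / "permanova.tsv")

        stage = "sharing"
        candidates = select_candidates(
            kept, cohort, config.min_members, config.min_family_frac
        )
        log.info("sharing: %d candidate populations", len(candidates))
        sharing_rows = []
        for pop in candidates:
            stats, dist = analyze_population(
                pop, cohort, config.ani_params,
                config.r2_threshold, config.p_threshold, config.sharing_ani,
                n_perm=config.n_perm, seed=config.seed,
            )
            sharing_rows.append(
                {"species_label": stats.species_label,
                 "shared_flag": stats.shared_flag,
                 "r_squared": stats.r_squared, "p_value": stats.p_value,
                 "sharing_times": stats.sharing_times,
                 "family_prevalence": stats.family_prevalence}
            )
            if stats.shared_flag and len(dist) >= 3:
                coords = classical_mds(dist, k=2)
                _write(coords, out / f"mds_{stats.species_label}.tsv",
                       index=True, index_label="genome_id")
        _write(
            pd.DataFrame(
                sharing_rows,
                columns=["species_label", "shared_flag", "r_squared", "p_value",
                         "sharing_times", "family_prevalence"],
            ),
            out / "sharing.tsv",
        )

        stage = "microdiversity"
        by_id = {g.genome_id: g for g in genomes}
        pi_rows, sel_rows, pooled = [], [], []
        for prof in snv_profiles:
            genome = by_id[prof.genome_id]
            pi_rows.append(
                {"genome_id": prof.genome_id,
                 "pi": nucleotide_diversity(prof, genome.length)}
            )
            gene_subset = [g for g in gene_models if g.contig in genome.contigs]
            if not gene_subset:
                continue
            report = pnps(prof, gene_subset, genome)
            for s in report:
                sel_rows.append(
                    {"genome_id": prof.genome_id, "gene_id": s.gene_id,
                     "pn": s.pn, "ps": s.ps,
                     "pnps": "" if s.pnps is None else s.pnps,
                     "classification": s.classification}
                )
                if s.pnps is not None:
                    pooled.append(
                        type(s)(f"{prof.genome_id}:{s.gene_id}",
                                s.pn, s.ps, s.pnps, s.classification)
                    )
        _write(pd.DataFrame(pi_rows), out / "pi.tsv")
        _write(pd.DataFrame(sel_rows), out / "pnps.tsv")
        if pooled:
            _write(rank_selection(pooled, annotations=None), out / "pnps_ranked.tsv")

        stage = "modules"
        modules = (
            read_modules(config.modules_file)
            if config.modules_file
            else packaged_scfa_modules()
        )
        ko_sets = _genome_ko_sets(kept, gene_models, annotations)
        presence = detect_modules(ko_sets, modules, config.module_cutoff)
        _write(presence.astype(int), out / "modules.tsv",
               index=True, index_label="genome_id")

        stage = "network"
        edges = correlation_network(
            abundance.T, rho_min=config.rho_min, p_max=config.p_max
        )
        _write(
            pd.DataFrame(
                [{"taxon_a": e.taxon_a, "taxon_b": e.taxon_b, "rho": e.rho,
                  "p_value": e.p_value, "sign": e.sign} for e in edges],
                columns=["taxon_a", "taxon_b", "rho", "p_value", "sign"],
            ),
            out / "network_edges.tsv",
        )
        _write(
            pd.DataFrame({"core_node": core_nodes(edges)}),
            out / "network_core.tsv",
        )

        stage = "manifest"
        cfg_record = asdict(config)
        # paths relative to the report dir keep reruns byte-identical
        cfg_record["bundle_dir"] = os.path.relpath(bundle, out)
        cfg_record["out_dir"] = "."
        manifest = {
            "version": __version__,
            "config": cfg_record,
            "input_hashes": {
                p.name: _hash_file(p) for p in sorted(bundle.iterdir())
                if p.is_file()
            },
            "counts": {
                "samples": len(cohort),
                "genomes_in": len(genomes),
                "genomes_kept": len(kept),
                "candidate_populations": len(candidates),
                "shared_populations": int(
                    sum(r["shared_flag"] for r in sharing_rows)
                ),
                "network_edges": len(edges),
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
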