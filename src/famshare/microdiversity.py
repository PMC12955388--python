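"""Within-species genetic statistics: nucleotide diversity and pN/pS.

Site counting is NG86-style with equal weights (no transition /
transversion weighting): at each codon position, each of the three
possible changes contributes 1/3 of a site, split between synonymous and
nonsynonymous according to the bacterial genetic code (translation
table 11).  Stop-gain changes count as nonsynonymous.

SNV sites are filtered before use: total allele count >= ``min_total``
and minor-allele frequency >= ``min_minor_freq`` (defaults 5 and 0.05;
these are conventions of this implementation, not measured values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .cohort import AnnotationRecord, GeneModel, GenomeAsset, SNVProfile, SNVSite

__all__ = [
    "GeneSelection",
    "PnpsReport",
    "nucleotide_diversity",
    "count_sites",
    "pnps",
    "rank_selection",
]

_TABLE = CodonTable.unambiguous_dna_by_id[11]
_STOP = "*"
_COMP = str.maketrans("ACGTN", "TGCAN")


def _translate(codon: str) -> str:
    if codon in _TABLE.stop_codons:
        return _STOP
    return _TABLE.forward_table.get(codon, "X")


@dataclass(frozen=True)
class GeneSelection:
    gene_id: str
    pn: float
    ps: float
    pnps: float | None  # None = undefined (too few synonymous changes)
    classification: str  # purifying | neutral | positive | undefined

    @staticmethod
    def classify(pnps: float | None) -> str:
        if pnps is None:
            return "undefined"
        if pnps < 1.0:
            return "purifying"
        if pnps > 1.0:
            return "positive"
        return "neutral"


@dataclass
class PnpsReport:
    selections: list[GeneSelection]
    n_sites_outside_genes: int = 0
    n_sites_filtered: int = 0
    n_ref_mismatch: int = 0

    def __iter__(self):
        return iter(self.selections)

    def __len__(self):
        return len(self.selections)


def _passes(site: SNVSite, min_total: int, min_minor_freq: float) -> bool:
    tot = site.total
    if tot == 0:
        raise ValueError(
            f"site {site.contig}:{site.position} has zero total count"
        )
    if tot < min_total:
        return False
    freqs = sorted(site.frequencies().values(), reverse=True)
    minor = 1.0 - freqs[0]
    return minor >= min_minor_freq


def nucleotide_diversity(
    profile: SNVProfile,
    genome_length: int,
    min_total: int = 5,
    min_minor_freq: float = 0.05,
) -> float:
    """Genome-wide pi: mean per-site heterozygosity 1 - sum f_b^2.

    Monomorphic (and filtered) sites contribute zero; the sum is divided
    by ``genome_length``.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    total = 0.0
    for site in profile.sites:
        if not _passes(site, min_total, min_minor_freq):
            continue
        f = np.array(list(site.frequencies().values()))
        total += 1.0 - float((f ** 2).sum())
    return total / genome_length


def count_sites(gene_sequence: str) -> tuple[float, float]:
    """NG86 (nonsynonymous_sites, synonymous_sites) of a coding sequence.

    Codons containing N are skipped; counted codons contribute exactly 3
    sites each.
    """
    seq = gene_sequence.upper()
    if len(seq) % 3:
        raise ValueError(f"length {len(seq)} not divisible by 3")
    nonsyn = syn = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if "N" in codon:
            continue
        aa = _translate(codon)
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1:]
                if _translate(mutant) == aa:
                    syn += 1.0 / 3.0
                else:
                    nonsyn += 1.0 / 3.0
    return nonsyn, syn


def _coding_sequence(gene: GeneModel, contig_seq: str) -> str:
    region = contig_seq[gene.start - 1:gene.end]
    if gene.strand == "-":
        region = region.translate(_COMP)[::-1]
    return region


def _contig_map(genome) -> dict[str, str]:
    if isinstance(genome, GenomeAsset):
        return genome.contigs
    if isinstance(genome, dict):
        return genome
    raise TypeError("genome must be a GenomeAsset or a contig->sequence dict")


def pnps(
    profile: SNVProfile,
    gene_models: list[GeneModel],
    genome,
    min_syn_changes: int = 1,
    min_total: int = 5,
    min_minor_freq: float = 0.05,
) -> PnpsReport:
    """Per-gene pN, pS and their ratio from a genome's SNV profile.

    Each minor allele at a polymorphic site counts as one change
    (multi-allelic sites contribute each minor allele separately).
    pN/pS is reported as undefined — never infinity — when fewer than
    ``min_syn_changes`` synonymous changes were seen.
    """
    contigs = _contig_map(genome)
    by_contig: dict[str, list[GeneModel]] = {}
    for gene in gene_models:
        if gene.contig not in contigs:
            raise KeyError(f"gene {gene.gene_id}: unknown contig {gene.contig!r}")
        if gene.length % 3:
            raise ValueError(f"gene {gene.gene_id}: length not divisible by 3")
        by_contig.setdefault(gene.contig, []).append(gene)

    changes: dict[str, list[int]] = {g.gene_id: [0, 0] for g in gene_models}  # [N, S]
    outside = filtered = mismatch = 0
    for site in profile.sites:
        if not _passes(site, min_total, min_minor_freq):
            filtered += 1
            continue
        contig_seq = contigs.get(site.contig)
        host = None
        for gene in by_contig.get(site.contig, ()):
            if gene.start <= site.position <= gene.end:
                host = gene
                break
        if host is None or contig_seq is None:
            outside += 1
            continue
        ref = contig_seq[site.position - 1]
        if ref == "N":
            filtered += 1
            continue
        if site.ref_allele != ref:
            mismatch += 1
            continue
        coding = _coding_sequence(host, contig_seq)
        if host.strand == "+":
            cpos = site.position - host.start
        else:
            cpos = host.end - site.position
        codon_i, codon_pos = divmod(cpos, 3)
        codon = coding[codon_i * 3:codon_i * 3 + 3]
        if "N" in codon:
            filtered += 1
            continue
        aa = _translate(codon)
        freqs = site.frequencies()
        for allele in sorted(freqs):
            if allele == site.ref_allele:
                continue
            alt = allele if host.strand == "+" else allele.translate(_COMP)
            mutant = codon[:codon_pos] + alt + codon[codon_pos + 1:]
            if _translate(mutant) == aa:
                changes[host.gene_id][1] += 1
            else:
                changes[host.gene_id][0] += 1

    selections = []
    for gene in gene_models:
        coding = _coding_sequence(gene, contigs[gene.contig])
        nonsyn_sites, syn_sites = count_sites(coding)
        n_changes, s_changes = changes[gene.gene_id]
        pn = n_changes / nonsyn_sites if nonsyn_sites > 0 else 0.0
        ps = s_changes / syn_sites if syn_sites > 0 else 0.0
        ratio = pn / ps if s_changes >= min_syn_changes and ps > 0 else None
        selections.append(
            GeneSelection(
                gene_id=gene.gene_id,
                pn=pn,
                ps=ps,
                pnps=ratio,
                classification=GeneSelection.classify(ratio),
            )
        )
    return PnpsReport(selections, outside, filtered, mismatch)


def rank_selection(
    selections: list[GeneSelection] | PnpsReport,
    annotations: list[AnnotationRecord] | None = None,
    top_n: int = 10,
) -> pd.DataFrame:
    """Top and bottom ``top_n`` genes by defined pN/pS, with annotations.

    Ties are broken by lexicographic gene_id; genes with undefined pN/pS
    never appear.
    """
    if isinstance(selections, PnpsReport):
        selections = selections.selections
    defined = [s for s in selections if s.pnps is not None]
    if not defined:
        raise ValueError("no gene with a defined pN/pS value")
    defined.sort(key=lambda s: (-s.pnps, s.gene_id))
    ann_map: dict[str, dict[str, list[str]]] = {}
    for rec in annotations or []:
        ann_map.setdefault(rec.gene_id, {}).setdefault(
            rec.annotation_type, []
        ).append(rec.label)
    rows = []
    n = len(defined)
    top_idx = set(range(min(top_n, n)))
    bottom_idx = set(range(max(0, n - top_n), n))
    for i, s in enumerate(defined):
        if i not in top_idx and i not in bottom_idx:
            continue
        groups = []
        if i in top_idx:
            groups.append("top")
        if i in bottom_idx:
            groups.append("bottom")
        ann = ann_map.get(s.gene_id, {})
        rows.append(
            {
                "gene_id": s.gene_id,
                "pnps": s.pnps,
                "pn": s.pn,
                "ps": s.ps,
                "classification": s.classification,
                "rank_group": "+".join(groups),
                "KO": ",".join(sorted(ann.get("KO", []))),
                "CAZyme": ",".join(sorted(ann.get("CAZyme", []))),
                "resistance": ",".join(sorted(ann.get("resistance", []))),
            }
        )
    return pd.DataFrame(rows)
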