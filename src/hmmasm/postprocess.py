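"""Post-assembly processing: filters, clustering, coverage, abundance.

Contigs below the length or score cutoffs are discarded, survivors are
clustered by amino-acid identity with complete linkage and the longest
member represents each cluster.  Identity is computed in model-column space
(every contig is emitted along an HMM path, so its residues already carry
model coordinates), which keeps clustering deterministic without a pairwise
aligner.  Coverage splits shared-kmer counts equally among the contigs
containing the kmer so nothing is counted twice, and per-gene abundance is
normalised by read hits to the single-copy rplB marker.

Chimera screening is delegated to UCHIME: this module writes the inputs it
consumes and ingests its tab report, nothing more.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cag_search import Contig
from .io_formats import SequenceRecord, write_fasta
from .kmer_graph import canonical, read_kmers


@dataclass
class ContigCluster:
    members: list[Contig]
    representative: Contig
    threshold: float


@dataclass
class CoverageReport:
    coverage: dict[str, float]  # contig id -> mean kmer coverage
    split_counts: dict[str, float]  # contig id -> summed split kmer counts
    gene_read_hits: dict[str, int]  # gene -> reads covering >= 1 kmer
    total_matched_occurrences: int


def filter_contigs(
    contigs: Iterable[Contig], min_nt: int = 300, min_bits: float = 50.0
) -> list[Contig]:
    """Collapse exact nucleotide duplicates, then apply the length and HMM
    score cutoffs (defaults 300 nt and 50 bits).  Idempotent."""
    unique: dict[str, Contig] = {}
    for c in sorted(contigs, key=lambda c: c.id):
        unique.setdefault(c.nt, c)
    kept = [c for c in unique.values() if len(c.nt) >= min_nt and c.bits >= min_bits]
    kept.sort(key=lambda c: c.id)
    return kept


def pairwise_aa_identity(a: Contig, b: Contig) -> float:
    """Fraction of agreeing residues over the overlap of the two contigs'
    model-column projections; disjoint spans give 0 by convention."""
    cols = a.col_aa.keys() & b.col_aa.keys()
    if not cols:
        return 0.0
    matches = sum(1 for c in cols if a.col_aa[c] == b.col_aa[c])
    return matches / len(cols)


def _canonical_order(contigs: Iterable[Contig]) -> list[Contig]:
    return sorted(contigs, key=lambda c: (-len(c.aa), -c.bits, c.id))


def cluster_contigs(
    contigs: Iterable[Contig], threshold: float = 0.99
) -> list[ContigCluster]:
    """Complete-linkage clustering on distance ``1 - identity`` cut at
    ``1 - threshold``; representative is the longest member (ties broken by
    higher bit score, then id).  Input-order invariant."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    items = _canonical_order(contigs)
    if not items:
        return []
    if len(items) == 1:
        return [ContigCluster(items, items[0], threshold)]
    n = len(items)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_aa_identity(items[i], items[j])
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(Z, t=(1.0 - threshold) + 1e-9, criterion="distance")
    groups: dict[int, list[Contig]] = defaultdict(list)
    for contig, label in zip(items, labels):
        groups[label].append(contig)
    clusters = []
    for label in sorted(groups):
        members = groups[label]  # already canonically ordered
        clusters.append(ContigCluster(members, members[0], threshold))
    clusters.sort(key=lambda cl: cl.representative.id)
    return clusters


def kmer_coverage(
    contigs_by_gene: dict[str, list[Contig]],
    reads: Iterable,
    k: int,
) -> CoverageReport:
    """Mean kmer coverage per contig from a read scan (mapping-free).

    A read-kmer occurrence found in ``m`` contigs adds ``1/m`` to each, so
    split counts sum exactly to the total matched occurrences.  Contig
    coverage is the mean over its kmer positions; per-gene read hits count
    reads covering at least one kmer of that gene's contigs.  Canonical
    kmers are used throughout (reads are unstranded).
    """
    index: dict[str, set[str]] = defaultdict(set)  # kmer -> contig ids
    contig_positions: dict[str, list[str]] = {}
    contig_gene: dict[str, str] = {}
    for gene in sorted(contigs_by_gene):
        for contig in contigs_by_gene[gene]:
            kms = [canonical(km) for km in read_kmers(contig.nt, k)]
            contig_positions[contig.id] = kms
            contig_gene[contig.id] = gene
            for km in kms:
                index[km].add(contig.id)

    kmer_occurrences: dict[str, int] = defaultdict(int)
    gene_read_hits: dict[str, int] = {g: 0 for g in contigs_by_gene}
    for read in reads:
        genes_hit: set[str] = set()
        for km in read_kmers(read, k):
            ck = canonical(km)
            ids = index.get(ck)
            if ids:
                kmer_occurrences[ck] += 1
                genes_hit.update(contig_gene[cid] for cid in ids)
        for g in genes_hit:
            gene_read_hits[g] += 1

    share: dict[str, dict[str, float]] = defaultdict(dict)  # contig -> kmer -> share
    for km, occ in kmer_occurrences.items():
        per = occ / len(index[km])
        for cid in index[km]:
            share[cid][km] = per

    coverage = {}
    split_counts = {}
    for cid, positions in contig_positions.items():
        got = share.get(cid, {})
        coverage[cid] = (
            sum(got.get(km, 0.0) for km in positions) / len(positions)
            if positions
            else 0.0
        )
        split_counts[cid] = sum(got.values())
    return CoverageReport(
        coverage=coverage,
        split_counts=split_counts,
        gene_read_hits=gene_read_hits,
        total_matched_occurrences=sum(kmer_occurrences.values()),
    )


def relative_abundance(gene_hits: int, rplb_hits: int) -> Optional[float]:
    """Read-hit ratio of a gene to the rplB marker; rplB vs itself is 1.
    Zero rplB hits make the ratio undefined (None, with a warning)."""
    if rplb_hits <= 0:
        warnings.warn("zero rplB read hits: relative abundance undefined")
        return None
    return gene_hits / rplb_hits


def coverage_weighted_otu_table(
    clusters: list[ContigCluster],
    contig_sample: dict[str, str],
    coverage: dict[str, float],
) -> pd.DataFrame:
    """Sample x OTU abundance matrix, each OTU weighted by the summed mean
    coverage of its member contigs per sample (input to ordination)."""
    samples = sorted(set(contig_sample.values()))
    names = [f"OTU{i + 1}" for i in range(len(clusters))]
    table = pd.DataFrame(0.0, index=samples, columns=names)
    for name, cluster in zip(names, clusters):
        for member in cluster.members:
            sample = contig_sample[member.id]
            table.loc[sample, name] += coverage.get(member.id, 0.0)
    return table


# ---------------------------------------------------------------------------
# UCHIME delegation hooks

def write_chimera_inputs(
    representatives: Iterable[Contig],
    reference_nt: Iterable[SequenceRecord],
    outdir,
) -> tuple[Path, Path]:
    """Emit the nucleotide representatives and reference set in the layout
    an external chimera screen (UCHIME) consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    query_path = outdir / "chimera_query.fasta"
    ref_path = outdir / "chimera_reference.fasta"
    write_fasta(
        [SequenceRecord(id=c.id, residues=c.nt) for c in representatives], query_path
    )
    write_fasta(list(reference_nt), ref_path)
    return query_path, ref_path


def apply_chimera_report(contigs: Iterable[Contig], report_path) -> list[Contig]:
    """Drop contigs flagged 'Y' in a UCHIME-style tab report (query label in
    the second column, Y/N verdict in the last)."""
    flagged: set[str] = set()
    with open(report_path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            if fields[-1].strip().upper() == "Y":
                flagged.add(fields[1].split(";")[0])
    return [c for c in contigs if c.id not in flagged]
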