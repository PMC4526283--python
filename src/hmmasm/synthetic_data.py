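"""Synthetic communities with known ground truth.

Every stage of the assembler is testable without downloads: a protein
family is evolved from a random ancestor by i.i.d. substitution,
back-translated with random synonymous codons, planted in random background
DNA, and shredded into error-bearing reads from both strands.  A manifest
records each planted gene and each read's origin so recovery can be judged
exactly.  Defaults emulate short-read shotgun data over a defined mock
community: substitution-only errors, uniform start positions, equiprobable
strands.  Real data's quality-dependent error profiles, indels, repeats and
amplification bias are deliberately absent.

Four named fixtures (deterministic from seeds 1-4) cover the interesting
regimes: a clean community, a two-haplotype mixture for K-paths, a
shared-kmer pair that can chimerise at short kmer lengths, and a
low-coverage sample with zero-coverage gaps for exhaustion handling.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cag_search import Vertex
from .io_formats import MultipleAlignment, SequenceRecord, write_fasta, write_fastq
from .kmer_graph import (
    GENETIC_CODE,
    build_counter,
    reverse_complement,
    translate,
)
from .profile_hmm import AMINO_ACIDS, build_from_alignment

_BASES = "ACGT"

# aa -> sorted list of codons (stops excluded)
CODONS_FOR_AA: dict[str, list[str]] = defaultdict(list)
for _codon in sorted(GENETIC_CODE):
    _aa = GENETIC_CODE[_codon]
    if _aa != "*":
        CODONS_FOR_AA[_aa].append(_codon)


@dataclass
class CommunityConfig:
    """Study conditions for a mock community."""

    seed: int = 1
    n_variants: int = 3
    protein_length: int = 130
    sub_rate: float = 0.12
    abundances: Optional[list[float]] = None  # defaults to uniform
    read_length: int = 100
    error_rate: float = 0.0
    coverage: float = 30.0
    background_length: int = 1500

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_rate <= 1.0 or not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        if self.abundances is not None:
            if len(self.abundances) != self.n_variants:
                raise ValueError("one abundance weight per variant required")
            if abs(sum(self.abundances) - 1.0) > 1e-9:
                raise ValueError("abundances must sum to 1")


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def evolve_family(
    ancestor: str, n: int, sub_rate: float, rng: np.random.Generator
) -> list[str]:
    """``n`` descendants with i.i.d. per-site substitution at ``sub_rate``
    (replacement drawn uniformly from all 20 residues, so the expected
    identity at large length is ``1 - sub_rate * 19/20``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for _ in range(n):
        chars = list(ancestor)
        hits = rng.random(len(chars)) < sub_rate
        for i in np.flatnonzero(hits):
            chars[i] = AMINO_ACIDS[int(rng.integers(0, 20))]
        out.append("".join(chars))
    return out


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform random synonymous codon per residue; translates back exactly."""
    codons = []
    for aa in protein:
        options = CODONS_FOR_AA.get(aa)
        if not options:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def generate_reads(
    genomes: dict[str, str],
    *,
    read_length: int = 100,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    rng: np.random.Generator,
    quality: int = 40,
    weights: Optional[dict[str, float]] = None,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Shotgun reads with uniform starts, equiprobable strands, and i.i.d.
    substitution errors; constant quality.  Returns (records, manifest)."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    records: list[SequenceRecord] = []
    manifest: list[dict] = []
    counter = 0
    for name in sorted(genomes):
        seq = genomes[name]
        if len(seq) < read_length:
            raise ValueError(f"genome {name!r} shorter than the read length")
        weight = (weights or {}).get(name, 1.0)
        n_reads = math.ceil(len(seq) * coverage * weight / read_length)
        for _ in range(n_reads):
            start = int(rng.integers(0, len(seq) - read_length + 1))
            fragment = seq[start : start + read_length]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                fragment = reverse_complement(fragment)
            if error_rate > 0:
                chars = list(fragment)
                hits = rng.random(len(chars)) < error_rate
                for i in np.flatnonzero(hits):
                    current = chars[i]
                    alternatives = [b for b in _BASES if b != current]
                    chars[i] = alternatives[int(rng.integers(0, 3))]
                fragment = "".join(chars)
            counter += 1
            rid = f"r{counter:06d}"
            records.append(
                SequenceRecord(
                    id=rid, residues=fragment, quality=[quality] * read_length
                )
            )
            manifest.append(
                {"read": rid, "genome": name, "start": start, "strand": strand}
            )
    return records, manifest


# ---------------------------------------------------------------------------
# Named fixtures

FIXTURE_SEEDS = {"clean": 1, "two_haplotype": 2, "shared_kmer": 3, "low_coverage": 4}


def _aln(records: dict[str, str]) -> MultipleAlignment:
    return MultipleAlignment(
        [SequenceRecord(id=name, residues=seq) for name, seq in sorted(records.items())]
    )


def _plant(gene_nt: str, rng: np.random.Generator, background_length: int) -> str:
    bg = random_dna(background_length, rng)
    pos = int(rng.integers(0, background_length + 1))
    return bg[:pos] + gene_nt + bg[pos:]


def _write_gene_dir(
    outdir: Path,
    gene: str,
    seed_proteins: dict[str, str],
    ref_proteins: dict[str, str],
    truth_nt: dict[str, str],
) -> None:
    gdir = outdir / gene
    gdir.mkdir(parents=True, exist_ok=True)
    write_fasta(_aln(seed_proteins).records, gdir / "seed.aln", wrap=0)
    write_fasta(_aln(ref_proteins).records, gdir / "refs.aln", wrap=0)
    write_fasta(
        [SequenceRecord(id=name, residues=seq) for name, seq in sorted(truth_nt.items())],
        gdir / "truth_nt.fasta",
        wrap=0,
    )


def make_fixture(name: str, outdir, seed: Optional[int] = None) -> dict:
    """Build one of the four named fixtures under ``outdir``.

    Layout per gene: ``<gene>/seed.aln`` (HMM training alignment),
    ``<gene>/refs.aln`` (start-finding references, a superset including the
    planted proteins), ``<gene>/truth_nt.fasta``; reads in ``reads.fastq``
    and ground truth in ``manifest.json`` at the top level.
    """
    if name not in FIXTURE_SEEDS:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURE_SEEDS)}")
    seed = FIXTURE_SEEDS[name] if seed is None else seed
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes: dict[str, dict] = {}
    genomes: dict[str, str] = {}
    coverage = 30.0
    error_rate = 0.0

    if name == "clean":
        for gene in ("nirk", "rplb"):
            ancestor = random_protein(130, rng)
            fam = evolve_family(ancestor, 6, 0.15, rng)
            planted = evolve_family(ancestor, 3, 0.12, rng)
            truth_nt = {}
            for i, prot in enumerate(planted):
                nt = back_translate(prot, rng)
                gid = f"{gene}_v{i + 1}"
                truth_nt[gid] = nt
                genomes[gid] = _plant(nt, rng, 1500)
            genes[gene] = {
                "seed": {f"{gene}_seed{i + 1}": p for i, p in enumerate(fam)},
                "refs": {f"{gene}_v{i + 1}": p for i, p in enumerate(planted)},
                "truth_nt": truth_nt,
            }
    elif name == "two_haplotype":
        gene = "target"
        ancestor = random_protein(130, rng)
        fam = evolve_family(ancestor, 6, 0.15, rng)
        hap_a = ancestor
        chars = list(ancestor)
        for pos in (90, 100, 110):
            old = chars[pos]
            choices = [a for a in AMINO_ACIDS if a != old]
            chars[pos] = choices[int(rng.integers(0, 19))]
        hap_b = "".join(chars)
        nt_a = back_translate(hap_a, rng)
        nt_b_codons = [nt_a[3 * i : 3 * i + 3] for i in range(len(hap_a))]
        for pos in (90, 100, 110):
            options = CODONS_FOR_AA[hap_b[pos]]
            nt_b_codons[pos] = options[int(rng.integers(0, len(options)))]
        nt_b = "".join(nt_b_codons)
        truth_nt = {"hapA": nt_a, "hapB": nt_b}
        genomes["hapA"] = _plant(nt_a, rng, 1500)
        genomes["hapB"] = _plant(nt_b, rng, 1500)
        genes[gene] = {
            "seed": {f"seed{i + 1}": p for i, p in enumerate(fam)},
            "refs": {"hapA": hap_a, "hapB": hap_b},
            "truth_nt": truth_nt,
        }
    elif name == "shared_kmer":
        gene = "target"
        prot_a = random_protein(130, rng)
        prot_b = list(evolve_family(prot_a, 1, 0.3, rng)[0])
        # identical 12-aa window (36 nt when codons match) flanked by forced
        # differences so the shared nucleotide run stays below 45
        prot_b[60:72] = prot_a[60:72]
        for pos in (59, 72):
            if prot_b[pos] == prot_a[pos]:
                choices = [a for a in AMINO_ACIDS if a != prot_a[pos]]
                prot_b[pos] = choices[int(rng.integers(0, 19))]
        prot_b = "".join(prot_b)
        nt_a = back_translate(prot_a, rng)
        nt_b = back_translate(prot_b, rng)
        nt_b = nt_b[: 3 * 60] + nt_a[3 * 60 : 3 * 72] + nt_b[3 * 72 :]
        fam = evolve_family(prot_a, 6, 0.15, rng)
        truth_nt = {"geneA": nt_a, "geneB": nt_b}
        # Gene A's coverage stops right at the end of the shared window, the
        # regime where short-kmer searches must cross into gene B (chimera)
        # while long kmers spanning past the 36-nt shared run cannot.
        genomes["geneA"] = _plant(nt_a[: 3 * 72], rng, 1500)
        genomes["geneB"] = _plant(nt_b, rng, 1500)
        genes[gene] = {
            "seed": {f"seed{i + 1}": p for i, p in enumerate(fam)},
            "refs": {"geneA": prot_a, "geneB": prot_b},
            "truth_nt": truth_nt,
        }
    else:  # low_coverage
        gene = "target"
        ancestor = random_protein(130, rng)
        fam = evolve_family(ancestor, 6, 0.15, rng)
        nt = back_translate(ancestor, rng)
        truth_nt = {"gene1": nt}
        genomes["gene1"] = _plant(nt, rng, 1500)
        genes[gene] = {
            "seed": {f"seed{i + 1}": p for i, p in enumerate(fam)},
            "refs": {"gene1": ancestor},
            "truth_nt": truth_nt,
        }
        coverage = 0.6

    reads, read_manifest = generate_reads(
        genomes,
        read_length=100,
        coverage=coverage,
        error_rate=error_rate,
        rng=rng,
    )
    write_fastq(reads, outdir / "reads.fastq")
    for gene, info in genes.items():
        _write_gene_dir(outdir, gene, info["seed"], info["refs"], info["truth_nt"])
    manifest = {
        "name": name,
        "seed": seed,
        "coverage": coverage,
        "error_rate": error_rate,
        "genes": {
            g: {"truth_nt": info["truth_nt"], "refs": info["refs"]}
            for g, info in genes.items()
        },
        "reads": read_manifest,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Toy instances for search-oracle audits

def make_toy_instance(
    rng: np.random.Generator,
    k: int = 6,
    model_length: tuple[int, int] = (4, 12),
    mutant_copies: tuple[int, int] = (1, 1),
):
    """A tiny model/graph pair (L <= 12, well under 200 kmers) suitable for
    exhaustive path enumeration: a short family alignment trains the model,
    one or two back-translated variants plus a few mutated copies populate
    the graph, and the search starts at the first variant's first kmer.
    ``model_length`` and ``mutant_copies`` are inclusive ranges controlling
    instance size (smaller settings keep full path enumeration cheap)."""
    L = int(rng.integers(model_length[0], model_length[1] + 1))
    ancestor = random_protein(L, rng)
    fam = evolve_family(ancestor, 3, 0.2, rng)
    aln = _aln({f"s{i}": p for i, p in enumerate(fam)})
    model = build_from_alignment(aln, name="toy")
    n_variants = int(rng.integers(1, 3))
    proteins = evolve_family(ancestor, n_variants, 0.15, rng)
    gene_nts = [back_translate(p, rng) for p in proteins]
    reads = list(gene_nts)
    for nt in gene_nts:
        for _ in range(int(rng.integers(mutant_copies[0], mutant_copies[1] + 1))):
            chars = list(nt)
            hits = rng.random(len(chars)) < 0.05
            for i in np.flatnonzero(hits):
                chars[i] = _BASES[int(rng.integers(0, 4))]
            reads.append("".join(chars))
    counter = build_counter(reads, k)
    start = Vertex(gene_nts[0][:k], k // 3, "M")
    return model, counter, start
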