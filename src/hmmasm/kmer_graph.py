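"""The de Bruijn graph as a kmer-abundance structure.

The graph is never materialised: membership and abundance queries against a
:class:`ExactKmerCounter` or :class:`CountingBloomFilter` define it
implicitly.  Kmers are stored canonically (lexicographic minimum of a kmer
and its reverse complement) because shotgun reads sample both strands, and
both orientations are queryable.

Protein-space traversal walks three single-nucleotide vertices at a time
(:func:`codon_neighbors`): a codon step exists only if each of the three
intermediate shift-by-one kmers passes the minimum-abundance cutoff.
"""

from __future__ import annotations

import math
import pickle
from hashlib import blake2b
from typing import Iterable, Iterator, Union

import numpy as np

from Bio.Data import CodonTable

from .io_formats import SequenceRecord

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID = frozenset("ACGT")
BASES = "ACGT"

# Bacterial/plastid code (NCBI table 11); identical to the standard code for
# elongation, which is all that matters when scoring coding triplets.
_TABLE = CodonTable.unambiguous_dna_by_id[11]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"


class ConfigurationError(ValueError):
    """Counter parameters are inconsistent or unsafe."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (involution)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a kmer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def translate_codon(codon: str) -> str:
    """Translate one triplet; stops give ``*``, ambiguity codes give ``X``."""
    return GENETIC_CODE.get(codon.upper(), "X")


def translate(nt: str) -> str:
    """Frame-1 translation of ``nt``, truncating a trailing partial codon."""
    end = len(nt) - len(nt) % 3
    return "".join(translate_codon(nt[i : i + 3]) for i in range(0, end, 3))


def read_kmers(read: Union[str, SequenceRecord], k: int) -> Iterator[str]:
    """Yield every length-``k`` window containing only A/C/G/T (case-folded).

    Windows touching N or any other code are skipped; reads shorter than
    ``k`` yield nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    residues = read.residues if isinstance(read, SequenceRecord) else read
    residues = residues.upper()
    last_bad = -1
    for i, ch in enumerate(residues):
        if ch not in _VALID:
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            yield residues[i - k + 1 : i + 1]


class ExactKmerCounter:
    """Exact canonical-kmer multiset backed by a hash map (default backend)."""

    backend = "exact"

    def __init__(self, k: int):
        if k < 1:
            raise ConfigurationError("k must be >= 1")
        self.k = k
        self._counts: dict[str, int] = {}

    def add(self, kmer: str) -> None:
        key = canonical(kmer)
        self._counts[key] = self._counts.get(key, 0) + 1

    def count(self, kmer: str) -> int:
        return self._counts.get(canonical(kmer), 0)

    def __contains__(self, kmer: str) -> bool:
        return self.count(kmer) > 0

    @property
    def n_distinct(self) -> int:
        return len(self._counts)

    def params(self) -> dict:
        return {"k": self.k, "backend": self.backend}


class CountingBloomFilter:
    """Counting Bloom filter with 4-bit saturating counters.

    Counts never fail low (no false negatives); a query may overestimate.
    Hashing is keyed blake2b with Kirsch-Mitzenmacher double hashing, so a
    fixed ``seed`` gives identical filters across processes and platforms.
    """

    backend = "counting-bloom"

    def __init__(
        self,
        k: int,
        n_counters: int = 1 << 20,
        n_hashes: int = 4,
        seed: int = 101,
        cap: int = 15,
        fp_ceiling: float = 0.05,
    ):
        if k < 1:
            raise ConfigurationError("k must be >= 1")
        if n_counters < 8 or n_hashes < 1:
            raise ConfigurationError("bloom filter needs >= 8 counters and >= 1 hash")
        self.k = k
        self.n_counters = int(n_counters)
        self.n_hashes = int(n_hashes)
        self.seed = int(seed)
        self.cap = int(cap)
        self.fp_ceiling = float(fp_ceiling)
        self._key = (self.seed & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little")
        self._counters = np.zeros(self.n_counters, dtype=np.uint8)
        self.n_inserts = 0

    def _indices(self, kmer: str) -> list[int]:
        digest = blake2b(canonical(kmer).encode(), digest_size=16, key=self._key).digest()
        h1 = int.from_bytes(digest[:8], "little")
        h2 = int.from_bytes(digest[8:], "little") | 1
        return [(h1 + i * h2) % self.n_counters for i in range(self.n_hashes)]

    def add(self, kmer: str) -> None:
        for idx in self._indices(kmer):
            if self._counters[idx] < self.cap:
                self._counters[idx] += 1
        self.n_inserts += 1

    def count(self, kmer: str) -> int:
        return int(min(self._counters[idx] for idx in self._indices(kmer)))

    def __contains__(self, kmer: str) -> bool:
        return self.count(kmer) > 0

    def expected_fp_rate(self) -> float:
        """Upper-bound estimate using total insert operations as n."""
        if self.n_inserts == 0:
            return 0.0
        load = self.n_hashes * self.n_inserts / self.n_counters
        return (1.0 - math.exp(-load)) ** self.n_hashes

    def params(self) -> dict:
        return {
            "k": self.k,
            "backend": self.backend,
            "n_counters": self.n_counters,
            "n_hashes": self.n_hashes,
            "seed": self.seed,
            "cap": self.cap,
            "fp_ceiling": self.fp_ceiling,
        }


KmerCounter = Union[ExactKmerCounter, CountingBloomFilter]


def build_counter(
    reads: Iterable[Union[str, SequenceRecord]],
    k: int,
    backend: str = "exact",
    **bloom_params,
) -> KmerCounter:
    """Count every kmer of every read (canonical storage, both strands).

    All kmers are kept regardless of abundance; minimum-abundance filtering
    happens at query time (:func:`passes_min_count`).  Raises
    :class:`ConfigurationError` if a Bloom backend ends up sized so that its
    expected false-positive rate exceeds its configured ceiling.
    """
    if backend == "exact":
        counter: KmerCounter = ExactKmerCounter(k)
    elif backend == "counting-bloom":
        counter = CountingBloomFilter(k, **bloom_params)
    else:
        raise ConfigurationError(f"unknown counter backend {backend!r}")
    for read in reads:
        for kmer in read_kmers(read, k):
            counter.add(kmer)
    if isinstance(counter, CountingBloomFilter):
        rate = counter.expected_fp_rate()
        if rate > counter.fp_ceiling:
            raise ConfigurationError(
                f"bloom sizing implies expected false-positive rate {rate:.4f} "
                f"> ceiling {counter.fp_ceiling:.4f}; increase n_counters"
            )
    return counter


def passes_min_count(counter: KmerCounter, kmer: str, min_count: int = 1) -> bool:
    """True iff the kmer's (strand-symmetric) count reaches ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return counter.count(kmer) >= min_count


def codon_neighbors(
    counter: KmerCounter, kmer: str, direction: str, min_count: int = 1
) -> list[tuple[str, str]]:
    """All codon-step neighbors of ``kmer`` in the given direction.

    A right step drops the 3-prefix and appends codon ``xyz``; a left step
    drops the 3-suffix and prepends it.  Each of the three intermediate
    single-nucleotide shifts must itself pass ``min_count`` ("walking three
    vertices at a time").  The returned codon is always in the left-to-right
    reading orientation, sorted for determinism.
    """
    if len(kmer) % 3 != 0:
        raise ValueError("codon steps require k to be a multiple of 3")
    out: list[tuple[str, str]] = []
    if direction == "right":
        base = kmer[1:]
        for x in BASES:
            k1 = base + x
            if counter.count(k1) < min_count:
                continue
            k1s = k1[1:]
            for y in BASES:
                k2 = k1s + y
                if counter.count(k2) < min_count:
                    continue
                k2s = k2[1:]
                for z in BASES:
                    k3 = k2s + z
                    if counter.count(k3) >= min_count:
                        out.append((k3, x + y + z))
    elif direction == "left":
        base = kmer[:-1]
        for z in BASES:
            k1 = z + base
            if counter.count(k1) < min_count:
                continue
            k1s = k1[:-1]
            for y in BASES:
                k2 = y + k1s
                if counter.count(k2) < min_count:
                    continue
                k2s = k2[:-1]
                for x in BASES:
                    k3 = x + k2s
                    if counter.count(k3) >= min_count:
                        out.append((k3, x + y + z))
    else:
        raise ValueError(f"direction must be 'right' or 'left', got {direction!r}")
    out.sort(key=lambda t: t[1])
    return out


_DUMP_VERSION = 1


def dump_counter(counter: KmerCounter, path) -> None:
    """Versioned binary dump of a counter (header: k, backend, params, seed)."""
    payload = {"version": _DUMP_VERSION, "params": counter.params()}
    if isinstance(counter, ExactKmerCounter):
        payload["counts"] = counter._counts
    else:
        payload["counters"] = counter._counters
        payload["n_inserts"] = counter.n_inserts
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=pickle.HIGHEST_PROTOCOL)


def load_counter(path) -> KmerCounter:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != _DUMP_VERSION:
        raise ConfigurationError(f"unsupported counter dump version in {path}")
    params = payload["params"]
    if params["backend"] == "exact":
        counter = ExactKmerCounter(params["k"])
        counter._counts = payload["counts"]
        return counter
    params = {key: val for key, val in params.items() if key != "backend"}
    counter = CountingBloomFilter(**params)
    counter._counters = payload["counters"]
    counter.n_inserts = payload["n_inserts"]
    return counter
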