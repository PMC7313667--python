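"""Male-specific transcript discovery by k-mer subtraction.

The subtraction strategy removes every male RNA read that could have come
from the female transcriptome — any read that matches a female transcript
exactly, or that shares even a single canonical k-mer with it — and
assembles what survives.  Surviving contigs are then vetted against sexed
genomic reads: a true Y-linked transcript sits at one copy in the male
genome (roughly half the diploid depth) and is absent from the female
genome entirely.

All matching is strand-agnostic via canonical k-mers (the lexicographic
minimum of a k-mer and its reverse complement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "KmerIndex",
    "CandidateYTranscript",
    "SubtractionStats",
    "revcomp",
    "canonical",
    "canonical_kmers",
    "build_kmer_index",
    "subtract_reads",
    "assemble_candidates",
    "classify_by_genomic_coverage",
]

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


def canonical_kmers(seq: str, k: int) -> set[str]:
    """All canonical k-mers of ``seq``; windows with non-ACGT bases skipped."""
    seq = seq.upper()
    rc = seq.translate(_COMP)[::-1]
    n = len(seq)
    out: set[str] = set()
    for i in range(n - k + 1):
        w = seq[i : i + k]
        if not _ACGT.issuperset(w):
            continue
        wrc = rc[n - k - i : n - i]
        out.add(w if w <= wrc else wrc)
    return out


@dataclass(frozen=True)
class KmerIndex:
    """Set of canonical k-mers of a sequence collection."""

    k: int
    kmers: frozenset[str]

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.kmers

    def __len__(self) -> int:
        return len(self.kmers)


def build_kmer_index(sequences: dict[str, str] | Iterable[str], k: int = 25) -> KmerIndex:
    """Index the canonical k-mers of a set of sequences (e.g. a transcriptome).

    ``k`` must be >= 3; odd values are recommended so that no k-mer is its
    own reverse complement.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    if k % 2 == 0:
        logger.warning("even k=%d: reverse-complement palindromes possible", k)
    seqs = sequences.values() if isinstance(sequences, dict) else sequences
    kmers: set[str] = set()
    for seq in seqs:
        if not _ACGT.issuperset(seq.upper()):
            logger.info("sequence contains non-ACGT characters; those windows are skipped")
        kmers |= canonical_kmers(seq, k)
    return KmerIndex(k=k, kmers=frozenset(kmers))


@dataclass
class SubtractionStats:
    n_input: int = 0
    n_retained: int = 0
    n_kmer_hit: int = 0
    n_exact_match: int = 0
    n_too_short: int = 0


def subtract_reads(
    male_rna: Iterable[tuple[str, str, str]],
    female_index: KmerIndex,
    female_transcriptome: dict[str, str] | None = None,
) -> tuple[list[tuple[str, str, str]], SubtractionStats]:
    """Retain male RNA reads that cannot derive from the female transcriptome.

    A read is retained iff it shares no canonical k-mer with the female
    index *and* is not an exact full-length substring (either strand) of
    any female transcript.  For reads of length >= k the k-mer condition
    subsumes the exact-match one, but both are checked so the contract
    holds regardless of input.  Input order of survivors is preserved;
    reads shorter than k are discarded and counted.
    """
    k = female_index.k
    transcripts = list(female_transcriptome.values()) if female_transcriptome else []
    retained: list[tuple[str, str, str]] = []
    stats = SubtractionStats()
    for title, seq, qual in male_rna:
        stats.n_input += 1
        seq_u = seq.upper()
        if len(seq_u) < k:
            stats.n_too_short += 1
            continue
        rc = seq_u.translate(_COMP)[::-1]
        n = len(seq_u)
        shared = False
        for i in range(n - k + 1):
            w = seq_u[i : i + k]
            wrc = rc[n - k - i : n - i]
            if (w if w <= wrc else wrc) in female_index.kmers:
                shared = True
                break
        if shared:
            stats.n_kmer_hit += 1
            continue
        if any(seq_u in t or rc in t for t in transcripts):
            stats.n_exact_match += 1
            continue
        retained.append((title, seq, qual))
        stats.n_retained += 1
    if stats.n_too_short:
        logger.info("discarded %d reads shorter than k=%d", stats.n_too_short, k)
    return retained, stats


# ---------------------------------------------------------------------------
# unitig assembly
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def assemble_candidates(
    reads: Iterable[tuple[str, str, str]] | Iterable[str],
    k: int = 25,
    min_contig_len: int = 200,
) -> dict[str, str]:
    """Assemble reads into unitigs over the canonical de Bruijn graph.

    Maximal non-branching paths are emitted as contigs, each reported on
    its canonical strand (lexicographic min of the contig and its reverse
    complement) and named ``contig_00000`` ... in sorted-sequence order,
    so output is invariant to read order.  Contigs shorter than
    ``min_contig_len`` are dropped.  This is a deliberately simple
    assembler for high-identity reads, not a general-purpose one.
    """
    kmers: set[str] = set()
    for r in reads:
        seq = r[1] if isinstance(r, tuple) else r
        kmers |= canonical_kmers(seq, k)
    if not kmers:
        return {}

    def succ(s: str) -> list[str]:
        return [s[1:] + b for b in _BASES if canonical(s[1:] + b) in kmers]

    def pred(s: str) -> list[str]:
        return [b + s[:-1] for b in _BASES if canonical(b + s[:-1]) in kmers]

    visited: set[str] = set()
    contigs: set[str] = set()
    for km in sorted(kmers):
        if km in visited:
            continue
        visited.add(km)
        seq = km
        # extend right
        cur = km
        while True:
            nxts = succ(cur)
            if len(nxts) != 1:
                break
            nxt = nxts[0]
            if len(pred(nxt)) != 1 or canonical(nxt) in visited:
                break
            visited.add(canonical(nxt))
            seq += nxt[-1]
            cur = nxt
        # extend left
        cur = km
        while True:
            prvs = pred(cur)
            if len(prvs) != 1:
                break
            prv = prvs[0]
            if len(succ(prv)) != 1 or canonical(prv) in visited:
                break
            visited.add(canonical(prv))
            seq = prv[0] + seq
            cur = prv
        if len(seq) >= min_contig_len:
            contigs.add(min(seq, revcomp(seq)))
    return {f"contig_{i:05d}": s for i, s in enumerate(sorted(contigs))}


# ---------------------------------------------------------------------------
# genomic-depth classification
# ---------------------------------------------------------------------------


@dataclass
class CandidateYTranscript:
    """A male-restricted contig with its sexed genomic depth evidence."""

    id: str
    sequence: str
    male_depth: float
    female_depth: float
    verdict: str  # retained | rejected_low_male | rejected_high_male | rejected_female_cov

    VERDICTS = ("retained", "rejected_low_male", "rejected_high_male", "rejected_female_cov")


@dataclass
class _SeqIndex:
    k: int
    seqs: list[str]
    # canonical k-mer -> list of (seq_idx, pos, is_rc_of_stored)
    table: dict[str, list[tuple[int, int, bool]]] = field(default_factory=dict)


def _build_seq_index(seqs: Sequence[str], k: int) -> _SeqIndex:
    idx = _SeqIndex(k=k, seqs=list(seqs))
    for si, seq in enumerate(seqs):
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            c = canonical(w)
            idx.table.setdefault(c, []).append((si, i, c != w))
    return idx


def mean_read_depth(
    targets: dict[str, str],
    reads: Iterable[tuple[str, str, str]],
    identity: float = 0.99,
    min_cov_frac: float = 0.9,
    k: int = 25,
) -> dict[str, float]:
    """Mean per-base depth of reads over each target at >= ``identity``.

    A read contributes where it aligns ungapped to a target at
    >= ``identity`` over >= ``min_cov_frac`` of its length (either
    strand).  Candidate placements are found by k-mer seeding: seed
    windows are probed on a stride small enough that any qualifying
    error-free placement yields at least two seeds.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    names = list(targets)
    idx = _build_seq_index([targets[n] for n in names], k)
    bases = [0.0] * len(names)
    for title, seq, _q in reads:
        seq = seq.upper()
        L = len(seq)
        if L < k:
            continue
        rc = seq.translate(_COMP)[::-1]
        min_olap = int(min_cov_frac * L + 0.9999)
        stride = max(1, (min_olap - k + 1) // 2)
        placed = False
        for j in range(0, L - k + 1, stride):
            w = seq[j : j + k]
            wrc = rc[L - k - j : L - j]
            c = w if w <= wrc else wrc
            hits = idx.table.get(c)
            if not hits:
                continue
            for si, pos, stored_rc in hits:
                target = idx.seqs[si]
                # orientation of the read relative to the target occurrence
                forward = (c != w) == stored_rc
                query = seq if forward else rc
                qoff = j if forward else L - k - j
                start_t = pos - qoff
                t0 = max(start_t, 0)
                t1 = min(start_t + L, len(target))
                olap = t1 - t0
                if olap < min_olap:
                    continue
                q0 = t0 - start_t
                sub_q = query[q0 : q0 + olap]
                sub_t = target[t0:t1]
                matches = sum(a == b for a, b in zip(sub_q, sub_t))
                if matches / olap >= identity - 1e-12:
                    bases[si] += olap
                    placed = True
                    break
            if placed:
                break
    return {n: bases[i] / len(targets[n]) for i, n in enumerate(names)}


def classify_by_genomic_coverage(
    contigs: dict[str, str],
    male_dna: Iterable[tuple[str, str, str]],
    female_dna: Iterable[tuple[str, str, str]],
    identity: float = 0.99,
    male_depth_window: tuple[float, float] = (4.0, 14.0),
    female_depth_max: float = 0.0,
    min_cov_frac: float = 0.9,
    k: int = 25,
) -> list[CandidateYTranscript]:
    """Apply the sexed genomic depth filter to candidate contigs.

    A contig is retained iff its mean male genomic depth falls inside
    ``male_depth_window`` (inclusive, default the hemizygous 4x-14x band
    at 20x diploid sequencing) and its mean female depth does not exceed
    ``female_depth_max`` (default strictly zero).  Female coverage takes
    precedence over the male window in the rejection verdict.
    """
    if not contigs:
        raise ValueError("no contigs to classify")
    lo, hi = male_depth_window
    m_depth = mean_read_depth(contigs, male_dna, identity, min_cov_frac, k)
    f_depth = mean_read_depth(contigs, female_dna, identity, min_cov_frac, k)
    out = []
    for name, seq in contigs.items():
        md, fd = m_depth[name], f_depth[name]
        if fd > female_depth_max:
            verdict = "rejected_female_cov"
        elif md < lo:
            verdict = "rejected_low_male"
        elif md > hi:
            verdict = "rejected_high_male"
        else:
            verdict = "retained"
        out.append(CandidateYTranscript(name, seq, md, fd, verdict))
    return out
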