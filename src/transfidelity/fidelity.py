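"""Transcription error rates from RNA-seq mismatches.

The statistic: for each read position p (1-based, in sequencing direction),
the total error rate is the percentage of reads with a mismatched base at p,

    E(p) = 100 * M(p) / N(p),

and the substitution-specific rate for ref>obs type s is
E(p, s) = 100 * M(p, s) / N(p). A base contributes to the denominator N(p)
only if it passes the inclusion predicates: neither read nor reference base
is N, the base call's Phred score is at least ``qmin`` (default 30, i.e.
bases with quality < 30 are excluded), and the reference position is not in
the genomic-variant mask. M counts the included bases that mismatch the
reference. Excluding sub-threshold calls from numerator and denominator
symmetrically keeps E(p) a proper per-base frequency; the numerator-only
alternative is available via ``threshold_numerator_only``.

Upstream of the statistic, alignments are filtered to unique placements with
at most three mismatches (mirroring an ungapped, substitution-only alignment
model), and fixed genomic single-base variants are masked by a transparent
frequency-consensus caller so that strain differences from the reference are
not mistaken for transcription errors.

Coordinates: reference positions are 0-based internally (1-based only at the
SAM/VCF boundary); read positions are 1-based in sequencing direction, so a
reverse-strand alignment is flipped into read orientation before indexing
and its substitution types are reported on the RNA-level (read) strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from ._alphabet import (
    BASES,
    N_CODE,
    SUBSTITUTIONS,
    complement,
    encode,
    substitution_index,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "VariantMask",
    "MismatchEvent",
    "ErrorRateTable",
    "SampleComparison",
    "read_alignments",
    "trim_reads",
    "filter_alignments",
    "call_variant_mask",
    "extract_mismatches",
    "compute_error_table",
    "specific_error_rate",
    "compare_samples",
]


@dataclass
class AlignedRead:
    """One aligned read in sequencing (read) orientation.

    ``seq_codes``, ``quals``, ``ref_codes`` and ``ref_positions`` are all
    indexed by read position - 1; for a reverse-strand alignment they have
    been reverse-complemented / reversed relative to the SAM record, so
    ``ref_positions`` is descending.
    """

    name: str
    reference_name: str
    ref_start: int
    is_reverse: bool
    seq_codes: np.ndarray      # int8, 0-3 or 4 for N
    quals: np.ndarray          # int Phred scores
    ref_codes: np.ndarray      # reference bases in read orientation
    ref_positions: np.ndarray  # 0-based reference position per read base
    is_unique: bool
    n_mismatches: int

    def __post_init__(self) -> None:
        if not (len(self.seq_codes) == len(self.quals) == len(self.ref_codes) == len(self.ref_positions)):
            raise ValueError("sequence, qualities and reference window must have equal length")

    def __len__(self) -> int:
        return len(self.seq_codes)

    @property
    def sequence(self) -> str:
        from ._alphabet import decode

        return decode(self.seq_codes)

    def recount_mismatches(self) -> int:
        return int(np.count_nonzero(self.seq_codes != self.ref_codes))


@dataclass(frozen=True)
class MismatchEvent:
    """One qualifying mismatch between a read base and the reference."""

    read_id: str
    read_pos: int   # 1-based, sequencing direction
    ref_pos: int    # 0-based
    ref_base: str
    read_base: str
    quality: int


@dataclass
class VariantMask:
    """Reference positions excluded as genomic single-base variants."""

    positions: frozenset[int]
    evidence: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["pos", "coverage", "alt_base", "alt_fraction"])
    )

    def __contains__(self, pos: int) -> bool:
        return pos in self.positions

    def __len__(self) -> int:
        return len(self.positions)

    def lookup(self, genome_length: int) -> np.ndarray:
        """Boolean per-reference-position mask array."""
        arr = np.zeros(genome_length, dtype=bool)
        if self.positions:
            arr[np.fromiter(self.positions, dtype=np.int64)] = True
        return arr

    @classmethod
    def empty(cls) -> "VariantMask":
        return cls(positions=frozenset())

    @classmethod
    def from_positions(cls, positions: Iterable[int]) -> "VariantMask":
        return cls(positions=frozenset(int(p) for p in positions))

    @classmethod
    def from_vcf(cls, path: Path | str) -> "VariantMask":
        """Load a mask override from a minimal VCF (POS is 1-based)."""
        positions = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.split("\t")
                positions.append(int(fields[1]) - 1)
        return cls.from_positions(positions)


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

def _load_reference(fasta_path: Path | str) -> dict[str, np.ndarray]:
    return {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")}


def _single_match_run(aln: pysam.AlignedSegment) -> bool:
    cig = aln.cigartuples
    return cig is not None and len(cig) == 1 and cig[0][0] == 0  # one M op


def read_alignments(sam_path: Path | str, fasta_path: Path | str) -> list[AlignedRead]:
    """Load mapped SAM records against their reference as AlignedRead.

    Unmapped records are skipped silently; records whose CIGAR is anything
    but a single match run (the substitution-only alignment model) are
    skipped with a warning. Uniqueness requires the record to be neither
    secondary nor supplementary and, when an NH tag is present, NH == 1.
    """
    refs = _load_reference(fasta_path)
    reads: list[AlignedRead] = []
    n_skipped_cigar = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if not _single_match_run(aln):
                n_skipped_cigar += 1
                continue
            if aln.reference_name not in refs:
                raise ValueError(f"reference {aln.reference_name!r} not in FASTA")
            ref = refs[aln.reference_name]
            start = aln.reference_start
            seq = encode(aln.query_sequence)
            quals = np.asarray(aln.query_qualities, dtype=np.int16)
            end = start + len(seq)
            if end > len(ref):
                raise ValueError(f"read {aln.query_name!r} overhangs the reference")
            window = ref[start:end]
            positions = np.arange(start, end, dtype=np.int64)
            if aln.is_reverse:
                seq = complement(seq)[::-1].copy()
                quals = quals[::-1].copy()
                window = complement(window)[::-1].copy()
                positions = positions[::-1].copy()
            unique = not (aln.is_secondary or aln.is_supplementary)
            if unique and aln.has_tag("NH"):
                unique = aln.get_tag("NH") == 1
            reads.append(
                AlignedRead(
                    name=aln.query_name,
                    reference_name=aln.reference_name,
                    ref_start=start,
                    is_reverse=aln.is_reverse,
                    seq_codes=seq,
                    quals=quals,
                    ref_codes=window,
                    ref_positions=positions,
                    is_unique=unique,
                    n_mismatches=int(np.count_nonzero(seq != window)),
                )
            )
    if n_skipped_cigar:
        logger.warning("skipped %d records with non-single-M CIGAR", n_skipped_cigar)
    logger.info("loaded %d aligned reads", len(reads))
    return reads


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def trim_reads(reads: Sequence[AlignedRead], keep_first: int, drop_first: int = 0) -> list[AlignedRead]:
    """Fixed-window trim: drop the first ``drop_first`` bases, keep the next
    ``keep_first``. Read positions renumber from the trimmed start."""
    if drop_first < 0 or keep_first <= 0:
        raise ValueError("drop_first must be >= 0 and keep_first >= 1")
    out = []
    for r in reads:
        if drop_first + keep_first > len(r):
            raise ValueError(
                f"trim window {drop_first}+{keep_first} exceeds read length {len(r)} for {r.name!r}"
            )
        sl = slice(drop_first, drop_first + keep_first)
        seq = r.seq_codes[sl].copy()
        win = r.ref_codes[sl].copy()
        pos = r.ref_positions[sl].copy()
        out.append(
            replace(
                r,
                ref_start=int(pos.min()),
                seq_codes=seq,
                quals=r.quals[sl].copy(),
                ref_codes=win,
                ref_positions=pos,
                n_mismatches=int(np.count_nonzero(seq != win)),
            )
        )
    return out


def filter_alignments(
    reads: Sequence[AlignedRead], max_mismatches: int | float = 3, unique_only: bool = True
) -> list[AlignedRead]:
    """Keep reads with at most ``max_mismatches`` mismatches and, if
    ``unique_only``, a unique placement — the -n 3 -m 1 alignment policy."""
    kept = [
        r
        for r in reads
        if r.n_mismatches <= max_mismatches and (r.is_unique or not unique_only)
    ]
    logger.info("alignment filter kept %d / %d reads", len(kept), len(reads))
    return kept


# ---------------------------------------------------------------------------
# variant masking
# ---------------------------------------------------------------------------

def call_variant_mask(
    reads: Sequence[AlignedRead],
    reference: str | np.ndarray,
    min_coverage: int = 10,
    alt_fraction: float = 0.8,
    qmin: int = 30,
) -> VariantMask:
    """Frequency-consensus single-base-variant caller.

    A reference position is masked iff its coverage by quality-passing
    (Phred >= qmin, non-N) read bases reaches ``min_coverage`` and the
    single most frequent non-reference base accounts for at least
    ``alt_fraction`` of those bases. If two alternative bases tie for most
    frequent, the position is masked when their combined fraction clears the
    threshold (conservative exclusion; logged).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    if not 0.5 < alt_fraction <= 1.0:
        raise ValueError("alt_fraction must lie in (0.5, 1]")
    ref_codes = reference if isinstance(reference, np.ndarray) else encode(reference)
    L = len(ref_codes)
    counts = np.zeros((L, 4), dtype=np.int64)
    for r in reads:
        ok = (r.seq_codes != N_CODE) & (r.ref_codes != N_CODE) & (r.quals >= qmin)
        np.add.at(counts, (r.ref_positions[ok], r.seq_codes[ok]), 1)

    coverage = counts.sum(axis=1)
    ref_counts = counts[np.arange(L), np.clip(ref_codes, 0, 3)]
    ref_counts = np.where(ref_codes == N_CODE, 0, ref_counts)
    alt_total = coverage - ref_counts
    candidates = np.nonzero((coverage >= min_coverage) & (alt_total > 0))[0]

    rows = []
    positions = []
    n_ties = 0
    for p in candidates:
        row = counts[p].copy()
        if ref_codes[p] != N_CODE:
            row[ref_codes[p]] = 0
        top = row.max()
        tied = np.nonzero(row == top)[0]
        count = int(top if len(tied) == 1 else row[tied].sum())
        frac = count / coverage[p]
        if frac >= alt_fraction:
            if len(tied) > 1:
                n_ties += 1
            positions.append(int(p))
            rows.append(
                {
                    "pos": int(p),
                    "coverage": int(coverage[p]),
                    "alt_base": BASES[int(tied[0])],
                    "alt_fraction": float(frac),
                }
            )
    if n_ties:
        logger.warning("%d masked positions had tied alternative bases", n_ties)
    logger.info("variant mask: %d positions", len(positions))
    evidence = pd.DataFrame(rows, columns=["pos", "coverage", "alt_base", "alt_fraction"])
    return VariantMask(positions=frozenset(positions), evidence=evidence)


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def _included(read: AlignedRead, mask_lookup: np.ndarray | None, qmin: int) -> np.ndarray:
    inc = (read.seq_codes != N_CODE) & (read.ref_codes != N_CODE) & (read.quals >= qmin)
    if mask_lookup is not None:
        inc &= ~mask_lookup[read.ref_positions]
    return inc


def extract_mismatches(
    read: AlignedRead,
    reference: str | np.ndarray | None = None,
    mask: VariantMask | None = None,
    qmin: int = 30,
) -> list[MismatchEvent]:
    """Qualifying mismatch events for one read.

    A position yields an event iff read base != reference base, neither is
    N, the call's Phred >= qmin, and the reference position is unmasked.
    ``reference`` is accepted for interface symmetry but the read's own
    reference window (fixed at load time) is authoritative.
    """
    mask_pos = mask.positions if mask is not None else frozenset()
    inc = (read.seq_codes != N_CODE) & (read.ref_codes != N_CODE) & (read.quals >= qmin)
    mm = inc & (read.seq_codes != read.ref_codes)
    events = []
    for j in np.nonzero(mm)[0]:
        p = int(read.ref_positions[j])
        if p in mask_pos:
            continue
        events.append(
            MismatchEvent(
                read_id=read.name,
                read_pos=int(j) + 1,
                ref_pos=p,
                ref_base=BASES[read.ref_codes[j]],
                read_base=BASES[read.seq_codes[j]],
                quality=int(read.quals[j]),
            )
        )
    return events


@dataclass
class ErrorRateTable:
    """Per-read-position mismatch counts and rates.

    Row p (1-based read position) holds the denominator N(p), the mismatch
    count M(p) and the per-substitution counts M(p, s) for the 12 ref>obs
    types. Rates are percentages; positions with N(p) = 0 report NaN
    (undefined, distinct from an observed 0%).
    """

    N: np.ndarray          # (P,) denominators
    M: np.ndarray          # (P,) mismatch counts
    M_sub: np.ndarray      # (P, 12)
    qmin: int = 30

    def __post_init__(self) -> None:
        if not np.array_equal(self.M_sub.sum(axis=1), self.M):
            raise AssertionError("substitution counts do not decompose the mismatch count")
        if (self.M > self.N).any():
            raise AssertionError("mismatch count exceeds denominator")

    @property
    def n_positions(self) -> int:
        return len(self.N)

    def total_rate(self, read_pos: int) -> float:
        """E(p) in percent; NaN when undefined (N(p) = 0)."""
        i = self._index(read_pos)
        return 100.0 * self.M[i] / self.N[i] if self.N[i] > 0 else float("nan")

    def rate_profile(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.N > 0, 100.0 * self.M / np.maximum(self.N, 1), np.nan)

    def _index(self, read_pos: int) -> int:
        if not 1 <= read_pos <= self.n_positions:
            raise IndexError(f"read position {read_pos} outside 1..{self.n_positions}")
        return read_pos - 1

    def substitution_rate(self, read_pos: int, substitution: str) -> float:
        i = self._index(read_pos)
        s = SUBSTITUTIONS.index(substitution)
        if self.N[i] == 0:
            return float("nan")
        return 100.0 * self.M_sub[i, s] / self.N[i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "read_pos": np.arange(1, self.n_positions + 1),
                "N": self.N,
                "M": self.M,
                "E_percent": self.rate_profile(),
            }
        )
        for s, name in enumerate(SUBSTITUTIONS):
            df[f"M_{name}"] = self.M_sub[:, s]
        return df

    def to_tsv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def compute_error_table(
    reads: Sequence[AlignedRead],
    reference: str | np.ndarray | None = None,
    mask: VariantMask | None = None,
    qmin: int = 30,
    threshold_numerator_only: bool = False,
) -> ErrorRateTable:
    """Accumulate N(p), M(p) and M(p, s) over filtered reads.

    With the default symmetric threshold, a base below ``qmin`` is excluded
    from numerator and denominator alike; with
    ``threshold_numerator_only=True`` the denominator keeps all non-N,
    unmasked bases and only mismatches are quality-thresholded.
    """
    max_len = max((len(r) for r in reads), default=0)
    N = np.zeros(max_len, dtype=np.int64)
    M = np.zeros(max_len, dtype=np.int64)
    M_sub = np.zeros((max_len, 12), dtype=np.int64)
    if max_len == 0:
        return ErrorRateTable(N=N, M=M, M_sub=M_sub, qmin=qmin)

    if mask is not None and len(mask) > 0:
        max_ref = max(int(r.ref_positions.max()) for r in reads) + 1
        if reference is not None:
            max_ref = max(max_ref, len(reference))
        lookup = mask.lookup(max_ref)
    else:
        lookup = None

    # batch same-length reads into matrices so the hot path is vectorized
    by_len: dict[int, list[AlignedRead]] = {}
    for r in reads:
        by_len.setdefault(len(r), []).append(r)

    for L, group in by_len.items():
        seq = np.stack([r.seq_codes for r in group])
        win = np.stack([r.ref_codes for r in group])
        quals = np.stack([r.quals for r in group])
        base_ok = (seq != N_CODE) & (win != N_CODE)
        if lookup is not None:
            pos = np.stack([r.ref_positions for r in group])
            base_ok &= ~lookup[pos]
        q_ok = quals >= qmin
        denom = base_ok if threshold_numerator_only else (base_ok & q_ok)
        numer = base_ok & q_ok & (seq != win)
        N[:L] += denom.sum(axis=0)
        M[:L] += numer.sum(axis=0)
        rr, cc = np.nonzero(numer)
        if rr.size:
            s_idx = substitution_index(win[rr, cc], seq[rr, cc])
            np.add.at(M_sub, (cc, s_idx), 1)

    return ErrorRateTable(N=N, M=M, M_sub=M_sub, qmin=qmin)


def specific_error_rate(table: ErrorRateTable, read_pos: int = 7, substitution: str = "C>T") -> float:
    """E(read_pos, substitution) in percent; raises when undefined."""
    if substitution not in SUBSTITUTIONS:
        raise ValueError(f"unknown substitution {substitution!r}")
    rate = table.substitution_rate(read_pos, substitution)
    if np.isnan(rate):
        raise ValueError(f"rate undefined at read position {read_pos} (no included bases)")
    return rate


@dataclass
class SampleComparison:
    """Ratio of two samples' specific error rates, as a percentage."""

    ratio_percent: float
    se_percent: float
    read_pos: int
    substitution: str


def compare_samples(
    table_a: ErrorRateTable,
    table_b: ErrorRateTable,
    read_pos: int = 7,
    substitution: str = "C>T",
) -> SampleComparison:
    """100 * E_a / E_b at one read position, with a binomial standard error.

    The s.e. treats M_a and M_b as independent binomial counts:
    se(ratio)/ratio = sqrt((1-p_a)/M_a + (1-p_b)/M_b).
    """
    e_a = specific_error_rate(table_a, read_pos, substitution)
    e_b = specific_error_rate(table_b, read_pos, substitution)
    if e_b == 0:
        raise ValueError("reference sample rate is zero; ratio undefined")
    ratio = 100.0 * e_a / e_b
    s = SUBSTITUTIONS.index(substitution)
    i_a, i_b = read_pos - 1, read_pos - 1
    m_a, n_a = table_a.M_sub[i_a, s], table_a.N[i_a]
    m_b, n_b = table_b.M_sub[i_b, s], table_b.N[i_b]
    if m_a > 0 and m_b > 0:
        rel_var = (1 - m_a / n_a) / m_a + (1 - m_b / n_b) / m_b
        se = ratio * float(np.sqrt(rel_var))
    else:
        se = float("nan")
    return SampleComparison(ratio_percent=ratio, se_percent=se, read_pos=read_pos, substitution=substitution)
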