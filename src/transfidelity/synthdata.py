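"""Synthetic RNA-seq and kinetics data with known ground truth.

This module emulates the statistical structure that the error-rate statistic
assumes: strand-specific reads drawn from a reference genome, carrying three
independently controlled mismatch sources —

* transcription errors, injected per base with a 4x4 substitution matrix
  (the RNA-level channel the pipeline is meant to recover),
* sequencing errors, injected per base with probability 10**(-Q/10) for the
  base's sampled Phred score Q (quality-correlated noise),
* genomic single-base variants (SNVs), fixed differences between the sample
  genome the reads come from and the reference they are aligned to.

Every injected event is recorded in a truth table so downstream estimates can
be compared against exact expectations. A separate generator draws noisy
kinetic series (exponential time courses, Michaelis-Menten titrations,
Arrhenius temperature series, pH profiles) from the models in
:mod:`transfidelity.kinetics`.

All randomness flows from a single integer seed through
``numpy.random.default_rng([seed, stage])`` so each stage is independently
reproducible and identical configs give byte-identical output files.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._alphabet import BASES, N_CODE, decode, encode, substitution_name
from .kinetics import MODEL_NAMES, KineticSeries, model_function

__all__ = [
    "QualityProfile",
    "SimConfig",
    "GenomeSim",
    "ReadSim",
    "KineticSimSpec",
    "substitution_matrix",
    "simulate_genome",
    "simulate_reads",
    "simulate_kinetics",
    "write_read_sim",
]

TRUTH_COLUMNS = ["read_id", "read_pos", "ref_pos", "event_class", "ref_base", "obs_base"]


@dataclass(frozen=True)
class QualityProfile:
    """Per-read-position Phred score model.

    Mean Phred declines linearly from ``mean_start`` at read position 1 to
    ``mean_end`` at the last position; per-base scores are Gaussian around
    that mean with standard deviation ``sd``, rounded and truncated to
    ``[qmin, qmax]``. The default (38 -> 28, sd 3, clipped to [2, 41])
    produces a realistic mixture of bases above and below a Q30 threshold.
    """

    mean_start: float = 38.0
    mean_end: float = 28.0
    sd: float = 3.0
    qmin: int = 2
    qmax: int = 41

    def position_means(self, read_length: int) -> np.ndarray:
        return np.linspace(self.mean_start, self.mean_end, read_length)

    @classmethod
    def constant(cls, q: float) -> "QualityProfile":
        """A degenerate profile with every base at Phred ``q`` exactly."""
        return cls(mean_start=q, mean_end=q, sd=0.0, qmin=2, qmax=max(41, int(np.ceil(q))))


def substitution_matrix(**rates: float) -> np.ndarray:
    """Build a 4x4 off-diagonal substitution-probability matrix.

    Keyword names are substitution labels such as ``CT=1e-3`` or, via dict
    unpacking, ``{"C>T": 1e-3}``. Unnamed entries are zero.
    """
    m = np.zeros((4, 4))
    for name, rate in rates.items():
        label = name.replace(">", "")
        if len(label) != 2 or label[0] not in BASES or label[1] not in BASES:
            raise ValueError(f"unknown substitution {name!r}")
        r, o = BASES.index(label[0]), BASES.index(label[1])
        if r == o:
            raise ValueError(f"substitution {name!r} is not a substitution")
        m[r, o] = rate
    return m


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic sequencing experiment."""

    genome_length: int = 10_000
    gc_content: float = 0.5
    n_reads: int = 1_000
    read_length: int = 50
    transcription_error_matrix: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    snv_fraction: float = 0.0
    quality_profile: QualityProfile = field(default_factory=QualityProfile)
    seed: int = 0
    reference_name: str = "ref1"
    include_reverse: bool = False
    #: disable the quality-correlated sequencing-error channel entirely
    #: (Phred scores are still sampled and reported)
    sequencing_errors: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.transcription_error_matrix, dtype=float).copy()
        if m.shape != (4, 4):
            raise ValueError("transcription_error_matrix must be 4x4")
        np.fill_diagonal(m, 0.0)
        if (m < 0).any() or (m > 1).any():
            raise ValueError("substitution probabilities must lie in [0, 1]")
        if (m.sum(axis=1) > 1.0 + 1e-12).any():
            raise ValueError("off-diagonal row sums of the error matrix must be <= 1")
        object.__setattr__(self, "transcription_error_matrix", m)
        if not 0.0 <= self.snv_fraction <= 1.0:
            raise ValueError("snv_fraction must lie in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly between 0 and 1")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")
        if self.genome_length < 100:
            raise ValueError("genome_length must be >= 100")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


@dataclass
class GenomeSim:
    """Reference genome, the sample genome reads are drawn from, and the
    true variant list separating the two."""

    reference: str
    sample: str
    variants: pd.DataFrame  # columns: pos (0-based), ref, alt
    name: str = "ref1"

    @property
    def variant_positions(self) -> np.ndarray:
        return self.variants["pos"].to_numpy(dtype=np.int64)


@dataclass
class ReadSim:
    """Simulated reads with their true placements and event truth table."""

    ids: list[str]
    seqs: np.ndarray          # (n_reads, read_length) int8 base codes, read orientation
    quals: np.ndarray         # (n_reads, read_length) int Phred scores, read orientation
    starts: np.ndarray        # 0-based leftmost reference position
    is_reverse: np.ndarray    # bool per read
    truth: pd.DataFrame       # TRUTH_COLUMNS
    reference_name: str
    read_length: int

    def ref_positions(self, i: int) -> np.ndarray:
        """0-based reference position of each read base, in sequencing order."""
        fwd = self.starts[i] + np.arange(self.read_length)
        return fwd[::-1].copy() if self.is_reverse[i] else fwd

    def to_aligned_reads(self, genome: GenomeSim, start: int = 0, stop: int | None = None):
        """Adapt to the fidelity module's AlignedRead without a SAM round trip.

        ``start``/``stop`` select a read range, letting very large
        simulations be processed in bounded-memory chunks.
        """
        from .fidelity import AlignedRead

        ref_codes = encode(genome.reference)
        reads = []
        stop = len(self.ids) if stop is None else min(stop, len(self.ids))
        for i in range(start, stop):
            rid = self.ids[i]
            pos = self.ref_positions(i)
            win = ref_codes[pos]
            seq = self.seqs[i]
            reads.append(
                AlignedRead(
                    name=rid,
                    reference_name=self.reference_name,
                    ref_start=int(self.starts[i]),
                    is_reverse=bool(self.is_reverse[i]),
                    seq_codes=seq.copy(),
                    quals=self.quals[i].copy(),
                    ref_codes=win.copy(),
                    ref_positions=pos,
                    is_unique=True,
                    n_mismatches=int(np.count_nonzero(seq != win)),
                )
            )
        return reads


def _rng(seed: int, stage: int) -> np.random.Generator:
    # independent, reproducible stream per pipeline stage
    return np.random.default_rng([int(seed), int(stage)])


def simulate_genome(config: SimConfig) -> GenomeSim:
    """Draw a random genome and a sample genome differing at SNV positions.

    The number of variant positions is exactly
    ``round(genome_length * snv_fraction)``; each variant base is drawn
    uniformly from the three alternatives to the reference base.
    """
    rng = _rng(config.seed, 0)
    L = config.genome_length
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    ref = rng.choice(4, size=L, p=probs).astype(np.int8)

    n_var = int(round(L * config.snv_fraction))
    pos = np.sort(rng.choice(L, size=n_var, replace=False))
    alt = ((ref[pos] + rng.integers(1, 4, size=n_var)) % 4).astype(np.int8)

    sample = ref.copy()
    sample[pos] = alt
    variants = pd.DataFrame(
        {
            "pos": pos.astype(np.int64),
            "ref": [BASES[b] for b in ref[pos]],
            "alt": [BASES[b] for b in alt],
        }
    )
    return GenomeSim(
        reference=decode(ref), sample=decode(sample), variants=variants,
        name=config.reference_name,
    )


def simulate_reads(config: SimConfig, genome: GenomeSim) -> ReadSim:
    """Draw reads from the sample genome and inject the error channels.

    Per base, a transcription error is applied first (probability from the
    config matrix row of the template base), then a sequencing error with
    probability ``10**(-Q/10)`` for the base's sampled Phred Q; a sequencing
    error replaces the current base with one of the three alternatives
    uniformly. Both events are recorded when they hit the same base; the
    truth table stores each event's before (ref_base) and after (obs_base)
    base so chains resolve to the emitted read base.
    """
    if len(genome.reference) != len(genome.sample):
        raise ValueError("reference and sample genome must have equal length")
    L, rl, n = len(genome.reference), config.read_length, config.n_reads
    if rl > L:
        raise ValueError("read_length exceeds genome length")

    rng = _rng(config.seed, 1)
    ref_codes = encode(genome.reference)
    sample_codes = encode(genome.sample)

    starts = rng.integers(0, L - rl + 1, size=n)
    if config.include_reverse:
        is_reverse = rng.random(n) < 0.5
    else:
        is_reverse = np.zeros(n, dtype=bool)

    # per-base reference positions in sequencing direction
    offs = np.arange(rl)
    pos_mat = starts[:, None] + offs[None, :]
    if config.include_reverse:
        pos_mat = np.where(is_reverse[:, None], starts[:, None] + (rl - 1 - offs)[None, :], pos_mat)

    ref_mat = ref_codes[pos_mat]
    tmpl = sample_codes[pos_mat]  # template the polymerase copies
    if config.include_reverse:
        # reverse reads observe the complementary strand in sequencing order
        comp = np.array([3, 2, 1, 0], dtype=np.int8)
        ref_mat = np.where(is_reverse[:, None], comp[ref_mat], ref_mat)
        tmpl = np.where(is_reverse[:, None], comp[tmpl], tmpl)

    # --- transcription-error channel ---------------------------------------
    m = config.transcription_error_matrix
    row_tot = m.sum(axis=1)
    cum = np.cumsum(m, axis=1)
    u = rng.random(size=tmpl.shape)
    t_err = u < row_tot[tmpl]
    after_tx = tmpl.copy()
    if t_err.any():
        hit_cum = cum[tmpl[t_err]]                       # (n_hits, 4)
        alt = (u[t_err, None] < hit_cum).argmax(axis=1)  # first interval containing u
        after_tx[t_err] = alt.astype(np.int8)

    # --- sequencing-error channel -------------------------------------------
    qp = config.quality_profile
    means = qp.position_means(rl)
    q = np.rint(rng.normal(means[None, :], qp.sd, size=tmpl.shape))
    q = np.clip(q, qp.qmin, qp.qmax).astype(np.int16)
    if config.sequencing_errors:
        p_seq = 10.0 ** (-q / 10.0)
        s_err = rng.random(size=tmpl.shape) < p_seq
    else:
        s_err = np.zeros(tmpl.shape, dtype=bool)
    final = after_tx.copy()
    if s_err.any():
        shift = rng.integers(1, 4, size=int(s_err.sum()))
        final[s_err] = ((after_tx[s_err] + shift) % 4).astype(np.int8)

    ids = [f"read{i:07d}" for i in range(n)]

    # --- truth table ----------------------------------------------------------
    snv_mask = tmpl != ref_mat
    frames = []
    for cls, mask, before, after in (
        ("snv", snv_mask, ref_mat, tmpl),
        ("transcription_error", t_err, tmpl, after_tx),
        ("sequencing_error", s_err, after_tx, final),
    ):
        r, c = np.nonzero(mask)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [ids[i] for i in r],
                    "read_pos": c + 1,
                    "ref_pos": pos_mat[r, c],
                    "event_class": cls,
                    "ref_base": [BASES[b] for b in before[r, c]],
                    "obs_base": [BASES[b] for b in after[r, c]],
                }
            )
        )
    truth = pd.concat(frames, ignore_index=True)
    # causal order within a site: snv, then transcription, then sequencing
    order = {"snv": 0, "transcription_error": 1, "sequencing_error": 2}
    truth["_ord"] = truth["event_class"].map(order)
    truth = truth.sort_values(["read_id", "read_pos", "_ord"], kind="stable").reset_index(drop=True)
    truth = truth.drop(columns="_ord")

    return ReadSim(
        ids=ids,
        seqs=final,
        quals=q,
        starts=starts.astype(np.int64),
        is_reverse=is_reverse,
        truth=truth[TRUTH_COLUMNS],
        reference_name=genome.name,
        read_length=rl,
    )


# ---------------------------------------------------------------------------
# file writers (all plain text, deterministic)
# ---------------------------------------------------------------------------

def write_fasta(path: Path | str, name: str, sequence: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def write_variants(genome: GenomeSim, vcf_path: Path | str, tsv_path: Path | str | None = None) -> None:
    """Write the true variant list as minimal VCF (and optionally TSV)."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.name},length={len(genome.reference)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\n")
        for row in genome.variants.itertuples(index=False):
            fh.write(f"{genome.name}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\n")
    if tsv_path is not None:
        genome.variants.to_csv(tsv_path, sep="\t", index=False)


def write_fastq(sim: ReadSim, path: Path | str) -> None:
    with open(path, "w") as fh:
        for i, rid in enumerate(sim.ids):
            seq = decode(sim.seqs[i])
            qual = "".join(chr(q + 33) for q in sim.quals[i])
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_sam(sim: ReadSim, genome: GenomeSim, path: Path | str) -> None:
    """True-placement SAM: FLAG 0/16, 1-based POS, single-M CIGAR, NH:i:1."""
    ref_codes = encode(genome.reference)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{genome.name}\tLN:{len(genome.reference)}\n")
        fh.write("@PG\tID:transfidelity\tPN:transfidelity\n")
        for i, rid in enumerate(sim.ids):
            seq = sim.seqs[i]
            qual = sim.quals[i]
            if sim.is_reverse[i]:
                # SAM stores reference-orientation sequence and qualities
                seq = np.array([3, 2, 1, 0], dtype=np.int8)[seq][::-1]
                qual = qual[::-1]
            win = ref_codes[sim.starts[i] : sim.starts[i] + sim.read_length]
            nm = int(np.count_nonzero(seq != win))
            flag = 16 if sim.is_reverse[i] else 0
            fh.write(
                f"{rid}\t{flag}\t{sim.reference_name}\t{sim.starts[i] + 1}\t42\t"
                f"{sim.read_length}M\t*\t0\t0\t{decode(seq)}\t"
                f"{''.join(chr(q + 33) for q in qual)}\tNM:i:{nm}\tNH:i:1\n"
            )


def write_truth(sim: ReadSim, path: Path | str) -> None:
    sim.truth.to_csv(path, sep="\t", index=False)


def write_read_sim(config: SimConfig, outdir: Path | str) -> tuple[GenomeSim, ReadSim]:
    """Simulate genome + reads and write the full file set into ``outdir``.

    Emits reference.fa, sample_genome.fa, variants.vcf/.tsv, reads.fastq,
    reads.sam and truth.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    sim = simulate_reads(config, genome)
    write_fasta(outdir / "reference.fa", genome.name, genome.reference)
    write_fasta(outdir / "sample_genome.fa", genome.name, genome.sample)
    write_variants(genome, outdir / "variants.vcf", outdir / "variants.tsv")
    write_fastq(sim, outdir / "reads.fastq")
    write_sam(sim, genome, outdir / "reads.sam")
    write_truth(sim, outdir / "truth.tsv")
    return genome, sim


# ---------------------------------------------------------------------------
# kinetic series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticSimSpec:
    """One simulated kinetic experiment.

    ``noise_sd`` is the standard deviation of Gaussian noise on the model's
    natural response scale: additive on the measured fraction or rate for the
    exponential and Michaelis-Menten models, and on the log response for the
    rate-valued profiles — ln k for Arrhenius and the pH titration (so
    noise_sd is approximately the fractional error, and rates stay
    positive), log10 k for the log-linear pH model.
    """

    model: str
    params: dict
    x: Sequence[float]
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; expected one of {sorted(MODEL_NAMES)}")
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("design points must be a non-empty 1-D sequence")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.model == "exponential" and (x < 0).any():
            raise ValueError("times must be >= 0")
        if self.model == "michaelis_menten" and (x <= 0).any():
            raise ValueError("concentrations must be > 0")
        if self.model == "arrhenius" and (x <= 0).any():
            raise ValueError("absolute temperatures must be > 0")
        object.__setattr__(self, "x", tuple(float(v) for v in x))


#: models whose noise acts on a log response (rates are measured with
#: roughly proportional error and must stay positive)
_LOG_NOISE = {"arrhenius": np.log, "ph_loglinear": np.log10, "ph_titration": np.log}
_LOG_NOISE_INV = {"arrhenius": np.exp, "ph_loglinear": lambda z: 10.0 ** z, "ph_titration": np.exp}


def simulate_kinetics(spec: KineticSimSpec) -> list[KineticSeries]:
    """Generate one noisy KineticSeries per replicate from the named model."""
    rng = _rng(spec.seed, 2)
    fn = model_function(spec.model)
    x = np.asarray(spec.x, dtype=float)
    clean = fn(x, **spec.params)
    out = []
    for rep in range(spec.n_replicates):
        eps = rng.normal(0.0, spec.noise_sd, size=x.size) if spec.noise_sd > 0 else 0.0
        if spec.model in _LOG_NOISE and spec.noise_sd > 0:
            y = _LOG_NOISE_INV[spec.model](_LOG_NOISE[spec.model](clean) + eps)
        else:
            y = clean + eps
        out.append(KineticSeries(x=x.copy(), y=np.asarray(y, dtype=float), condition=spec.condition or spec.model, replicate=rep))
    return out


def kinetics_to_frame(series: list[KineticSeries]) -> pd.DataFrame:
    """Tidy CSV layout: condition, x, y, replicate."""
    rows = []
    for s in series:
        for xi, yi in zip(s.x, s.y):
            rows.append({"condition": s.condition, "x": xi, "y": yi, "replicate": s.replicate})
    return pd.DataFrame(rows, columns=["condition", "x", "y", "replicate"])
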