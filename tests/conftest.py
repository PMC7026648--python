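import numpy as np
import pytest

import transfidelity as tf
from transfidelity._alphabet import SUBSTITUTIONS


def grid_search_sse(f, x, y, ranges, n=60, passes=5):
    """Independent SSE minimizer: iteratively refined 2-D grid scan."""
    lo = np.array([r[0] for r in ranges], dtype=float)
    hi = np.array([r[1] for r in ranges], dtype=float)
    best = None
    for _ in range(passes):
        g0 = np.linspace(lo[0], hi[0], n)
        g1 = np.linspace(lo[1], hi[1], n)
        pred = f(x[None, None, :], g0[:, None, None], g1[None, :, None])
        sse = ((pred - y[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        best = (g0[i], g1[j])
        step0, step1 = g0[1] - g0[0], g1[1] - g1[0]
        lo = np.array([max(lo[0], best[0] - 2 * step0), max(lo[1], best[1] - 2 * step1)])
        hi = np.array([best[0] + 2 * step0, best[1] + 2 * step1])
    return best


def naive_error_counts(reads, mask_positions=frozenset(), qmin=30):
    """Independent double-loop recount of N(p), M(p), M(p, s).

    Deliberately written with plain Python loops and explicit predicates so
    it shares no code path with compute_error_table.
    """
    max_len = max((len(r) for r in reads), default=0)
    N = [0] * max_len
    M = [0] * max_len
    M_sub = [[0] * 12 for _ in range(max_len)]
    for r in reads:
        for j in range(len(r)):
            b = int(r.seq_codes[j])
            w = int(r.ref_codes[j])
            q = int(r.quals[j])
            p = int(r.ref_positions[j])
            if b == 4 or w == 4:
                continue
            if q < qmin:
                continue
            if p in mask_positions:
                continue
            N[j] += 1
            if b != w:
                M[j] += 1
                sub = "ACGT"[w] + ">" + "ACGT"[b]
                M_sub[j][SUBSTITUTIONS.index(sub)] += 1
    return N, M, M_sub


def resolved_mismatches_from_truth(sim, genome):
    """Per-read mismatch count vs the REFERENCE genome, derived only from
    the truth table by chaining events at each (read, position) site."""
    ref = genome.reference
    per_site = {}
    for row in sim.truth.itertuples(index=False):
        key = (row.read_id, row.read_pos)
        per_site[key] = (row.ref_pos, row.obs_base)  # events are sorted; last wins
    counts = {rid: 0 for rid in sim.ids}
    for (rid, _), (ref_pos, final) in per_site.items():
        if final != ref[ref_pos]:
            counts[rid] += 1
    return counts


@pytest.fixture(scope="session")
def rich_dataset():
    """A mid-size dataset exercising all three mismatch channels at once."""
    cfg = tf.SimConfig(
        genome_length=20_000,
        gc_content=0.5,
        n_reads=12_000,
        read_length=50,
        transcription_error_matrix=tf.substitution_matrix(**{"C>T": 1e-3, "A>G": 5e-4}),
        snv_fraction=0.005,
        seed=11,
    )
    genome = tf.simulate_genome(cfg)
    sim = tf.simulate_reads(cfg, genome)
    reads = sim.to_aligned_reads(genome)
    return cfg, genome, sim, reads
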