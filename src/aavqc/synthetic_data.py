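"""Ground-truth-labelled synthetic inputs for the QC pipeline.

Real input to the pipeline is a BAM of HiFi reads aligned to the vector
plasmid and contaminant references.  This module fabricates that input
with known truth, emitting alignment records directly (no aligner in
the loop) so every downstream component can be tested hermetically:

* a toy vector genome — GC-rich palindromic ITRs flanking a random
  payload — plus synthetic contaminant references,
* reads of each DNA state with the exact alignment geometry the state
  implies (duplex: full match; fill-up/snapback: palindromic fold-back
  split across primary + one supplementary alignment; multimer: five
  fragments at non-adjacent positions),
* noisy spiking tables with a known dsDNA interference factor, and
* mass-photometry populations with a known length→mass map.

Reads are deterministic under the seed, down to byte-identical SAM.
HiFi reads are treated as sequence-accurate: no base-error or
quality-score model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .alignfeatures import AlignedRead, parse_record
from .quant import SpikingTable, KDA_PER_NT
from .refmodel import ReferenceModel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: ds/ss concentration design (ng/ul) of the published spiking experiment
SPIKING_DESIGN = ((10.0, 0.0), (6.67, 6.67), (5.0, 10.0), (3.33, 13.33), (0.0, 20.0))


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the read simulator.

    ``payload_length`` is the total vector-genome length including both
    ITRs (default: 3342 nt, a GFP-cassette-sized genome).  The state
    mix defaults to a population exercising all four DNA states, with
    fill-ups dominant as in a well-behaved second-strand synthesis.
    ``fold_jitter`` shifts fold points by up to the given nt to mimic
    imperfect symmetry at the fold (0 = ideal molecules).
    """

    payload_length: int = 3342
    itr_length: int = 145
    gc_content: float = 0.55
    state_mix: dict[str, float] = field(
        default_factory=lambda: {
            "duplex": 0.25,
            "fillup": 0.40,
            "snapback": 0.20,
            "multimer": 0.15,
        }
    )
    truncation_fraction: float = 0.2
    truncation_max: int = 800
    fold_jitter: int = 0
    contaminant_fraction: dict[str, float] = field(
        default_factory=lambda: {"human": 0.05, "ecoli": 0.03, "repcaphelper": 0.02}
    )
    n_reads: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.payload_length <= 2 * self.itr_length:
            raise ValueError("payload_length must exceed twice the ITR length")
        if self.fold_jitter < 0:
            raise ValueError("fold_jitter must be >= 0")
        mix_total = sum(self.state_mix.values())
        if not self.state_mix or mix_total <= 0:
            raise ValueError("state_mix is degenerate")
        if any(p < 0 for p in self.state_mix.values()):
            raise ValueError("state_mix probabilities must be >= 0")
        unknown = set(self.state_mix) - {"duplex", "fillup", "snapback", "multimer"}
        if unknown:
            raise ValueError(f"unknown states in mix: {sorted(unknown)}")
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError("state_mix must sum to 1")
        if not (0 <= sum(self.contaminant_fraction.values()) < 1):
            raise ValueError("contaminant fractions must sum to < 1")


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def make_itr(rng: np.random.Generator, length: int, gc: float = 0.8) -> str:
    """GC-rich random palindrome (reverse complement of itself up to a
    possible odd middle base) standing in for an ITR."""
    half = length // 2
    left = _random_seq(rng, half, gc)
    middle = _random_seq(rng, length - 2 * half, gc)
    return left + middle + revcomp(left)


def make_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> ReferenceModel:
    """Toy vector genome plus contaminant references.

    The genome is 5'ITR + random payload + 3'ITR where the 3' ITR is
    the reverse complement of the 5' one (inverted repeats).  Three
    contaminant references (human / ecoli / repcaphelper surrogates)
    are random sequences — the pipeline only uses them as alignment
    targets, never their biology.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    itr = make_itr(rng, cfg.itr_length)
    core = _random_seq(rng, cfg.payload_length - 2 * cfg.itr_length, cfg.gc_content)
    genome = itr + core + revcomp(itr)
    L = cfg.payload_length
    refs = [("vector_plasmid", genome, "vector")]
    for name, cat in (("human_frag", "human"), ("ecoli_frag", "ecoli"), ("repcaphelper", "repcaphelper")):
        refs.append((name, _random_seq(rng, 4000, 0.45), cat))
    return ReferenceModel(
        references=tuple(refs),
        genome_start=0,
        genome_end=L,
        itr_intervals=((0, cfg.itr_length), (L - cfg.itr_length, L)),
    )


def write_genome_fasta(model: ReferenceModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, _ in model.references:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_annotation_bed(model: ReferenceModel, path: str | Path) -> None:
    from .refmodel import write_annotations

    write_annotations(model, path)


@dataclass
class SimResult:
    """Simulated read set: reference model, truth table, SAM text."""

    model: ReferenceModel
    truth: pd.DataFrame
    header_lines: list[str]
    record_lines: list[str]

    def sam_text(self) -> str:
        return "\n".join(self.header_lines + self.record_lines) + "\n"

    def write_sam(self, path: str | Path) -> None:
        Path(path).write_text(self.sam_text())

    def write_truth_csv(self, path: str | Path) -> None:
        self.truth.to_csv(path, index=False)

    def write_reads_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for line in self.record_lines:
                fields = line.split("\t")
                fh.write(f">{fields[0]}\n{fields[9]}\n")

    def aligned_reads(self) -> list[AlignedRead]:
        """Parse the emitted records back through the standard parser."""
        names = [name for name, _, _ in self.model.references]
        lengths = [max(len(seq), 1) for _, seq, _ in self.model.references]
        header = pysam.AlignmentHeader.from_references(names, lengths)
        return [parse_record(line, header) for line in self.record_lines]


def _sam_line(
    qname: str,
    flag: int,
    rname: str,
    pos0: int,
    cigar: str,
    seq: str,
    sa_entries: Sequence[tuple[str, int, str, str]] = (),
) -> str:
    fields = [
        qname,
        str(flag),
        rname,
        str(pos0 + 1),
        "60",
        cigar,
        "*",
        "0",
        "0",
        seq,
        "*",
    ]
    if sa_entries:
        sa = "".join(f"{r},{p + 1},{s},{c},60,0;" for r, p, s, c in sa_entries)
        fields.append(f"SA:Z:{sa}")
    return "\t".join(fields)


def _allocate(n: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items to weighted bins."""
    keys = sorted(weights)
    total = sum(weights.values())
    raw = {k: n * weights[k] / total for k in keys}
    counts = {k: int(raw[k]) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_reads(model: ReferenceModel, cfg: SimConfig) -> SimResult:
    """Emit labelled reads of each DNA state as SAM records.

    Geometry per state (genome span ``[0, L)``, fragment ``[a, b)``):

    * duplex — the fragment itself, fully matched, no clipping;
    * fill-up — fragment reaching the 3' end, read = fragment +
      reverse complement folded at ``b`` inside the 3' ITR; primary
      covers the first half (50 % clip), one supplementary covers the
      second on the minus strand;
    * snapback — same fold-back geometry with ``b`` placed in the
      payload interior, away from both ITRs;
    * multimer — five equal fragments at non-adjacent positions; the
      primary covers the first query fragment (80 % clip), four
      supplementary entries cover the rest.

    Truncations shorten the underlying fragment from its 5' end.
    ``fold_jitter`` moves fill-up/snapback fold points by up to the
    configured nt.  The truth table records the planted label, fold
    point and clip fraction per read.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    L = model.genome_length
    vec = model.vector_name
    genome = model.vector_sequence
    itr_len = model.itr_intervals[0][1] - model.itr_intervals[0][0]

    contam_total = sum(cfg.contaminant_fraction.values())
    n_contam = _allocate(int(round(cfg.n_reads * contam_total)), cfg.contaminant_fraction) if contam_total else {}
    n_vector = cfg.n_reads - sum(n_contam.values())
    n_state = _allocate(n_vector, cfg.state_mix)

    records: list[str] = []
    truth_rows: list[dict] = []
    idx = 0

    def truncate(a: int, b: int) -> int:
        """Maybe shorten a fragment from its 5' end; returns new a."""
        if rng.random() < cfg.truncation_fraction:
            t = int(rng.integers(50, cfg.truncation_max + 1))
            return min(a + t, b - 200)
        return a

    for _ in range(n_state.get("duplex", 0)):
        a, b = truncate(0, L), L
        n = b - a
        seq = genome[a:b]
        records.append(_sam_line(f"read{idx:05d}", 0, vec, a, f"{n}M", seq))
        truth_rows.append(
            dict(read_id=f"read{idx:05d}", label="duplex", ref_name=vec, category="vector",
                 read_length=n, clip_fraction=0.0, n_supp=0, fold_point=np.nan,
                 span_left=a, span_right=b, aligned_bases=n)
        )
        idx += 1

    def foldback(label: str, a: int, b: int) -> None:
        nonlocal idx
        n = b - a
        frag = genome[a:b]
        read_seq = frag + revcomp(frag)
        cigar = f"{n}M{n}S"
        sa = [(vec, a, "-", f"{n}M{n}S")]
        records.append(_sam_line(f"read{idx:05d}", 0, vec, a, cigar, read_seq, sa))
        truth_rows.append(
            dict(read_id=f"read{idx:05d}", label=label, ref_name=vec, category="vector",
                 read_length=2 * n, clip_fraction=0.5, n_supp=1, fold_point=b,
                 span_left=a, span_right=b, aligned_bases=n)
        )
        idx += 1

    for _ in range(n_state.get("fillup", 0)):
        # fragment contains the 3' ITR and folds there
        b = L - int(rng.integers(0, cfg.fold_jitter + 1)) if cfg.fold_jitter else L
        a = truncate(0, b)
        foldback("fillup", a, b)

    itr1_end = model.itr_intervals[0][1]
    itr2_start = model.itr_intervals[-1][0]
    axis_tol_guard = 100 + cfg.fold_jitter + 10  # keep planted snapbacks clear of ITRs
    for _ in range(n_state.get("snapback", 0)):
        # fold point needs >=300 nt upstream for the fragment
        lo = max(itr1_end + axis_tol_guard, 300 + cfg.fold_jitter)
        hi = itr2_start - axis_tol_guard
        if hi <= lo:
            raise ValueError("genome too short to place snapback fold points")
        b = int(rng.integers(lo, hi))
        if cfg.fold_jitter:
            b += int(rng.integers(-cfg.fold_jitter, cfg.fold_jitter + 1))
        frag_len = int(rng.integers(300, min(b, 2200) + 1))
        a = truncate(b - frag_len, b)
        foldback("snapback", a, b)

    for _ in range(n_state.get("multimer", 0)):
        n = int(rng.integers(300, 500))
        # five starts with pairwise gaps > n + 50: non-adjacent fragments
        max_start = L - n
        slots = np.linspace(0, max_start, 5).astype(int)
        starts = [
            min(int(s + rng.integers(0, max(1, (max_start // 5 - n) // 2))), max_start)
            for s in slots
        ]
        order = rng.permutation(5)
        frags = [(int(starts[i]), int(starts[i]) + n) for i in order]
        read_seq = "".join(genome[a:b] for a, b in frags)
        total = 5 * n
        # primary covers query fragment 0
        cigar = f"{n}M{total - n}S"
        sa = []
        for qi in range(1, 5):
            a, b = frags[qi]
            qoff = qi * n
            sa.append((vec, a, "+", f"{qoff}S{n}M{total - qoff - n}S"))
        records.append(_sam_line(f"read{idx:05d}", 0, vec, frags[0][0], cigar, read_seq, sa))
        span_l = min(a for a, _ in frags)
        span_r = max(b for _, b in frags)
        truth_rows.append(
            dict(read_id=f"read{idx:05d}", label="multimer", ref_name=vec, category="vector",
                 read_length=total, clip_fraction=(total - n) / total, n_supp=4,
                 fold_point=np.nan, span_left=span_l, span_right=span_r, aligned_bases=n)
        )
        idx += 1

    contam_refs = {cat: (name, seq) for name, seq, cat in model.references if cat not in ("vector",)}
    for cat, count in n_contam.items():
        if cat not in contam_refs:
            raise ValueError(f"no reference of category {cat!r} in model")
        name, seq = contam_refs[cat]
        for _ in range(count):
            n = int(rng.integers(500, 2500))
            a = int(rng.integers(0, len(seq) - n))
            records.append(_sam_line(f"read{idx:05d}", 0, name, a, f"{n}M", seq[a : a + n]))
            truth_rows.append(
                dict(read_id=f"read{idx:05d}", label="contaminant", ref_name=name,
                     category=cat, read_length=n, clip_fraction=0.0, n_supp=0,
                     fold_point=np.nan, span_left=a, span_right=a + n, aligned_bases=n)
            )
            idx += 1

    header = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{name}\tLN:{max(len(seq), 1)}"
        for name, seq, _ in model.references
    ]
    truth = pd.DataFrame(truth_rows)
    return SimResult(model=model, truth=truth, header_lines=header, record_lines=records)


def simulate_spiking_table(
    f_true: float,
    design: Sequence[tuple[float, float]] = SPIKING_DESIGN,
    noise_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> SpikingTable:
    """Spiking table under ``measured = ss + f_true * ds + N(0, sd)``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len({d for d, _ in design}) < 2:
        raise ValueError("design needs >= 2 distinct dsDNA levels")
    rng = np.random.default_rng(seed)
    measurements = []
    for ds, ss in design:
        reps = ss + f_true * ds + rng.normal(0.0, noise_sd, size=n_replicates)
        measurements.append(tuple(float(x) for x in reps))
    return SpikingTable(
        ds_conc=tuple(d for d, _ in design),
        ss_conc=tuple(s for _, s in design),
        measurements=tuple(measurements),
    )


def simulate_mass_photometry(
    populations: Sequence[tuple[float, float, float]],
    mass_empty: float,
    seed: int = 0,
    n_particles: int = 1000,
    noise_sd_kda: float = 0.0,
) -> np.ndarray:
    """Particle masses (kDa) for capsid populations.

    ``populations`` is a list of ``(mean_length_nt, sd_length_nt,
    weight)``; each particle's mass is the empty-capsid mass plus
    0.33 kDa per packaged nucleotide plus optional Gaussian noise.
    Weights must sum to 1.
    """
    weights = [w for _, _, w in populations]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("population weights must sum to 1")
    rng = np.random.default_rng(seed)
    counts = _allocate(n_particles, {i: w for i, (_, _, w) in enumerate(populations)})
    masses = []
    for i, (mean_nt, sd_nt, _) in enumerate(populations):
        lengths = np.clip(rng.normal(mean_nt, sd_nt, size=counts[i]) if sd_nt > 0
                          else np.full(counts[i], float(mean_nt)), 0, None)
        m = mass_empty + KDA_PER_NT * lengths
        if noise_sd_kda > 0:
            m = m + rng.normal(0.0, noise_sd_kda, size=counts[i])
        masses.append(m)
    return np.concatenate(masses) if masses else np.array([])
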