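"""Dataset assembly for TSS window classification, and a synthetic benchmark.

A labelled instance is a pair of windows centred on a candidate transcription
start site: a 201-base window (positions -100..+100) compared by string
kernels, and a 300-base physics window (positions -150..+149) from which the
breathing profile is computed.  Real benchmarks pair one experimentally
confirmed TSS per gene with ten decoy windows drawn from inside the gene body
(an imbalance ratio near 10:1), undersampled to 1:1 before learning.

The synthetic generator emulates exactly that shape without any external
genome: positive windows carry a degenerate promoter-like motif at a fixed
offset from the centre *and* locally elevated AT content in the central
region, so that both the sequence view and the physics view carry (partially
complementary) signal; negatives are plain background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pbd import SequenceAlphabetError, VALID_BASES

SEQ_WINDOW = 201   # [-100, +100] around the candidate site
PBD_WINDOW = 300   # [-150, +149] around the candidate site
SEQ_OFFSET = 50    # seq201 == seq300[50:251]
BASES = np.array(list("ACGT"))


@dataclass
class LabeledWindow:
    """One candidate site: its two sequence windows, label and optional features."""

    id: str
    seq201: str
    seq300: str
    label: int  # +1 TSS, -1 decoy
    profile: np.ndarray | None = None
    source_position: int = -1

    def __post_init__(self):
        self.seq201 = str(self.seq201).upper()
        self.seq300 = str(self.seq300).upper()
        if len(self.seq201) != SEQ_WINDOW:
            raise ValueError(f"seq201 must have length {SEQ_WINDOW}, got {len(self.seq201)}")
        if len(self.seq300) != PBD_WINDOW:
            raise ValueError(f"seq300 must have length {PBD_WINDOW}, got {len(self.seq300)}")
        for seq in (self.seq201, self.seq300):
            if set(seq) - VALID_BASES:
                raise SequenceAlphabetError(
                    f"window {self.id} contains non-ACGT characters", [self.id])
        if self.label not in (-1, 1):
            raise ValueError("label must be +1 or -1")
        if self.profile is not None:
            self.profile = np.asarray(self.profile, float)
            if self.profile.shape != (PBD_WINDOW - 100,):
                raise ValueError("profile must hold the 200 trimmed probabilities")
            if self.profile.min() < 0 or self.profile.max() > 1:
                raise ValueError("profile values must lie in [0, 1]")


@dataclass
class Dataset:
    windows: list[LabeledWindow] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(w.id for w in self.windows)

    @property
    def n_pos(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_neg(self) -> int:
        return int(np.sum(self.labels == -1))

    @property
    def ir(self) -> float:
        """Imbalance ratio: negatives per positive."""
        if self.n_pos == 0:
            raise ValueError("imbalance ratio undefined without positives")
        return self.n_neg / self.n_pos

    def seq201s(self) -> list[str]:
        return [w.seq201 for w in self.windows]

    def seq300s(self) -> list[str]:
        return [w.seq300 for w in self.windows]

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.windows[i] for i in indices])


# -- FASTA / label-table I/O -----------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs, in file order.

    Records with empty sequences or characters outside A/C/G/T (after
    uppercasing) are rejected with an error naming the offending ids.
    """
    records = []
    bad_ids = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) == 0 or set(seq) - VALID_BASES:
            bad_ids.append(rec.id)
        records.append((rec.id, seq))
    if bad_ids:
        raise SequenceAlphabetError(
            f"records with empty or non-ACGT sequences: {', '.join(bad_ids)}", bad_ids)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seq_records = [SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def write_labels(ds: Dataset, path) -> None:
    """Tab-separated label table: id, label (+1/-1), source_position."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\tsource_position\n")
        for w in ds.windows:
            fh.write(f"{w.id}\t{w.label:+d}\t{w.source_position}\n")


def read_labels(path) -> dict[str, int]:
    labels = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels[parts[0]] = int(parts[1])
    return labels


def write_dataset(ds: Dataset, directory) -> None:
    """Write a dataset as genome-style FASTA (physics windows) plus labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(((w.id, w.seq300) for w in ds.windows), directory / "windows300.fasta")
    write_fasta(((w.id, w.seq201) for w in ds.windows), directory / "windows201.fasta")
    write_labels(ds, directory / "labels.tsv")


def load_dataset(directory) -> Dataset:
    directory = Path(directory)
    seq300 = dict(read_fasta(directory / "windows300.fasta"))
    seq201 = dict(read_fasta(directory / "windows201.fasta"))
    labels = read_labels(directory / "labels.tsv")
    windows = [LabeledWindow(rid, seq201[rid], seq300[rid], labels[rid])
               for rid in seq300]
    return Dataset(windows)


# -- window extraction from a genome-like sequence --------------------------

def extract_windows(genome_seq: str, tss_positions: Sequence[int],
                    gene_ends: Sequence[int], n_neg_per_gene: int = 10,
                    seed: int = 0) -> Dataset:
    """One positive window per TSS plus decoys drawn from the gene body.

    For each gene the positive windows are centred on the TSS (0-based
    position in ``genome_seq``); ``n_neg_per_gene`` negatives are drawn
    uniformly from positions between 100 bases downstream of the TSS and the
    gene end.  Draws whose windows would overrun the sequence, or that repeat
    a position, are redrawn; genes with no feasible negative interval are
    skipped with a warning.
    """
    genome = str(genome_seq).upper()
    if set(genome) - VALID_BASES:
        raise SequenceAlphabetError("genome sequence contains non-ACGT characters")
    if len(tss_positions) != len(gene_ends):
        raise ValueError("tss_positions and gene_ends must have equal length")
    rng = np.random.default_rng(seed)
    windows = []

    def cut(centre: int) -> tuple[str, str]:
        s300 = genome[centre - 150:centre + 150]
        s201 = genome[centre - 100:centre + 101]
        return s201, s300

    def feasible(centre: int) -> bool:
        return centre - 150 >= 0 and centre + 150 <= len(genome)

    for g, (tss, end) in enumerate(zip(tss_positions, gene_ends)):
        tss, end = int(tss), int(end)
        if not feasible(tss):
            raise ValueError(f"TSS {tss} does not admit full windows within the sequence")
        if end <= tss + 100:
            raise ValueError(f"gene end {end} must exceed TSS + 100")
        s201, s300 = cut(tss)
        windows.append(LabeledWindow(f"gene{g}_tss", s201, s300, +1,
                                     source_position=tss))
        lo, hi = tss + 100, end
        candidates = [p for p in range(lo, hi + 1) if feasible(p)]
        if len(candidates) < n_neg_per_gene:
            warnings.warn(f"gene {g}: negative interval [{lo}, {hi}] infeasible; skipped")
            continue
        chosen: set[int] = set()
        while len(chosen) < n_neg_per_gene:
            p = int(rng.integers(lo, hi + 1))
            if p in chosen or not feasible(p):
                continue
            chosen.add(p)
            s201, s300 = cut(p)
            windows.append(LabeledWindow(f"gene{g}_neg{len(chosen) - 1}",
                                         s201, s300, -1, source_position=p))
    return Dataset(windows)


# -- undersampling -----------------------------------------------------------

def undersample_indices(labels: np.ndarray, target_ir: float, rng) -> np.ndarray:
    """Indices keeping all minority instances and a uniform majority subsample
    of size round(target_ir * minority count); order of the input preserved."""
    y = np.asarray(labels)
    if not target_ir > 0:
        raise ValueError("target_ir must be positive")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == -1)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("both classes must be present")
    minority, majority = (pos_idx, neg_idx) if pos_idx.size <= neg_idx.size else (neg_idx, pos_idx)
    n_keep = int(round(target_ir * minority.size))
    if n_keep > majority.size:
        raise ValueError(
            f"target imbalance ratio {target_ir} needs {n_keep} majority instances, "
            f"only {majority.size} available")
    kept = rng.choice(majority, size=n_keep, replace=False)
    return np.sort(np.concatenate([minority, kept]))


def undersample(ds: Dataset, target_ir: float = 1.0, seed: int = 0) -> Dataset:
    """Random undersampling of the majority class to the requested imbalance ratio."""
    rng = np.random.default_rng(seed)
    return ds.subset(undersample_indices(ds.labels, target_ir, rng).tolist())


# -- synthetic benchmark -----------------------------------------------------

@dataclass(frozen=True)
class MotifSpec:
    """Degenerate consensus motif planted in positive windows.

    ``offset`` positions the motif start relative to the candidate site
    (centre of the window); each motif position is independently replaced by
    a uniform random base with probability ``mutation_rate``.
    """

    consensus: str = "TATAAA"
    offset: int = -28
    mutation_rate: float = 0.15

    def __post_init__(self):
        if set(self.consensus.upper()) - VALID_BASES:
            raise ValueError("motif consensus must be over A/C/G/T")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


#: Half-width (bases) of the AT-enriched central region of positive windows.
CORE_HALFWIDTH = 30


def make_synthetic(n_pos: int, n_neg: int, motif: MotifSpec | None = None,
                   at_bias: float = 0.15, seed: int = 0,
                   id_prefix: str = "") -> Dataset:
    """Generate a TSS-like synthetic dataset with two complementary signals.

    Positive windows receive (a) extra AT probability mass ``at_bias`` in the
    central +/-30 bases, raising local breathing propensity, and (b) the
    planted motif near the centre, giving the string kernel a positional
    anchor.  Negatives are uniform background.  With ``at_bias = 0`` and
    ``mutation_rate = 1`` the positives are statistically indistinguishable
    from the negatives (the null construction).
    """
    motif = motif or MotifSpec()
    if not 0.0 <= at_bias <= 0.5:
        raise ValueError("at_bias must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    centre = PBD_WINDOW // 2  # candidate site at index 150 of the physics window
    core = slice(centre - CORE_HALFWIDTH, centre + CORE_HALFWIDTH + 1)
    p_bg = np.full(4, 0.25)
    at_each = (0.5 + at_bias) / 2.0
    gc_each = (0.5 - at_bias) / 2.0
    p_core = np.array([at_each, gc_each, gc_each, at_each])  # A, C, G, T

    consensus = motif.consensus.upper()
    m_start = centre + motif.offset
    if not (0 <= m_start and m_start + len(consensus) <= PBD_WINDOW):
        raise ValueError("motif placement falls outside the physics window")

    def draw_window(positive: bool) -> str:
        codes = rng.choice(4, size=PBD_WINDOW, p=p_bg)
        if positive:
            codes[core] = rng.choice(4, size=core.stop - core.start, p=p_core)
            motif_codes = np.fromiter((_CODE[b] for b in consensus), dtype=int)
            mutate = rng.random(len(consensus)) < motif.mutation_rate
            motif_codes[mutate] = rng.choice(4, size=int(mutate.sum()))
            codes[m_start:m_start + len(consensus)] = motif_codes
        return "".join(BASES[codes])

    windows = []
    for i in range(n_pos):
        s300 = draw_window(True)
        windows.append(LabeledWindow(f"{id_prefix}pos_{i:05d}", s300[SEQ_OFFSET:SEQ_OFFSET + SEQ_WINDOW],
                                     s300, +1, source_position=centre))
    for i in range(n_neg):
        s300 = draw_window(False)
        windows.append(LabeledWindow(f"{id_prefix}neg_{i:05d}", s300[SEQ_OFFSET:SEQ_OFFSET + SEQ_WINDOW],
                                     s300, -1, source_position=centre))
    return Dataset(windows)


_CODE = {b: i for i, b in enumerate("ACGT")}
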