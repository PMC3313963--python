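"""Synthetic motif-implanted epitope data with known ground truth.

Real MHC class II training data are variable-length epitopes, each
hiding one 9-residue binding register whose sequence preferences
concentrate on a few anchor positions (a strongly conserved P9 with
weaker P8/P4 conservation).  The generator emulates exactly that
structure: a position-specific profile with configurable anchors,
epitopes built as background-composition flanks around one profile-drawn
core, and host proteins into which each epitope is embedded so negative
windows and the 8-mer extension rule can be exercised.  Everything is
reproducible from (seed, config), and the emitted files pass the dataset
module's validators unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gibbs import EpitopeRecord
from .matrices import AMINO_ACIDS, CORE_LENGTH, N_RESIDUES

#: Approximate natural amino-acid abundances (UniProt-like composition),
#: selectable instead of the uniform default background.
NATURAL_ABUNDANCE = {
    "A": 0.083, "R": 0.056, "N": 0.041, "D": 0.055, "C": 0.014,
    "Q": 0.039, "E": 0.067, "G": 0.071, "H": 0.023, "I": 0.059,
    "L": 0.097, "K": 0.058, "M": 0.024, "F": 0.039, "P": 0.047,
    "S": 0.066, "T": 0.053, "W": 0.011, "Y": 0.029, "V": 0.069,
}


def background_composition(kind: str = "uniform") -> np.ndarray:
    """20-residue background distribution: "uniform" or "natural"."""
    if kind == "uniform":
        return np.full(N_RESIDUES, 1.0 / N_RESIDUES)
    if kind == "natural":
        p = np.array([NATURAL_ABUNDANCE[aa] for aa in AMINO_ACIDS])
        return p / p.sum()
    raise ValueError(f"unknown background kind {kind!r}")


@dataclass
class MotifProfile:
    """Position-specific residue distributions for the 9-mer core.

    ``probs`` is (9, 20), each row summing to 1.  ``anchors`` records the
    anchor positions (1-based) and their consensus residues.
    """

    probs: np.ndarray
    anchors: dict[int, str] = field(default_factory=dict)
    anchor_strength: float = 0.0
    background: np.ndarray = field(default_factory=lambda: background_composition())

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (CORE_LENGTH, N_RESIDUES):
            raise ValueError(f"profile must be {CORE_LENGTH}x{N_RESIDUES}")
        if not np.allclose(self.probs.sum(axis=1), 1.0):
            raise ValueError("each profile position must sum to 1")

    def sample_core(self, rng: np.random.Generator) -> str:
        idx = [rng.choice(N_RESIDUES, p=self.probs[i]) for i in range(CORE_LENGTH)]
        return "".join(AMINO_ACIDS[int(i)] for i in idx)

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[int(i)] for i in self.probs.argmax(axis=1))


@dataclass
class EpitopeTruth:
    """Ground truth for one generated epitope."""

    epitope_index: int
    protein_id: str
    core: str
    core_offset: int  # 0-based offset of the core within the epitope peptide
    core_start: int  # 1-based start of the core in the host protein
    emitted_length: int  # 8 for truncated epitopes, else the full length


@dataclass
class SyntheticTruth:
    """Everything needed to check recovery: per-epitope truth, profile, seed."""

    epitopes: list[EpitopeTruth]
    profile: MotifProfile
    seed: int


def generate_motif(
    anchor_positions=(9, 8, 4),
    anchor_strength: float = 0.9,
    rng: np.random.Generator | None = None,
    background: np.ndarray | None = None,
    secondary_strength: float | None = None,
) -> MotifProfile:
    """Build a core profile with concentrated anchors over a background.

    Every anchor position concentrates at least ``anchor_strength`` of its
    mass on one random residue; non-anchor positions follow the
    background.  To emulate a graded conservation pattern (one dominant
    position plus weaker companions) pass ``secondary_strength`` for the
    anchors after the first.
    """
    if not 0.05 < anchor_strength <= 1.0:
        raise ValueError("anchor_strength must lie in (0.05, 1]")
    rng = rng or np.random.default_rng()
    bg = background if background is not None else background_composition()
    if secondary_strength is None:
        secondary_strength = anchor_strength
    probs = np.tile(bg, (CORE_LENGTH, 1))
    anchors: dict[int, str] = {}
    for rank, pos in enumerate(anchor_positions):
        if not 1 <= pos <= CORE_LENGTH:
            raise ValueError(f"anchor position {pos} outside 1..{CORE_LENGTH}")
        strength = anchor_strength if rank == 0 else secondary_strength
        residue = int(rng.integers(N_RESIDUES))
        row = bg * (1.0 - strength) / (1.0 - bg[residue])
        row[residue] = strength
        probs[pos - 1] = row / row.sum()
        anchors[pos] = AMINO_ACIDS[residue]
    return MotifProfile(probs, anchors, anchor_strength, bg)


def exact_motif_profile(core: str) -> MotifProfile:
    """Degenerate profile that always emits one fixed 9-mer (for recovery tests)."""
    probs = np.zeros((CORE_LENGTH, N_RESIDUES))
    for i, aa in enumerate(core.upper()):
        probs[i, AMINO_ACIDS.index(aa)] = 1.0
    return MotifProfile(probs, {i + 1: aa for i, aa in enumerate(core.upper())}, 1.0)


def _random_sequence(n: int, bg: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(N_RESIDUES, size=n, p=bg)
    return "".join(AMINO_ACIDS[int(i)] for i in idx)


def generate_epitope_set(
    profile: MotifProfile,
    n: int,
    length_range: tuple[int, int] = (12, 25),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    protein_length: int = 120,
    eight_mer_fraction: float = 0.05,
    haplotype: str = "SYN",
    protein_prefix: str = "SYNP",
) -> tuple[dict[str, str], list[EpitopeRecord], SyntheticTruth]:
    """Generate host proteins, epitope records and ground truth.

    Each epitope is one profile-drawn core at a uniform random offset
    inside background flanks, embedded at a recorded locus of a
    background host protein (one protein per epitope).  A configurable
    fraction of epitopes is emitted as 8-mers — the core with one
    terminal residue cut off — to exercise the extension rule; the host
    protein always contains the full context.
    """
    lo, hi = length_range
    if n < 2:
        raise ValueError("generate at least 2 epitopes")
    if lo < CORE_LENGTH or hi < lo:
        raise ValueError(f"length range must satisfy {CORE_LENGTH} <= min <= max")
    if seed is not None:
        rng = np.random.default_rng(seed)
    elif rng is None:
        rng = np.random.default_rng()
    seed_used = seed if seed is not None else -1

    proteins: dict[str, str] = {}
    epitopes: list[EpitopeRecord] = []
    truths: list[EpitopeTruth] = []
    n_short = int(round(eight_mer_fraction * n))
    for i in range(n):
        pid = f"{protein_prefix}{i + 1:04d}"
        as_8mer = i < n_short
        length = CORE_LENGTH if as_8mer else int(rng.integers(lo, hi + 1))
        core = profile.sample_core(rng)
        offset = int(rng.integers(0, length - CORE_LENGTH + 1))
        left = _random_sequence(offset, profile.background, rng)
        right = _random_sequence(length - CORE_LENGTH - offset, profile.background, rng)
        peptide = left + core + right
        # embed away from the termini so an 8-mer can always be extended
        locus = int(rng.integers(2, protein_length - length))  # 1-based epitope start
        host = _random_sequence(protein_length, profile.background, rng)
        host = host[: locus - 1] + peptide + host[locus - 1 + length :]
        proteins[pid] = host
        start, end = locus, locus + length - 1
        emitted = peptide
        if as_8mer:
            # cut one terminal residue off the 9-mer so ingest sees an 8-mer
            if int(rng.integers(2)) == 0:
                emitted, start = peptide[1:], start + 1
            else:
                emitted, end = peptide[:-1], end - 1
        epitopes.append(EpitopeRecord(pid, start, end, emitted, haplotype))
        truths.append(
            EpitopeTruth(
                epitope_index=i,
                protein_id=pid,
                core=core,
                core_offset=offset,
                core_start=locus + offset,
                emitted_length=len(emitted),
            )
        )
    return proteins, epitopes, SyntheticTruth(truths, profile, seed_used)


def generate_null_nonamers(
    background: np.ndarray, n: int, rng: np.random.Generator | None = None
) -> list[str]:
    """I.i.d. background 9-mers (negatives for power and AROC studies)."""
    if n < 1:
        raise ValueError("generate at least 1 nonamer")
    rng = rng or np.random.default_rng()
    return [_random_sequence(CORE_LENGTH, background, rng) for _ in range(n)]


def generate_labeled_set(
    profile: MotifProfile,
    n_positives: int,
    n_negatives: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Unique profile-drawn positives plus background negatives, disjoint.

    Sampling continues until the requested number of *unique* positives is
    reached, mirroring the deduplicated unique-core training sets built
    from real epitopes.
    """
    from .dataset import LabeledNonamerSet

    if seed is not None:
        rng = np.random.default_rng(seed)
    elif rng is None:
        rng = np.random.default_rng()
    positives: dict[str, None] = {}
    guard = 0
    while len(positives) < n_positives:
        positives.setdefault(profile.sample_core(rng))
        guard += 1
        if guard > 100 * n_positives:
            raise ValueError(
                "profile is too concentrated to yield the requested number of "
                "unique positive cores"
            )
    negatives = generate_null_nonamers(profile.background, n_negatives, rng)
    return LabeledNonamerSet(list(positives), negatives)


def write_truth_table(path, truth: SyntheticTruth) -> None:
    """Ground-truth TSV: one row per epitope with core placement."""
    with open(path, "w") as fh:
        fh.write(f"# generator seed: {truth.seed}\n")
        fh.write("epitope_index\tprotein_id\tcore\tcore_offset\tcore_start\temitted_length\n")
        for t in truth.epitopes:
            fh.write(
                f"{t.epitope_index}\t{t.protein_id}\t{t.core}\t{t.core_offset}\t"
                f"{t.core_start}\t{t.emitted_length}\n"
            )
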