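"""Substitution matrices, position weights, and the residue alphabet.

The similarity scoring throughout the package is defined over the 20
standard amino acids only.  Matrices start from the canonical published
BLOSUM tables (via Biopython) but live in a mutable integer container so
the matrix-mutation training stage can perturb individual entries and the
result can be saved and reloaded exactly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices as _bp_matrices

#: Canonical residue order used for encoding and for matrix text layout
#: (the conventional NCBI substitution-matrix ordering).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_RESIDUES = 20

#: Length of the binding-groove core register.
CORE_LENGTH = 9

AVAILABLE_MATRICES = ("BLOSUM62", "BLOSUM45")


class NonStandardResidueError(ValueError):
    """A residue outside the 20-letter standard alphabet was encountered."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(
            f"non-standard residue {symbol!r}; scoring is defined only over "
            f"the standard alphabet {AMINO_ACIDS}"
        )


# byte -> residue index lookup, -1 for anything non-standard (case-folded)
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _CODE_TABLE[ord(_aa)] = _i
    _CODE_TABLE[ord(_aa.lower())] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a peptide/protein string into residue indices (int8).

    Case-insensitive.  Raises :class:`NonStandardResidueError` naming the
    first offending symbol.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE_TABLE[raw]
    if (codes < 0).any():
        bad = sequence[int(np.argmax(codes < 0))]
        raise NonStandardResidueError(bad)
    return codes


def encode_sequence_masked(sequence: str) -> np.ndarray:
    """Encode like :func:`encode_sequence` but keep -1 for non-standard symbols."""
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[int(c)] for c in codes)


def encode_peptides(peptides, length: int | None = None) -> np.ndarray:
    """Encode an iterable of equal-length peptides into a 2-D code array."""
    rows = [encode_sequence(p) for p in peptides]
    if length is not None:
        for p, r in zip(peptides, rows):
            if len(r) != length:
                raise ValueError(f"peptide {p!r} has length {len(r)}, expected {length}")
    return np.vstack(rows) if rows else np.empty((0, length or 0), dtype=np.int8)


@dataclass(eq=False)
class SubstitutionMatrix:
    """Integer residue-pair score matrix over the standard alphabet.

    ``scores[i, j]`` is the score for the ordered residue pair
    ``(AMINO_ACIDS[i], AMINO_ACIDS[j])``.  Shipped matrices are symmetric;
    matrix-mutation training keeps them symmetric by perturbing ``(a, b)``
    and ``(b, a)`` jointly.
    """

    scores: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.shape != (N_RESIDUES, N_RESIDUES):
            raise ValueError(
                f"substitution matrix must be {N_RESIDUES}x{N_RESIDUES}, "
                f"got {self.scores.shape}"
            )

    def score(self, a: str, b: str) -> int:
        """Score for the residue pair (a, b); case-insensitive."""
        ia, ib = _residue_index(a), _residue_index(b)
        return int(self.scores[ia, ib])

    def copy(self) -> "SubstitutionMatrix":
        return SubstitutionMatrix(self.scores.copy(), self.name)

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.scores, self.scores.T))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SubstitutionMatrix)
            and self.name == other.name
            and np.array_equal(self.scores, other.scores)
        )

    # -- text serialization: conventional square-table layout ---------------

    def to_text(self) -> str:
        """Whitespace-delimited square table with residue header row/column."""
        out = io.StringIO()
        out.write("   " + "  ".join(AMINO_ACIDS) + "\n")
        for i, aa in enumerate(AMINO_ACIDS):
            row = " ".join(f"{int(v):3d}" for v in self.scores[i])
            out.write(f"{aa} {row}\n")
        return out.getvalue()

    @classmethod
    def from_text(cls, text: str, name: str = "custom") -> "SubstitutionMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        header = lines[0].split()
        if "".join(header) != AMINO_ACIDS:
            raise ValueError(
                "matrix header must list the 20 standard residues in the order "
                f"{AMINO_ACIDS}, got {''.join(header)!r}"
            )
        scores = np.zeros((N_RESIDUES, N_RESIDUES), dtype=np.int64)
        for line in lines[1:]:
            parts = line.split()
            aa, values = parts[0], parts[1:]
            if aa not in AA_INDEX or len(values) != N_RESIDUES:
                raise ValueError(f"malformed matrix row: {line!r}")
            scores[AA_INDEX[aa]] = [int(v) for v in values]
        return cls(scores, name)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path, name: str = "custom") -> "SubstitutionMatrix":
        with open(path) as fh:
            return cls.from_text(fh.read(), name)


def _residue_index(symbol: str) -> int:
    if len(symbol) != 1:
        raise ValueError(f"expected a single residue symbol, got {symbol!r}")
    idx = _CODE_TABLE[ord(symbol)] if ord(symbol) < 256 else -1
    if idx < 0:
        raise NonStandardResidueError(symbol)
    return int(idx)


def load_substitution_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a shipped substitution matrix by label ("BLOSUM62", "BLOSUM45")."""
    label = name.upper()
    if label not in AVAILABLE_MATRICES:
        raise ValueError(
            f"unknown substitution matrix {name!r}; available: "
            + ", ".join(AVAILABLE_MATRICES)
        )
    bp = _bp_matrices.load(label)
    scores = np.zeros((N_RESIDUES, N_RESIDUES), dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            scores[i, j] = int(bp[a, b])
    return SubstitutionMatrix(scores, label)


def pair_score(matrix: SubstitutionMatrix, a: str, b: str) -> int:
    """Elementary residue-pair score lookup (symmetric on shipped matrices)."""
    return matrix.score(a, b)


@dataclass(eq=False)
class PositionWeights:
    """Nine non-negative per-position weights for the core register.

    All-ones initially, so the weighted similarity reduces to the plain
    substitution-score sum before any weight training has run.
    """

    w: np.ndarray = field(default_factory=lambda: np.ones(CORE_LENGTH))

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.shape != (CORE_LENGTH,):
            raise ValueError(f"weights must have length {CORE_LENGTH}, got {self.w.shape}")
        if (self.w < 0).any():
            raise ValueError("position weights must be non-negative")

    def copy(self) -> "PositionWeights":
        return PositionWeights(self.w.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, PositionWeights) and np.array_equal(self.w, other.w)

    def __iter__(self):
        return iter(self.w)
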