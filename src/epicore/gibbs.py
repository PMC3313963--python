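"""Gibbs-sampling assignment of one 9-mer binding core per epitope.

Experimentally mapped MHC class II epitopes vary in length (roughly
9-30 aa) but bind through a fixed 9-residue register.  This module
implements the similarity-driven Gibbs sampler that aligns a set of
variable-length epitopes to nonamer cores: starting from one random
window per epitope, it repeatedly revisits epitopes in random order and
moves each assignment to the window whose average clamped similarity to
all other current cores is maximal, until a full pass changes nothing.

Unlike the classical motif-sampling formulation, the objective is the
average substitution-matrix similarity score, not a PSSM log-odds
frequency ratio; the sampler runs before any weight or matrix training
and therefore always uses the unweighted matrix score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrices import CORE_LENGTH, SubstitutionMatrix, encode_sequence
from .scoring import Nonamer

logger = logging.getLogger(__name__)


@dataclass
class EpitopeRecord:
    """A literature epitope: protein accession, 1-based inclusive span, peptide."""

    protein_id: str
    start: int
    end: int
    peptide: str
    haplotype: str = ""

    def __post_init__(self):
        self.peptide = self.peptide.upper()
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError(
                f"epitope span {self.start}..{self.end} does not match peptide "
                f"length {len(self.peptide)} ({self.protein_id})"
            )

    def __len__(self) -> int:
        return len(self.peptide)


@dataclass
class CoreAssignment:
    """The chosen window for one epitope: offset within the epitope and the core."""

    epitope_index: int
    offset: int  # 0-based offset of the core within the epitope peptide
    core: str

    @property
    def core_nonamer(self) -> Nonamer:
        return Nonamer(self.core)


@dataclass
class CoreSet:
    """Per-epitope core assignments plus the deduplicated unique-core list."""

    assignments: list[CoreAssignment]
    unique_cores: list[str]
    sweeps_run: int
    converged: bool
    seed: int | None = None
    total_objective: float = 0.0
    restarts: int = 1


@dataclass
class GibbsConfig:
    """Sampler settings: seed, convergence sweep cap, and restart count."""

    seed: int = 0
    max_sweeps: int = 200
    restarts: int = 5


def extend_short_epitope(
    epitope: EpitopeRecord, protein_sequence: str | None
) -> EpitopeRecord | None:
    """Grow an 8-mer epitope by one residue on each side using its protein.

    Epitopes of length >= 9 pass through unchanged.  An 8-mer that abuts a
    protein terminus, or whose protein sequence is unavailable, is dropped
    (returns None) with a logged warning.
    """
    if len(epitope) != 8:
        return epitope
    if protein_sequence is None:
        logger.warning(
            "dropping 8-mer epitope %s %d..%d: protein sequence unavailable",
            epitope.protein_id, epitope.start, epitope.end,
        )
        return None
    if epitope.start <= 1 or epitope.end >= len(protein_sequence):
        logger.warning(
            "dropping 8-mer epitope %s %d..%d: cannot extend past a terminus",
            epitope.protein_id, epitope.start, epitope.end,
        )
        return None
    new_start, new_end = epitope.start - 1, epitope.end + 1
    peptide = protein_sequence[new_start - 1 : new_end].upper()
    return EpitopeRecord(epitope.protein_id, new_start, new_end, peptide, epitope.haplotype)


def candidate_mean_similarity(core, others, matrix: SubstitutionMatrix) -> float:
    """Mean clamped unweighted similarity of one candidate core to the others."""
    others = list(others)
    if not others:
        raise ValueError("candidate_mean_similarity requires a non-empty comparator set")
    c = encode_sequence(str(core))[None, :]
    o = np.vstack([encode_sequence(str(p)) for p in others])
    per_pos = matrix.scores[c[:, None, :], o[None, :, :]].sum(axis=2)
    return float(np.maximum(per_pos, 0.0).mean())


def _window_codes(epitopes: list[EpitopeRecord]) -> list[np.ndarray]:
    """All 9-mer window code arrays per epitope, shape (n_windows, 9) each."""
    out = []
    for e in epitopes:
        codes = encode_sequence(e.peptide)
        out.append(np.lib.stride_tricks.sliding_window_view(codes, CORE_LENGTH).copy())
    return out


def _run_once(
    windows: list[np.ndarray],
    scores: np.ndarray,
    rng: np.random.Generator,
    max_sweeps: int,
) -> tuple[np.ndarray, int, bool]:
    """One sampler run: returns (offsets, sweeps_run, converged)."""
    n = len(windows)
    offsets = np.array([rng.integers(len(w)) for w in windows])
    cores = np.vstack([w[o] for w, o in zip(windows, offsets)])

    sweeps = 0
    converged = False
    mask = np.ones(n, dtype=bool)
    for sweeps in range(1, max_sweeps + 1):
        changed = 0
        for i in rng.permutation(n):
            mask[i] = False
            others = cores[mask]
            mask[i] = True
            # (n_windows, n-1) clamped similarities, then mean per window
            per_pos = scores[windows[i][:, None, :], others[None, :, :]].sum(axis=2)
            means = np.maximum(per_pos, 0.0).mean(axis=1)
            best = int(np.argmax(means))  # first max -> smallest offset wins ties
            if best != offsets[i]:
                offsets[i] = best
                cores[i] = windows[i][best]
                changed += 1
        if changed == 0:
            converged = True
            break
    return offsets, sweeps, converged


def _total_objective(windows, offsets, scores) -> float:
    cores = np.vstack([w[o] for w, o in zip(windows, offsets)])
    per_pos = scores[cores[:, None, :], cores[None, :, :]].sum(axis=2)
    clamped = np.maximum(per_pos, 0.0)
    n = len(windows)
    np.fill_diagonal(clamped, 0.0)
    return float((clamped.sum(axis=1) / (n - 1)).sum())


def sample_cores(
    epitopes: list[EpitopeRecord],
    matrix: SubstitutionMatrix,
    config: GibbsConfig | None = None,
) -> CoreSet:
    """Assign one 9-mer core per epitope by similarity-driven Gibbs sampling.

    Runs ``config.restarts`` independent restarts from one seeded generator
    and keeps the run with the highest total objective (the sum over
    epitopes of each core's mean clamped similarity to the others).
    Identical seed and input order give an identical result.
    """
    config = config or GibbsConfig()
    if len(epitopes) < 2:
        raise ValueError("core sampling requires at least 2 epitopes")
    for e in epitopes:
        if len(e) < CORE_LENGTH:
            raise ValueError(
                f"epitope {e.protein_id} {e.start}..{e.end} is shorter than "
                f"{CORE_LENGTH} aa; extend or drop it first"
            )

    windows = _window_codes(epitopes)
    rng = np.random.default_rng(config.seed)

    best = None
    for _ in range(max(1, config.restarts)):
        offsets, sweeps, converged = _run_once(windows, matrix.scores, rng, config.max_sweeps)
        objective = _total_objective(windows, offsets, matrix.scores)
        if best is None or objective > best[3]:
            best = (offsets, sweeps, converged, objective)

    offsets, sweeps, converged, objective = best
    if not converged:
        logger.warning("Gibbs sampler did not converge within %d sweeps", config.max_sweeps)

    assignments = []
    seen: dict[str, None] = {}
    for i, (e, off) in enumerate(zip(epitopes, offsets)):
        core = e.peptide[off : off + CORE_LENGTH]
        assignments.append(CoreAssignment(i, int(off), core))
        seen.setdefault(core)
    return CoreSet(
        assignments=assignments,
        unique_cores=list(seen),
        sweeps_run=sweeps,
        converged=converged,
        seed=config.seed,
        total_objective=objective,
        restarts=max(1, config.restarts),
    )
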