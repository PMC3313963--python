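"""Peptide similarity scoring and sliding-window protein scanning.

The similarity between two nonamers A and B is the position-wise sum of
substitution scores, optionally weighted per position:

    S'(A, B) = sum_i w_i * Score(A[i], B[i]),   clamped to 0 if negative.

A query nonamer is scored against a model by averaging its clamped
pairwise similarity over all training cores.  Clamping is applied per
pair, before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrices import (
    CORE_LENGTH,
    PositionWeights,
    SubstitutionMatrix,
    encode_peptides,
    encode_sequence,
    encode_sequence_masked,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Nonamer:
    """A 9-residue peptide, optionally with its (protein_id, 1-based start) origin."""

    sequence: str
    origin: tuple[str, int] | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        codes = encode_sequence(seq)  # validates alphabet
        if len(codes) != CORE_LENGTH:
            raise ValueError(f"nonamer must have length {CORE_LENGTH}, got {len(seq)}")

    def __str__(self) -> str:
        return self.sequence


def _as_sequence(p) -> str:
    return p.sequence if isinstance(p, Nonamer) else str(p)


def _unit_weights() -> np.ndarray:
    return np.ones(CORE_LENGTH)


def _weights_array(weights) -> np.ndarray:
    if weights is None:
        return _unit_weights()
    if isinstance(weights, PositionWeights):
        return weights.w
    return np.asarray(weights, dtype=np.float64)


def pairwise_similarity_matrix(
    query_codes: np.ndarray,
    core_codes: np.ndarray,
    matrix: SubstitutionMatrix,
    weights=None,
) -> np.ndarray:
    """Clamped weighted similarity for every (query, core) pair.

    ``query_codes``/``core_codes`` are int code arrays of shape (n, 9);
    the result has shape (n_query, n_core), every entry >= 0.
    """
    w = _weights_array(weights)
    per_pos = matrix.scores[query_codes[:, None, :], core_codes[None, :, :]]
    raw = per_pos @ w
    return np.maximum(raw, 0.0)


def peptide_similarity(a, b, matrix: SubstitutionMatrix, weights=None) -> float:
    """Clamped (weighted) similarity between two nonamers."""
    qa = encode_peptides([_as_sequence(a)], CORE_LENGTH)
    qb = encode_peptides([_as_sequence(b)], CORE_LENGTH)
    return float(pairwise_similarity_matrix(qa, qb, matrix, weights)[0, 0])


def model_score(query, cores, matrix: SubstitutionMatrix, weights=None) -> float:
    """Average clamped similarity of ``query`` over a non-empty core list."""
    cores = list(cores)
    if not cores:
        raise ValueError("model_score requires a non-empty core set")
    q = encode_peptides([_as_sequence(query)], CORE_LENGTH)
    c = encode_peptides([_as_sequence(p) for p in cores], CORE_LENGTH)
    return float(pairwise_similarity_matrix(q, c, matrix, weights).mean(axis=1)[0])


def score_against_cores(
    query_codes: np.ndarray,
    core_codes: np.ndarray,
    matrix: SubstitutionMatrix,
    weights=None,
    leave_one_out: bool = False,
) -> np.ndarray:
    """Vectorized model scores for many queries against one core set.

    With ``leave_one_out=True`` the query set must *be* the core set
    (same array); each row is then averaged over the other cores only.
    """
    sims = pairwise_similarity_matrix(query_codes, core_codes, matrix, weights)
    n_cores = core_codes.shape[0]
    if leave_one_out:
        if query_codes.shape[0] != n_cores:
            raise ValueError("leave-one-out scoring requires queries == cores")
        if n_cores < 2:
            raise ValueError("leave-one-out scoring requires at least 2 cores")
        diag = np.diagonal(sims)
        return (sims.sum(axis=1) - diag) / (n_cores - 1)
    return sims.mean(axis=1)


@dataclass(frozen=True)
class PredictionHit:
    """One predicted binding core: 1-based inclusive span, peptide and score."""

    start: int
    end: int
    peptide: str
    score: float

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def scan_protein(
    sequence: str,
    model,
    threshold: float | None = None,
    tier: str | None = None,
) -> list[PredictionHit]:
    """Score every 9-residue window of a protein against a trained model.

    Windows scoring strictly above the cutoff are returned in ascending
    start order with 1-based inclusive spans.  Windows containing
    non-standard residues are skipped (and counted in the log); proteins
    shorter than 9 residues yield an empty list with a warning.

    ``threshold`` overrides ``tier``; with neither given the model's
    default tier ("medium") is used.
    """
    if threshold is None:
        cutoff = model.threshold_for_tier(tier or model.default_tier)
    else:
        cutoff = float(threshold)

    seq = sequence.upper()
    n = len(seq)
    if n < CORE_LENGTH:
        logger.warning("protein of length %d is shorter than %d; no windows scored", n, CORE_LENGTH)
        return []

    codes = encode_sequence_masked(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, CORE_LENGTH)
    valid = (windows >= 0).all(axis=1)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("skipped %d window(s) containing non-standard residues", n_skipped)
    if not valid.any():
        return []

    starts = np.nonzero(valid)[0]
    scores = score_against_cores(
        windows[starts].astype(np.int8), model.encoded_cores, model.matrix, model.weights
    )
    hits = []
    for k, s in zip(starts, scores):
        if s > cutoff:
            start1 = int(k) + 1
            hits.append(PredictionHit(start1, start1 + CORE_LENGTH - 1, seq[k : k + CORE_LENGTH], float(s)))
    return hits
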